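"""Hierarchical (imaging-site -> neuron) bootstrap tests.

Calcium-imaging datasets are nested: many neurons come from few imaging
sites, and neurons within a site share slow state, expression level and
optical conditions.  Treating neurons as independent underestimates the
sampling variance of population means.  The hierarchical bootstrap
resamples imaging sites with replacement first, then neurons with
replacement within each drawn site, and uses the spread of the resampled
grand means for inference: the p-value of a directional hypothesis is the
fraction of bootstrap means that violate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "GroupedSample",
    "BootstrapResult",
    "hboot_means",
    "hboot_test",
    "timecourse_test",
]

DIRECTIONS = ("two_sided", "a_gt_b", "a_lt_b")


@dataclass
class GroupedSample:
    """Per-neuron scalars (or time vectors) grouped by imaging site.

    ``values`` has shape (N,) or (N, T); ``site_id`` has shape (N,).
    ``keys`` optionally identifies neurons for paired comparisons.
    """

    values: np.ndarray
    site_id: np.ndarray
    keys: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.site_id = np.asarray(self.site_id)
        if self.values.shape[0] != self.site_id.shape[0]:
            raise ValueError("values and site_id must have one entry per neuron")
        if self.values.shape[0] == 0:
            raise ValueError("empty sample")
        sites, counts = np.unique(self.site_id, return_counts=True)
        if (counts == 0).any():
            raise ValueError("every site must contain at least one value")
        if self.keys is not None:
            self.keys = np.asarray(self.keys)
            if self.keys.shape[0] != self.values.shape[0]:
                raise ValueError("keys must have one entry per neuron")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def sites(self) -> np.ndarray:
        return np.unique(self.site_id)


@dataclass
class BootstrapResult:
    """Bootstrap distribution and p-value(s) for one hypothesis."""

    boot_means: np.ndarray        # (n_boot,) or (n_boot, n_bins)
    p_value: np.ndarray | float   # scalar, or per time bin
    n_boot: int
    seed: int
    hypothesis: str
    direction: str = "two_sided"
    alpha: float = 0.05
    sig_mask: Optional[np.ndarray] = None   # per time bin, p < alpha
    bin_time_s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_value, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p-values must lie in [0, 1]")


def _boot_mean_matrix(values: np.ndarray, site_id: np.ndarray, n_boot: int,
                      rng: np.random.Generator,
                      equal_site_counts: bool = False) -> np.ndarray:
    """Vectorized two-level bootstrap means.

    Each replicate draws S sites with replacement (S = number of sites),
    then within each drawn site draws as many neurons with replacement as
    that site contains (or a fixed count per site when
    ``equal_site_counts``), and takes the grand mean over all drawn values.

    Returns shape (n_boot,) for scalar values or (n_boot, T) for vectors.
    """
    values = np.asarray(values, dtype=float)
    scalar = values.ndim == 1
    vals = values[:, None] if scalar else values
    T = vals.shape[1]
    sites = np.unique(site_id)
    S = sites.size
    site_indices = [np.flatnonzero(site_id == s) for s in sites]
    site_sizes = np.array([ix.size for ix in site_indices])
    if equal_site_counts:
        draw_sizes = np.full(S, max(1, int(round(vals.shape[0] / S))))
    else:
        draw_sizes = site_sizes
    slot = rng.integers(0, S, size=n_boot * S)          # site draws, flattened
    flat_sums = np.empty((n_boot * S, T))
    flat_n = draw_sizes[slot].astype(float)
    for s in range(S):
        pos = np.flatnonzero(slot == s)
        if pos.size == 0:
            continue
        n_s = int(draw_sizes[s])
        idx = rng.integers(0, site_sizes[s], size=(pos.size, n_s))
        flat_sums[pos] = vals[site_indices[s]][idx].sum(axis=1)
    sums = flat_sums.reshape(n_boot, S, T).sum(axis=1)
    totals = flat_n.reshape(n_boot, S).sum(axis=1)
    out = sums / totals[:, None]
    return out[:, 0] if scalar else out


def hboot_means(sample: GroupedSample, n_boot: int = 10000,
                seed: int = 0, equal_site_counts: bool = False) -> np.ndarray:
    """Bootstrap distribution of the population mean under site->neuron
    resampling.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    return _boot_mean_matrix(sample.values, sample.site_id, n_boot, rng,
                             equal_site_counts)


def _group_seed(seed: int, sample: GroupedSample) -> int:
    """Derive a per-group bootstrap seed from the test seed and the group's
    content (so unpaired tests are symmetric under argument swap)."""
    import zlib

    h = zlib.crc32(np.ascontiguousarray(sample.values).tobytes())
    h = zlib.crc32(np.ascontiguousarray(sample.site_id).tobytes(), h)
    ss = np.random.SeedSequence([int(seed) % (2**31), h % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def _pair(a: GroupedSample, b: GroupedSample) -> GroupedSample:
    """Align two samples by key and return the per-neuron differences."""
    if a.keys is None or b.keys is None:
        raise ValueError("paired comparison requires keys on both samples")
    if a.n != b.n or set(a.keys.tolist()) != set(b.keys.tolist()):
        raise ValueError("paired comparison requires identical key sets")
    order_a = np.argsort(a.keys, kind="stable")
    order_b = np.argsort(b.keys, kind="stable")
    diff = a.values[order_a] - b.values[order_b]
    return GroupedSample(values=diff, site_id=a.site_id[order_a],
                         keys=a.keys[order_a])


def hboot_test(a: GroupedSample, b: Optional[GroupedSample] = None,
               direction: str = "two_sided", n_boot: int = 10000,
               seed: int = 0, paired: bool = False,
               alpha: float = 0.05) -> BootstrapResult:
    """Hierarchical bootstrap test of the mean of ``a`` against ``b``
    (or against zero when ``b`` is None).

    The per-replicate statistic is the (paired or unpaired) mean difference.
    ``p`` is the fraction of replicates violating the directional
    hypothesis; ties (difference exactly 0) count as violations, which makes
    degenerate all-zero data conservatively non-significant.  The two-sided
    p-value is ``min(1, 2 * min(p_gt, p_lt))``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    rng_seed = int(seed)
    if b is None:
        stat = hboot_means(a, n_boot, rng_seed)
        label = "mean(a) vs 0"
    elif paired:
        stat = hboot_means(_pair(a, b), n_boot, rng_seed)
        label = "paired mean(a - b) vs 0"
    else:
        # each group's resampling stream is keyed to its own content so that
        # swapping the arguments negates the statistic exactly
        stat = (hboot_means(a, n_boot, _group_seed(rng_seed, a))
                - hboot_means(b, n_boot, _group_seed(rng_seed, b)))
        label = "mean(a) - mean(b) vs 0"
    # violations include exact ties
    p_gt = np.mean(stat <= 0, axis=0)   # violations of "a > b"
    p_lt = np.mean(stat >= 0, axis=0)   # violations of "a < b"
    if direction == "a_gt_b":
        p = p_gt
    elif direction == "a_lt_b":
        p = p_lt
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_gt, p_lt))
    p = float(p) if np.ndim(p) == 0 else p
    return BootstrapResult(boot_means=stat, p_value=p, n_boot=n_boot,
                           seed=rng_seed, hypothesis=f"{label} [{direction}]",
                           direction=direction, alpha=alpha)


def _bin_traces(traces: np.ndarray, bin_frames: int) -> np.ndarray:
    n_bins = traces.shape[1] // bin_frames
    return traces[:, : n_bins * bin_frames].reshape(
        traces.shape[0], n_bins, bin_frames).mean(axis=2)


def timecourse_test(a: GroupedSample, b: Optional[GroupedSample] = None,
                    fs: float = 15.0, bin_frames: int = 5,
                    alpha: float = 0.05, n_boot: int = 10000, seed: int = 0,
                    paired: bool = False, direction: str = "two_sided",
                    time_s: Optional[np.ndarray] = None) -> BootstrapResult:
    """Time-resolved hierarchical bootstrap: per-neuron traces are averaged
    in consecutive ``bin_frames``-frame bins (333 ms at 15 Hz) and the test
    is run per bin.  ``sig_mask`` marks bins with p < alpha.  No correction
    across bins is applied (each bin is reported as in the per-bin
    significance bars of population-trace figures).
    """
    if a.values.ndim != 2:
        raise ValueError("timecourse_test needs per-neuron time vectors")
    if b is not None and b.values.shape[1] != a.values.shape[1]:
        raise ValueError("incompatible time axes")
    ab = GroupedSample(_bin_traces(a.values, bin_frames), a.site_id, a.keys)
    bb = None
    if b is not None:
        bb = GroupedSample(_bin_traces(b.values, bin_frames), b.site_id, b.keys)
    res = hboot_test(ab, bb, direction=direction, n_boot=n_boot, seed=seed,
                     paired=paired, alpha=alpha)
    res.sig_mask = np.asarray(res.p_value) < alpha
    if time_s is not None:
        n_bins = a.values.shape[1] // bin_frames
        t = np.asarray(time_s)[: n_bins * bin_frames]
        res.bin_time_s = t.reshape(n_bins, bin_frames).mean(axis=1)
    return res
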