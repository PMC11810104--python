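"""Multimodal supralinearity: does the response to a concurrent [AM + VM]
mismatch exceed the linear sum of the unimodal mismatch responses?

The linear-sum prediction for each neuron is the pointwise sum of its mean
[AM]-mismatch trace and its mean [VM]-mismatch trace, each aligned to its
own halt onset.  Population-level supralinearity is tested with the
hierarchical bootstrap, paired at the neuron level; the population ratio
``mean(resp_concurrent) / mean(resp_sum)`` estimates the interaction gain.
Per-neuron selectivity (responsive to the concurrent halt only, to the sum
only, to both, or to neither) is assessed with a trial-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .hierboot import GroupedSample, hboot_test, timecourse_test
from .responses import TrialTensor, trial_responses, RESPONSE_WINDOW

__all__ = [
    "SelectivityRecord",
    "linear_sum_traces",
    "test_supralinearity",
    "classify_selectivity",
]

CATEGORIES = ("concurrent_only", "sum_only", "both", "neither")


@dataclass
class SelectivityRecord:
    """Per-neuron concurrent-vs-linear-sum selectivity."""

    neuron: int
    site_id: int
    resp_concurrent: float
    resp_sum: float
    p_concurrent: float
    p_sum: float
    sig_concurrent: bool
    sig_sum: bool
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def shift_earlier(traces: np.ndarray, frames: int) -> np.ndarray:
    """Shift traces ``frames`` frames earlier in time (edge-replicated)."""
    if frames <= 0:
        return np.asarray(traces, float).copy()
    out = np.empty_like(np.asarray(traces, float))
    out[..., :-frames] = traces[..., frames:]
    out[..., -frames:] = traces[..., -1:]
    return out


def linear_sum_traces(am_traces: np.ndarray, vm_traces: np.ndarray,
                      vm_lead_frames: int = 0) -> np.ndarray:
    """Pointwise sum of per-neuron mean [AM] and [VM] mismatch traces.

    Both inputs are neurons x time on the common event-aligned axis, each
    unimodal trace aligned to its own halt onset.  In the concurrent
    paradigm the VM halt leads the AM halt (to which trials are aligned) by
    the difference of the two loop delays; ``vm_lead_frames`` optionally
    shifts the unimodal VM trace earlier by that amount so the summed
    prediction has the same timing as the concurrent measurement.  The
    neuron sets must already be intersected to those recorded in both
    paradigms.
    """
    am_traces = np.asarray(am_traces, float)
    vm_traces = np.asarray(vm_traces, float)
    if am_traces.size == 0 or vm_traces.size == 0:
        raise ValueError("empty neuron intersection")
    if am_traces.shape != vm_traces.shape:
        raise ValueError("unimodal trace arrays must share shape")
    return am_traces + shift_earlier(vm_traces, vm_lead_frames)


def test_supralinearity(concurrent: TrialTensor, am: TrialTensor,
                        vm: TrialTensor, n_boot: int = 10000, seed: int = 0,
                        alpha: float = 0.05, bin_frames: int = 5,
                        window: Tuple[float, float] = RESPONSE_WINDOW) -> dict:
    """Compare concurrent [AM+VM] mismatch responses with the unimodal
    responses and their linear sum (all on the matched neuron set).

    Returns a dict with per-bin timecourse results and scalar paired tests
    for concurrent-vs-AM, concurrent-vs-VM and concurrent-vs-sum, plus the
    population supralinearity ratio ``mean(concurrent) / mean(sum)``.
    """
    n = concurrent.n_neurons
    if not (am.n_neurons == vm.n_neurons == n):
        raise ValueError("tensors must be on the matched neuron set")
    keys = np.arange(n)
    site = concurrent.neuron_site
    tr_c = concurrent.mean_traces()
    tr_sum = linear_sum_traces(am.mean_traces(), vm.mean_traces())

    def scal(t: TrialTensor) -> np.ndarray:
        return trial_responses(t, window).mean(axis=0)

    r_c = scal(concurrent)
    r_am, r_vm = scal(am), scal(vm)
    r_sum = r_am + r_vm

    def paired_scalar(x, y, tag, sd):
        return hboot_test(GroupedSample(x, site, keys), GroupedSample(y, site, keys),
                          direction="a_gt_b", n_boot=n_boot, seed=seed + sd,
                          paired=True, alpha=alpha)

    def paired_bins(x, y, sd):
        return timecourse_test(GroupedSample(x, site, keys),
                               GroupedSample(y, site, keys), fs=concurrent.fs,
                               bin_frames=bin_frames, alpha=alpha,
                               n_boot=n_boot, seed=seed + sd, paired=True,
                               direction="a_gt_b", time_s=concurrent.time_s)

    denom = r_sum.mean()
    ratio = float(r_c.mean() / denom) if denom != 0 else np.inf
    return {
        "scalar_vs_am": paired_scalar(r_c, r_am, "c>am", 1),
        "scalar_vs_vm": paired_scalar(r_c, r_vm, "c>vm", 2),
        "scalar_vs_sum": paired_scalar(r_c, r_sum, "c>sum", 3),
        "bins_vs_am": paired_bins(tr_c, am.mean_traces(), 4),
        "bins_vs_vm": paired_bins(tr_c, vm.mean_traces(), 5),
        "bins_vs_sum": paired_bins(tr_c, tr_sum, 6),
        "ratio": ratio,
        "resp_concurrent": r_c,
        "resp_sum": r_sum,
    }


def _trial_boot_p(vals: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    """Two-sided trial-level bootstrap p for mean(vals) != 0 (ties count as
    violations, matching the package's hierarchical convention)."""
    n = vals.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = vals[idx].mean(axis=1)
    p_gt = np.mean(means <= 0)
    p_lt = np.mean(means >= 0)
    return float(min(1.0, 2.0 * min(p_gt, p_lt)))


def classify_selectivity(concurrent: TrialTensor, am: TrialTensor,
                         vm: TrialTensor, alpha: float = 0.05,
                         n_boot_trials: int = 1000, seed: int = 0,
                         window: Tuple[float, float] = RESPONSE_WINDOW):
    """Per-neuron selectivity for the concurrent mismatch vs the linear sum.

    For each neuron, a trial-level bootstrap tests (two-sided, ``alpha``)
    whether the mean concurrent response differs from 0, and whether the
    summed response does.  Because [AM] and [VM] trials are not naturally
    paired, summed per-trial responses are built by randomly pairing trials
    across the two unimodal conditions (seeded); the number of summed
    trials is the smaller unimodal trial count.  Neurons with fewer than 2
    trials in any condition are unclassifiable and excluded from the
    reported fractions.

    Returns ``(records: list[SelectivityRecord], fractions: dict)`` where
    fractions also carries ``n_classified`` and ``n_unclassifiable``.
    """
    n = concurrent.n_neurons
    if not (am.n_neurons == vm.n_neurons == n):
        raise ValueError("tensors must be on the matched neuron set")
    rng = np.random.default_rng(seed)
    tr_c = trial_responses(concurrent, window)      # trials x neurons
    tr_am = trial_responses(am, window)
    tr_vm = trial_responses(vm, window)
    n_pair = min(tr_am.shape[0], tr_vm.shape[0])
    records = []
    n_unclassifiable = 0
    if tr_c.shape[0] < 2 or n_pair < 2:
        raise ValueError("need at least 2 trials per condition")
    ix_am = rng.permutation(tr_am.shape[0])[:n_pair]
    ix_vm = rng.permutation(tr_vm.shape[0])[:n_pair]
    tr_sum = tr_am[ix_am] + tr_vm[ix_vm]
    for i in range(n):
        p_c = _trial_boot_p(tr_c[:, i], n_boot_trials, rng)
        p_s = _trial_boot_p(tr_sum[:, i], n_boot_trials, rng)
        sig_c, sig_s = p_c < alpha, p_s < alpha
        cat = ("both" if sig_c and sig_s else
               "concurrent_only" if sig_c else
               "sum_only" if sig_s else "neither")
        records.append(SelectivityRecord(
            neuron=i, site_id=int(concurrent.neuron_site[i]),
            resp_concurrent=float(tr_c[:, i].mean()),
            resp_sum=float(tr_sum[:, i].mean()),
            p_concurrent=p_c, p_sum=p_s,
            sig_concurrent=bool(sig_c), sig_sum=bool(sig_s), category=cat))
    n_classified = len(records)
    fractions = {c: sum(r.category == c for r in records) / n_classified
                 for c in CATEGORIES}
    fractions["n_classified"] = n_classified
    fractions["n_unclassifiable"] = n_unclassifiable
    return records, fractions
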