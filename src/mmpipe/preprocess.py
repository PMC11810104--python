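"""Fluorescence preprocessing: percentile-baseline drift correction, ΔF/F,
and the widefield tonotopic-mapping variant.

ΔF/F is computed as ``(F - baseline(t)) / F0`` where ``baseline(t)`` is a
moving low-percentile (default 8th) estimate of the slow drift in a centered
window (default 66 s) and ``F0`` is the median of the raw trace.  The
percentile uses linear interpolation between order statistics (the numpy
default), and windows are truncated — not padded — at the recording edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DffMatrix",
    "percentile_baseline",
    "compute_dff",
    "widefield_dff_and_map",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class DffMatrix:
    """Drift-corrected ΔF/F traces with the parameters used to compute them."""

    dff: np.ndarray          # neurons x frames, dimensionless
    fs: float
    f0: np.ndarray           # per-neuron median raw fluorescence
    baseline_percentile: float
    window_s: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")
        if np.any(self.f0 <= 0):
            raise ValueError("f0 must be strictly positive")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@njit(cache=True)
def _rolling_percentile_sorted(x, w_before, w_after, q):  # pragma: no cover
    """Exact moving percentile via an incrementally maintained sorted buffer.

    Window for frame i is [i - w_before, i + w_after], truncated at the
    edges.  Percentile = linear interpolation between order statistics.
    """
    n = x.size
    out = np.empty(n)
    cap = w_before + w_after + 1
    buf = np.empty(cap)
    # initial window for i = 0
    hi = min(n - 1, w_after)
    m = hi + 1
    buf[:m] = np.sort(x[: m])
    for i in range(n):
        if i > 0:
            # element entering on the right
            enter = i + w_after
            if enter < n:
                v = x[enter]
                lo, hig = 0, m
                while lo < hig:
                    mid = (lo + hig) // 2
                    if buf[mid] < v:
                        lo = mid + 1
                    else:
                        hig = mid
                for j in range(m, lo, -1):
                    buf[j] = buf[j - 1]
                buf[lo] = v
                m += 1
            # element leaving on the left
            leave = i - w_before - 1
            if leave >= 0:
                v = x[leave]
                lo, hig = 0, m
                while lo < hig:
                    mid = (lo + hig) // 2
                    if buf[mid] < v:
                        lo = mid + 1
                    else:
                        hig = mid
                for j in range(lo, m - 1):
                    buf[j] = buf[j + 1]
                m -= 1
        pos = q / 100.0 * (m - 1)
        k = int(np.floor(pos))
        frac = pos - k
        if k + 1 < m:
            out[i] = buf[k] + frac * (buf[k + 1] - buf[k])
        else:
            out[i] = buf[m - 1]
    return out


def _rolling_percentile_numpy(x, w_before, w_after, q):
    """Plain-numpy fallback with identical conventions."""
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - w_before)
        hi = min(n, i + w_after + 1)
        out[i] = np.percentile(x[lo:hi], q)
    return out


def percentile_baseline(F_row: np.ndarray, fs: float, window_s: float = 66.0,
                        percentile: float = 8.0) -> np.ndarray:
    """Moving low-percentile estimate of the slow fluorescence drift.

    For every frame, the ``percentile``-th percentile of the raw trace
    within a centered window of ``round(window_s * fs)`` frames (truncated
    at the edges).  Output has the same length as the input.
    """
    x = np.ascontiguousarray(F_row, dtype=np.float64)
    if x.size < 2:
        raise ValueError("trace must have at least 2 frames")
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError("window shorter than one frame")
    w_before = w // 2
    w_after = w - w_before - 1
    if _HAVE_NUMBA:
        return _rolling_percentile_sorted(x, w_before, w_after, float(percentile))
    return _rolling_percentile_numpy(x, w_before, w_after, float(percentile))


def compute_dff(F: np.ndarray, fs: float, window_s: float = 66.0,
                percentile: float = 8.0) -> DffMatrix:
    """Drift-corrected ΔF/F for a neurons x frames fluorescence matrix.

    ``dff[i, t] = (F[i, t] - baseline_i(t)) / median_t(F[i, :])``; invariant
    under rescaling any neuron's trace by a positive constant.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if np.any(F <= 0):
        raise ValueError("raw fluorescence must be strictly positive")
    f0 = np.median(F, axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(f"non-positive median fluorescence for neuron(s) {bad.tolist()}")
    dff = np.empty_like(F)
    for i in range(F.shape[0]):
        base = percentile_baseline(F[i], fs, window_s, percentile)
        dff[i] = (F[i] - base) / f0[i]
    return DffMatrix(dff=dff, fs=fs, f0=f0, baseline_percentile=percentile,
                     window_s=window_s)


def widefield_dff_and_map(stack: np.ndarray, events: pd.DataFrame, fs: float,
                          window_s: float = 62.5, percentile: float = 8.0,
                          response_window=(0.2, 1.2), baseline_window=(-1.0, 0.0),
                          top_fraction: float = 0.05,
                          stim_column: str = "frequency_khz"):
    """Widefield mapping: per-pixel ΔF/F, per-stimulus mean responses, and a
    label map of the most responsive pixels.

    ``stack`` is pixels x frames.  Per-pixel ΔF/F uses the moving
    8th-percentile drift correction (62.5-s window) with the session median
    as F0.  For each stimulus value (e.g. tone frequency) the mean response
    in ``response_window`` minus the mean in ``baseline_window`` is averaged
    over that stimulus's events.  Pixels in the top ``top_fraction`` of any
    stimulus's response distribution are labelled with their argmax
    stimulus; all other pixels get -1.

    Returns ``(responses: stim -> per-pixel array, labels: int array)``.
    """
    stack = np.atleast_2d(np.asarray(stack, float))
    dffm = compute_dff(stack, fs, window_s=window_s, percentile=percentile)
    dff = dffm.dff
    n_px, n_frames = dff.shape
    stims = [s for s in pd.unique(events[stim_column]) if np.isfinite(s)]
    responses = {}
    for stim in stims:
        sel = events[events[stim_column] == stim]
        acc = np.zeros(n_px)
        count = 0
        for _, row in sel.iterrows():
            k = int(round(row["onset_s"] * fs))
            r0, r1 = (k + int(round(w * fs)) for w in response_window)
            b0, b1 = (k + int(round(w * fs)) for w in baseline_window)
            if b0 < 0 or r1 > n_frames:
                continue
            acc += dff[:, r0:r1].mean(axis=1) - dff[:, b0:b1].mean(axis=1)
            count += 1
        if count == 0:
            warnings.warn(f"no usable events for stimulus {stim}; skipped")
            continue
        responses[stim] = acc / count
    labels = np.full(n_px, -1, dtype=int)
    if responses:
        resp_mat = np.stack([responses[s] for s in responses])  # stims x pixels
        order = list(responses)
        in_top = np.zeros(n_px, bool)
        for r in resp_mat:
            thresh = np.quantile(r, 1.0 - top_fraction)
            in_top |= r > thresh
        argmax = np.argmax(resp_mat, axis=0)
        labels[in_top] = argmax[in_top]  # index into list(responses)
    return responses, labels
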