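"""Event-aligned trial tensors and scalar response quantification.

Responses are quantified on baseline-subtracted ΔF/F snippets aligned to
stimulus / mismatch / running onsets: each trial's per-neuron mean over the
[-0.5, 0) s pre-onset window is subtracted, and the scalar response is the
mean over the 0.5-2.5 s post-onset window.  Windows are realized as frames
whose centers fall inside the half-open window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .hierboot import GroupedSample, hboot_test, BootstrapResult
from .preprocess import DffMatrix

__all__ = [
    "TrialTensor",
    "ResponseTable",
    "align_trials",
    "trial_responses",
    "response_scalar",
    "split_half_order",
    "select_top_responders",
    "openloop_correlations",
    "behavioral_control",
]

BASELINE_WINDOW = (-0.5, 0.0)
RESPONSE_WINDOW = (0.5, 2.5)


def _window_frames(window: Tuple[float, float], fs: float,
                   offsets: np.ndarray) -> np.ndarray:
    """Indices into ``offsets`` of frames whose centers lie in [w0, w1)."""
    centers = (offsets + 0.5) / fs
    return np.flatnonzero((centers >= window[0]) & (centers < window[1]))


@dataclass
class TrialTensor:
    """trials x neurons x time array of baseline-subtracted ΔF/F snippets."""

    data: np.ndarray
    time_s: np.ndarray            # frame centers relative to onset
    fs: float
    alignment_event: str
    trial_meta: pd.DataFrame      # one row per trial (onset_s, state, ...)
    neuron_site: np.ndarray       # site label per neuron

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("tensor must be trials x neurons x time")
        if self.data.shape[2] != self.time_s.size:
            raise ValueError("time axis length mismatch")
        base = _window_frames(BASELINE_WINDOW, self.fs,
                              np.round(self.time_s * self.fs - 0.5).astype(int))
        if base.size and self.data.shape[0]:
            resid = np.abs(self.data[:, :, base].mean(axis=2)).max()
            if resid > 1e-9:
                raise ValueError("baseline window mean is not zero after subtraction")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.data.shape[1]

    def mean_traces(self) -> np.ndarray:
        """Per-neuron mean trace over trials (neurons x time)."""
        return self.data.mean(axis=0)

    def grouped_mean_traces(self) -> GroupedSample:
        return GroupedSample(self.mean_traces(), self.neuron_site,
                             keys=np.arange(self.n_neurons))


@dataclass
class ResponseTable:
    """Per-neuron scalar responses for one condition."""

    response: np.ndarray      # mean over trials of windowed means
    n_trials: int
    site_id: np.ndarray
    window: Tuple[float, float] = RESPONSE_WINDOW
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("a condition needs at least 2 trials")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite responses")

    def grouped(self) -> GroupedSample:
        return GroupedSample(self.response, self.site_id,
                             keys=np.arange(self.response.size))


def align_trials(dff: DffMatrix, events: pd.DataFrame,
                 window: Tuple[float, float] = (-2.0, 5.0),
                 baseline: Tuple[float, float] = BASELINE_WINDOW,
                 neuron_site: Optional[np.ndarray] = None,
                 alignment_event: str = "") -> TrialTensor:
    """Extract event-aligned, baseline-subtracted ΔF/F snippets.

    Only included events are used.  Time 0 is the event onset; for
    concurrent [AM+VM] events the logged onset is the AM halt onset (the VM
    halt leads it by the difference of the two loop delays).  Trials whose
    window exceeds the recording are dropped with a warning.
    """
    fs = dff.fs
    ev = events[events["included"].astype(bool)] if "included" in events else events
    offsets = np.arange(int(round(window[0] * fs)), int(round(window[1] * fs)))
    time_s = (offsets + 0.5) / fs
    base_ix = _window_frames(baseline, fs, offsets)
    n_frames = dff.n_frames
    snippets, rows = [], []
    for _, row in ev.iterrows():
        k = int(round(row["onset_s"] * fs))
        lo, hi = k + offsets[0], k + offsets[-1] + 1
        if lo < 0 or hi > n_frames:
            warnings.warn(f"event at {row['onset_s']:.2f}s window exceeds the "
                          "recording; trial dropped")
            continue
        snip = dff.dff[:, lo:hi]
        snip = snip - snip[:, base_ix].mean(axis=1, keepdims=True)
        snippets.append(snip)
        rows.append(row)
    data = (np.stack(snippets) if snippets
            else np.empty((0, dff.n_neurons, offsets.size)))
    meta = pd.DataFrame(rows).reset_index(drop=True)
    if neuron_site is None:
        neuron_site = np.zeros(dff.n_neurons, dtype=int)
    return TrialTensor(data=data, time_s=time_s, fs=fs,
                       alignment_event=alignment_event or
                       (str(meta["event_type"].iloc[0]) if len(meta) else ""),
                       trial_meta=meta, neuron_site=np.asarray(neuron_site))


def trial_responses(tensor: TrialTensor,
                    window: Tuple[float, float] = RESPONSE_WINDOW) -> np.ndarray:
    """Per-trial windowed-mean responses (trials x neurons)."""
    offsets = np.round(tensor.time_s * tensor.fs - 0.5).astype(int)
    ix = _window_frames(window, tensor.fs, offsets)
    if ix.size == 0:
        raise ValueError("response window contains no frames")
    return tensor.data[:, :, ix].mean(axis=2)


def response_scalar(tensor: TrialTensor,
                    window: Tuple[float, float] = RESPONSE_WINDOW,
                    condition: str = "") -> ResponseTable:
    """Per-neuron scalar response: mean over trials of the mean ΔF/F over
    the response window."""
    if tensor.n_trials == 0:
        raise ValueError("empty trial set")
    per_trial = trial_responses(tensor, window)
    return ResponseTable(response=per_trial.mean(axis=0),
                         n_trials=tensor.n_trials, site_id=tensor.neuron_site,
                         window=window, condition=condition or tensor.alignment_event)


def split_half_order(tensor: TrialTensor, smooth_neurons: int = 10,
                     window: Tuple[float, float] = RESPONSE_WINDOW):
    """Split trials into interleaved halves; order neurons by the response
    in one half and return the other half's mean traces in that order.

    Interleaved (odd/even trial) halves cancel slow drift between the two
    halves.  The displayed matrix is boxcar-smoothed over ``smooth_neurons``
    adjacent neurons in sorted order, which avoids graphical aliasing, and
    the split avoids regression-to-the-mean bias in the displayed half.

    Returns ``(order, heatmap, resp_half1, resp_half2)``.
    """
    if tensor.n_trials < 2:
        raise ValueError("need at least 2 trials to split")
    half1 = np.arange(0, tensor.n_trials, 2)
    half2 = np.arange(1, tensor.n_trials, 2)
    per_trial = trial_responses(tensor, window)
    resp1 = per_trial[half1].mean(axis=0)
    resp2 = per_trial[half2].mean(axis=0)
    order = np.argsort(-resp1, kind="stable")
    heat = tensor.data[half2].mean(axis=0)[order]
    if smooth_neurons > 1 and heat.shape[0] > 1:
        heat = uniform_filter1d(heat, size=smooth_neurons, axis=0, mode="nearest")
    return order, heat, resp1, resp2


def select_top_responders(responses: ResponseTable, fraction: float = 0.05,
                          by: str = "absolute") -> np.ndarray:
    """Indices of the ``ceil(fraction * N)`` neurons with the largest
    absolute (or signed) scalar response; ties broken by neuron index."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if by not in ("absolute", "signed"):
        raise ValueError("by must be 'absolute' or 'signed'")
    r = responses.response
    n_sel = int(np.ceil(fraction * r.size))
    if r.size < int(np.ceil(1.0 / fraction)):
        raise ValueError("too few neurons for this selection fraction")
    key = np.abs(r) if by == "absolute" else r
    order = np.argsort(-key, kind="stable")
    return np.sort(order[:n_sel])


def openloop_correlations(dff: DffMatrix, session) -> pd.DataFrame:
    """Per-neuron Pearson correlations of ΔF/F with the open-loop stimulus
    trace and with running speed, over all frames, with no lag compensation.

    Returns a DataFrame with columns ``r_stim`` (sound amplitude or visual
    flow, whichever the session replays) and ``r_run``; zero-variance
    regressors yield NaN.
    """
    if session.loop_type != "open":
        raise ValueError("open-loop correlations need an open-loop session")
    if np.ptp(session.sound_db) > 0:
        stim = session.sound_db
    else:
        stim = session.visual_flow
    out = {}
    for name, reg in (("r_stim", stim), ("r_run", session.run_speed)):
        sd = np.std(reg)
        if sd == 0:
            warnings.warn(f"zero-variance regressor for {name}; reported NaN")
            out[name] = np.full(dff.n_neurons, np.nan)
            continue
        z = (reg - reg.mean()) / sd
        d = dff.dff
        dz = d - d.mean(axis=1, keepdims=True)
        denom = d.std(axis=1) * z.size
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = (dz @ z) / np.where(denom > 0, denom, np.nan)
    return pd.DataFrame(out)


def behavioral_control(trace: np.ndarray, events: pd.DataFrame, fs: float,
                       response: Tuple[float, float] = (0.5, 1.0),
                       baseline: Tuple[float, float] = BASELINE_WINDOW,
                       site_per_event: Optional[np.ndarray] = None,
                       n_boot: int = 10000, seed: int = 0) -> BootstrapResult:
    """Test whether a behavioral trace (running speed or pupil) changes at
    mismatch presentation.

    Per trial, the mean of the trace over ``response`` (0.5-1 s after
    onset) minus the mean over ``baseline`` (-0.5-0 s); the per-trial
    differences are tested against zero with the hierarchical bootstrap
    (sites -> trials; one nominal site unless ``site_per_event`` given).
    """
    ev = events[events["included"].astype(bool)] if "included" in events else events
    if len(ev) == 0:
        raise ValueError("no included events for the behavioral control")
    trace = np.asarray(trace, float)
    diffs, sites = [], []
    site_arr = (np.zeros(len(ev), int) if site_per_event is None
                else np.asarray(site_per_event))
    for (ix, (_, row)) in enumerate(ev.iterrows()):
        k = int(round(row["onset_s"] * fs))
        r0, r1 = (k + int(round(w * fs)) for w in response)
        b0, b1 = (k + int(round(w * fs)) for w in baseline)
        if b0 < 0 or r1 > trace.size:
            continue
        diffs.append(trace[r0:r1].mean() - trace[b0:b1].mean())
        sites.append(site_arr[ix])
    sample = GroupedSample(np.asarray(diffs), np.asarray(sites))
    return hboot_test(sample, None, direction="two_sided", n_boot=n_boot,
                      seed=seed)
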