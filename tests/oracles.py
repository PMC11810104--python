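"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: each re-implements the
rule it checks in the most literal way possible (explicit loops, sort-and-
index percentiles, frame-by-frame rule evaluation).
"""

from __future__ import annotations

import numpy as np


def brute_percentile_baseline(x: np.ndarray, fs: float, window_s: float,
                              percentile: float) -> np.ndarray:
    """Sort-per-window percentile with a centered, edge-truncated window.

    Window length w = round(window_s * fs); for frame i the window covers
    [i - w//2, i + (w - w//2 - 1)], clipped to the trace.  Percentile by
    linear interpolation between order statistics.
    """
    n = x.size
    w = int(round(window_s * fs))
    before, after = w // 2, w - w // 2 - 1
    out = np.empty(n)
    for i in range(n):
        seg = np.sort(x[max(0, i - before): min(n, i + after + 1)])
        pos = percentile / 100.0 * (seg.size - 1)
        k = int(np.floor(pos))
        frac = pos - k
        out[i] = seg[k] + frac * (seg[min(k + 1, seg.size - 1)] - seg[k])
    return out


def brute_running_onsets(v: np.ndarray, fs: float, thresh: float = 3.0,
                         pre_window_s: float = 3.0,
                         pre_mean_max: float = 1.8) -> np.ndarray:
    """Frame-by-frame evaluation of the running-onset rule."""
    pre = int(round(pre_window_s * fs))
    out = []
    for t in range(pre, v.size):
        if v[t] >= thresh and v[t - 1] < thresh:
            if np.mean(v[t - pre:t]) < pre_mean_max:
                out.append(t / fs)
    return np.asarray(out)


def brute_inclusion_flags(events, session_length_s: float, fs: float,
                          run_speed=None, min_pre_s: float = 2.0,
                          min_post_s: float = 3.0,
                          min_events_per_session: int = 2):
    """Literal per-event evaluation of the trial inclusion rules.

    Returns a list of exclusion reasons (None = included), in the order of
    the events sorted by onset.
    """
    ev = events.sort_values("onset_s", kind="stable").reset_index(drop=True)
    reasons = []
    for _, row in ev.iterrows():
        t0 = float(row["onset_s"])
        if t0 < min_pre_s:
            reasons.append("insufficient_pre")
        elif t0 + min_post_s > session_length_s:
            reasons.append("insufficient_post")
        elif row["event_type"] == "running_onset" and run_speed is not None:
            k0 = int(round(t0 * fs))
            k1 = min(len(run_speed), k0 + int(round(fs)))
            if np.mean(run_speed[k0:k1]) < 3.0:
                reasons.append("short_bout")
            else:
                reasons.append(None)
        else:
            reasons.append(None)
    for etype in ev["event_type"].unique():
        ix = [i for i in range(len(ev)) if ev.iloc[i]["event_type"] == etype]
        ok = [i for i in ix if reasons[i] is None]
        if len(ok) < min_events_per_session:
            for i in ok:
                reasons[i] = "too_few_in_session"
    return reasons


def enumerate_two_neuron_boot(values=(0.0, 2.0)):
    """Exact enumeration of the hierarchical bootstrap for one site with two
    neurons: 4 equally likely neuron resamples -> distribution of means."""
    a, b = values
    means = [np.mean([x, y]) for x in (a, b) for y in (a, b)]
    vals, counts = np.unique(means, return_counts=True)
    return vals, counts / counts.sum()
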