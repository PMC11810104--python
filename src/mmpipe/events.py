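"""Event detection, locomotion-state classification and trial inclusion.

Conventions used throughout the package: all windows are half-open
``[start, end)`` at frame resolution; frame ``k`` covers time
``[k/fs, (k+1)/fs)``.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "EventTable",
    "detect_running_onsets",
    "classify_trial_state",
    "apply_inclusion_rules",
]

EVENT_COLUMNS = [
    "event_type", "onset_s", "duration_s", "state", "included",
    "exclusion_reason", "frequency_khz", "level_db", "direction_deg",
    "vm_lead_s",
]

KNOWN_EVENT_TYPES = {
    "tone", "grating", "am_mismatch", "vm_mismatch", "avm_mismatch",
    "playback_halt_sound", "playback_halt_visual", "running_onset",
}


def EventTable(rows: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Normalize event rows to the canonical event-table schema.

    Missing columns are filled (state "n/a", included True); unknown event
    types are kept but warned about.
    """
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            if col == "state":
                df[col] = "n/a"
            elif col == "included":
                df[col] = True
            else:
                df[col] = np.nan
    df = df[EVENT_COLUMNS + [c for c in df.columns if c not in EVENT_COLUMNS]]
    if len(df):
        unknown = set(df["event_type"]) - KNOWN_EVENT_TYPES
        if unknown:
            warnings.warn(f"unknown event types kept as-is: {sorted(unknown)}")
        if (df["onset_s"] < 0).any():
            raise ValueError("event onsets must be >= 0")
        bad = df["included"].eq(False) & df["exclusion_reason"].isna()
        if bad.any():
            raise ValueError("excluded events must carry an exclusion_reason")
    return df.reset_index(drop=True)


def detect_running_onsets(run_speed: np.ndarray, fs: float,
                          thresh: float = 3.0, pre_window_s: float = 3.0,
                          pre_mean_max: float = 1.8) -> np.ndarray:
    """Detect running onsets: the first frame at or above ``thresh`` cm/s
    (previous frame below) where the mean speed over the preceding
    ``pre_window_s`` is below ``pre_mean_max`` cm/s.

    Onsets within the first ``pre_window_s`` of the recording are
    ineligible.  Returns sorted onset times in seconds.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    v = np.asarray(run_speed, float)
    pre = int(round(pre_window_s * fs))
    if v.size < pre:
        raise ValueError("trace shorter than the pre-window")
    cross = (v[1:] >= thresh) & (v[:-1] < thresh)
    idx = np.flatnonzero(cross) + 1
    idx = idx[idx >= pre]
    if idx.size == 0:
        return np.empty(0)
    # half-open pre-window [t - pre_window, t)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    pre_means = (csum[idx] - csum[idx - pre]) / pre
    return idx[pre_means < pre_mean_max] / fs


def classify_trial_state(run_speed: np.ndarray, onset_s: float, fs: float,
                         window_s: float = 1.0, thresh: float = 0.3) -> str:
    """Classify the locomotion state at a stimulus onset.

    ``running`` iff the mean speed over the 1-s half-open window preceding
    the onset is strictly greater than ``thresh`` cm/s, else ``sitting``.
    Onsets earlier than one window into the recording get state ``n/a``.
    """
    v = np.asarray(run_speed, float)
    k = int(round(onset_s * fs))
    w = int(round(window_s * fs))
    if k - w < 0:
        warnings.warn(f"onset at {onset_s:.2f}s precedes the first full "
                      "state window; state set to n/a")
        return "n/a"
    return "running" if v[k - w:k].mean() > thresh else "sitting"


def apply_inclusion_rules(events: pd.DataFrame, session_length_s: float,
                          fs: float, min_pre_s: float = 2.0,
                          min_post_s: float = 3.0,
                          min_events_per_session: int = 2,
                          run_speed: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Flag events that do not satisfy the trial inclusion rules.

    An event is excluded (``included=False`` with a reason) if it is not
    preceded by at least ``min_pre_s`` of recording (``insufficient_pre``),
    not followed by at least ``min_post_s`` (``insufficient_post``), or if
    fewer than ``min_events_per_session`` events of its type survive in the
    session (``too_few_in_session``).  Running-onset events additionally
    require the animal to keep running (mean speed >= 3 cm/s) for 1 s after
    the onset (``short_bout``); this check needs ``run_speed``.
    """
    ev = EventTable(events)
    if not ev["onset_s"].is_monotonic_increasing:
        ev = ev.sort_values("onset_s", kind="stable").reset_index(drop=True)
    onsets = ev["onset_s"].to_numpy(float)
    reasons = np.full(len(ev), None, dtype=object)
    reasons[onsets + min_post_s > session_length_s] = "insufficient_post"
    reasons[onsets < min_pre_s] = "insufficient_pre"
    if run_speed is not None:
        is_onset = (ev["event_type"] == "running_onset").to_numpy()
        for i in np.flatnonzero(is_onset & (reasons == None)):  # noqa: E711
            k0 = int(round(onsets[i] * fs))
            k1 = min(run_speed.size, k0 + int(round(1.0 * fs)))
            if np.mean(run_speed[k0:k1]) < 3.0:
                reasons[i] = "short_bout"
    # trial-count rule, applied per event type over the survivors
    types = ev["event_type"].to_numpy()
    for etype in pd.unique(types):
        sel = (types == etype) & (reasons == None)  # noqa: E711
        if sel.sum() < min_events_per_session:
            reasons[sel] = "too_few_in_session"
    ev["included"] = [r is None for r in reasons]
    ev["exclusion_reason"] = [r if r is not None else np.nan for r in reasons]
    return ev
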