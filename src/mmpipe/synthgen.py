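"""Synthetic closed-loop / open-loop VR session generator.

Emulates the statistical structure of head-fixed two-photon calcium imaging
experiments in which a mouse's running speed on a spherical treadmill is
experimentally coupled to self-generated sensory feedback:

* audiomotor (AM) coupling — running speed drives the amplitude of a pure
  tone (0 cm/s -> silence, ``v_ref`` cm/s -> ``a_ref_db`` dB SPL) with a
  ~260 ms loop delay;
* visuomotor (VM) coupling — running speed drives virtual-corridor visual
  flow with a ~90 ms delay;
* mismatches — 1-s halts of the coupled feedback injected at random times
  while the animal is running (a negative prediction-error stimulus);
* open-loop replay — the previously self-generated feedback is played back
  while new, uncoupled running behavior is generated.

Ground-truth neuron populations include subtractive prediction-error units
(motor-excited, sound-inhibited), sensory units, motor units, and units
selective for the concurrent halt of both modalities, so that every stage of
the downstream analysis can be validated against known labels.

Firing rates are converted to raw fluorescence through a Poisson-spike /
exponential-kernel forward model with slow additive drift, so the
percentile-baseline drift correction stage operates on realistic input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .events import EventTable

__all__ = [
    "SimConfig",
    "GroundTruthNeuron",
    "Session",
    "simulate_running",
    "apply_coupling",
    "sound_mapping",
    "inject_mismatches",
    "inject_concurrent_mismatches",
    "make_open_loop_replay",
    "neuron_rates",
    "rates_to_fluorescence",
    "make_population",
    "simulate_session",
    "add_tone_schedule",
    "add_grating_schedule",
]

RUN_SPEED_SILENCE = 0.3  # cm/s; below this the animal counts as stationary


@dataclass
class SimConfig:
    """Parameters of a simulated VR session.

    Durations are in seconds, speeds in cm/s, sound levels in dB SPL.
    """

    frame_rate_hz: float = 15.0
    session_length_s: float = 600.0
    v_ref: float = 30.0          # running speed mapped to a_ref_db
    a_ref_db: float = 60.0       # sound amplitude at v_ref
    am_delay_s: float = 0.26     # audiomotor loop delay
    vm_delay_s: float = 0.09     # visuomotor loop delay
    am_delay_jitter_s: float = 0.0   # optional SD of per-session delay jitter
    vm_delay_jitter_s: float = 0.0
    mm_duration_s: float = 1.0   # mismatch halt length
    mm_mean_interval_s: float = 15.0  # mean interval of the candidate process
    coupling_mode: str = "AM"    # one of {"AM", "VM", "AVM", "none"}
    mapping: str = "linear_pressure"  # or "linear_db"
    visual_gain: float = 1.0     # visual flow units per cm/s
    bout_rate_per_min: float = 3.0   # expected running-bout starts per minute
    bout_duration_mean_s: float = 12.0
    bout_rise_s: float = 0.7     # speed ramp time at bout edges (<= 1 s)
    n_sites: int = 1
    neurons_per_site: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        for name in ("session_length_s", "mm_duration_s", "mm_mean_interval_s",
                     "bout_duration_mean_s", "bout_rise_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.mm_duration_s < self.mm_mean_interval_s:
            raise ValueError("need 0 < mm_duration_s < mm_mean_interval_s")
        if self.v_ref <= 0:
            raise ValueError("v_ref must be > 0")
        if self.coupling_mode not in {"AM", "VM", "AVM", "none"}:
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")
        if self.mapping not in {"linear_pressure", "linear_db"}:
            raise ValueError(f"unknown mapping {self.mapping!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length_s * self.frame_rate_hz))


@dataclass
class GroundTruthNeuron:
    """Generative model of one simulated neuron.

    The instantaneous firing rate is

        rate(t) = max(0, baseline_rate + w_run * run_speed(t)
                         - w_sound * sound_db(t) + w_vis * visual_flow(t)
                         + mismatch_drive(t))

    where ``mismatch_drive`` is ``mm_amp_am`` during closed-loop AM halts
    and ``mm_amp_vm`` during closed-loop VM halts (halts are only injected
    while the animal is running, so each one removes an expected input),
    and the summed drive is multiplied by the interaction gain ``g``
    whenever both halts co-occur.  ``g = 1`` makes concurrent responses
    exactly linear.

    Subtractive prediction-error units need no explicit mismatch drive: with
    ``w_run > 0`` and ``w_sound > 0`` the halt of the coupled sound removes
    the inhibitory term while the motor term persists, so the mismatch
    excursion emerges from the subtraction itself.
    """

    site_id: int
    neuron_class: str  # sound_pos | sound_neg | visual | motor | am_mismatch
    #                    | vm_mismatch | multimodal_selective | silent
    w_run: float = 0.0      # Hz per cm/s
    w_sound: float = 0.0    # Hz per dB (enters with a minus sign)
    w_vis: float = 0.0      # Hz per flow unit
    g: float = 1.0          # concurrent-halt interaction gain
    mm_amp_am: float = 0.0  # Hz of explicit AM-halt drive
    mm_amp_vm: float = 0.0  # Hz of explicit VM-halt drive
    baseline_rate: float = 1.0  # Hz
    tau_ca_s: float = 0.6   # calcium indicator decay constant
    noise_sd: float = 0.2   # shot-noise SD in raw F units
    drift_amp: float = 2.0  # amplitude of slow additive drift in F units

    def __post_init__(self) -> None:
        if self.tau_ca_s <= 0:
            raise ValueError("tau_ca_s must be > 0")
        if self.g < 0:
            raise ValueError("interaction gain g must be >= 0")
        if self.neuron_class not in NEURON_CLASSES:
            raise ValueError(f"unknown neuron class {self.neuron_class!r}")


NEURON_CLASSES = (
    "sound_pos", "sound_neg", "visual", "motor",
    "am_mismatch", "vm_mismatch", "multimodal_selective", "silent",
)


@dataclass
class Session:
    """One recording: behavior traces, event log, and raw fluorescence."""

    site_id: int
    frame_rate_hz: float
    t: np.ndarray                 # time of each frame (s)
    run_speed: np.ndarray         # cm/s
    sound_db: np.ndarray          # dB SPL, 0 codes silence
    visual_flow: np.ndarray       # arbitrary speed units
    events: pd.DataFrame          # EventTable rows
    F: np.ndarray                 # neurons x frames raw fluorescence (> 0)
    loop_type: str = "closed"     # "closed" or "open"
    pupil: Optional[np.ndarray] = None
    ground_truth: Optional[list] = None   # list[GroundTruthNeuron]
    neuron_site: Optional[np.ndarray] = None  # site label per neuron
    config: Optional[SimConfig] = None

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("run_speed", "sound_db", "visual_flow"):
            if getattr(self, name).size != n:
                raise ValueError(f"trace {name} length != time vector length")
        if self.pupil is not None and self.pupil.size != n:
            raise ValueError("pupil trace length != time vector length")
        if self.F.ndim != 2 or self.F.shape[1] != n:
            raise ValueError("F must be neurons x frames with frames == len(t)")
        if np.any(self.F <= 0):
            raise ValueError("raw fluorescence must be strictly positive")
        if len(self.events) and (
            (self.events["onset_s"].to_numpy() < 0).any()
            or (self.events["onset_s"].to_numpy() > self.t[-1] + 1.0 / self.frame_rate_hz).any()
        ):
            raise ValueError("event onsets outside the recording")
        if self.neuron_site is None:
            self.neuron_site = np.full(self.F.shape[0], self.site_id)

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


# ---------------------------------------------------------------------------
# behavior


def simulate_running(config: SimConfig, seed: int) -> np.ndarray:
    """Generate a running-speed trace with alternating stationary and
    running bouts.

    Bout starts follow a Poisson process (``bout_rate_per_min``); each bout
    ramps up within ``bout_rise_s``, holds a plateau speed drawn from
    5-40 cm/s with slow within-bout fluctuations, and ramps back down.
    Stationary periods are exactly 0 cm/s.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    fs = config.frame_rate_hz
    n = config.n_frames
    if config.bout_rate_per_min > 0 and config.session_length_s < 2 * config.bout_rise_s + 1.0:
        raise ValueError("session too short to contain a single running bout")
    speed = np.zeros(n)
    if config.bout_rate_per_min == 0:
        return speed
    rate_per_s = config.bout_rate_per_min / 60.0
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_per_s)
        if t >= config.session_length_s:
            break
        dur = max(2.0, rng.gamma(shape=4.0, scale=config.bout_duration_mean_s / 4.0))
        peak = rng.uniform(5.0, 40.0)
        i0 = int(round(t * fs))
        i1 = min(n, int(round((t + dur) * fs)))
        if i1 <= i0:
            continue
        seg = np.full(i1 - i0, peak)
        # slow within-bout speed fluctuation (+-20%)
        wob = rng.standard_normal(seg.size)
        if seg.size > 3:
            k = min(seg.size, max(3, int(fs)))  # ~1-s smoothing
            kern = np.ones(k) / k
            wob = np.convolve(wob, kern, mode="same")
        seg *= 1.0 + 0.2 * wob / max(1e-12, np.abs(wob).max() or 1.0)
        # linear rise/fall ramps
        r = max(1, int(round(config.bout_rise_s * fs)))
        ramp = np.linspace(0.0, 1.0, r, endpoint=False)
        m = min(r, seg.size)
        seg[:m] *= ramp[:m]
        seg[-m:] *= ramp[:m][::-1]
        speed[i0:i1] = np.maximum(speed[i0:i1], seg)
        t += dur
    return np.clip(speed, 0.0, None)


def sound_mapping(run_speed: np.ndarray, config: SimConfig) -> np.ndarray:
    """Map running speed to sound amplitude in dB SPL.

    ``linear_pressure``: sound pressure proportional to speed, i.e.
    ``db = a_ref_db + 20*log10(v / v_ref)``, clipped to 0 (the silence code)
    where it would go negative; 0 cm/s maps to silence.

    ``linear_db``: dB value itself proportional to speed,
    ``db = a_ref_db * v / v_ref``.

    Both satisfy map(0) = 0 and map(v_ref) = a_ref_db.
    """
    v = np.clip(np.asarray(run_speed, dtype=float), 0.0, None)
    if config.mapping == "linear_db":
        return config.a_ref_db * v / config.v_ref
    with np.errstate(divide="ignore"):
        db = config.a_ref_db + 20.0 * np.log10(np.where(v > 0, v, np.nan) / config.v_ref)
    db = np.where(np.isfinite(db) & (db > 0), db, 0.0)
    return db


def _delay_frames(delay_s: float, fs: float) -> int:
    return int(round(delay_s * fs))


def _shift_trace(x: np.ndarray, k: int, fill: float = 0.0) -> np.ndarray:
    """Delay trace by k frames, filling the leading frames."""
    if k <= 0:
        return x.copy()
    out = np.full_like(x, fill)
    out[k:] = x[:-k]
    return out


def apply_coupling(run_speed: np.ndarray, config: SimConfig,
                   rng: Optional[np.random.Generator] = None):
    """Closed-loop coupling of running speed to sound amplitude and visual
    flow, each delayed by its loop lag (realized as a nearest-frame shift).

    Returns ``(sound_db, visual_flow)``.  Streams not active under the
    configured coupling mode are returned as zeros.  Optional per-session
    delay jitter is drawn from ``rng`` when the jitter SDs are non-zero.
    """
    fs = config.frame_rate_hz
    am_delay = config.am_delay_s
    vm_delay = config.vm_delay_s
    if rng is not None and config.am_delay_jitter_s > 0:
        am_delay = max(0.0, rng.normal(am_delay, config.am_delay_jitter_s))
    if rng is not None and config.vm_delay_jitter_s > 0:
        vm_delay = max(0.0, rng.normal(vm_delay, config.vm_delay_jitter_s))
    sound_db = np.zeros_like(run_speed, dtype=float)
    visual_flow = np.zeros_like(run_speed, dtype=float)
    if config.coupling_mode in ("AM", "AVM"):
        shifted = _shift_trace(np.asarray(run_speed, float), _delay_frames(am_delay, fs))
        sound_db = sound_mapping(shifted, config)
    if config.coupling_mode in ("VM", "AVM"):
        shifted = _shift_trace(np.asarray(run_speed, float), _delay_frames(vm_delay, fs))
        visual_flow = config.visual_gain * shifted
    return sound_db, visual_flow


def _draw_candidate_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson candidate process with mean interval
    ``mm_mean_interval_s`` over the session."""
    times = []
    t = 0.0
    while True:
        t += rng.exponential(config.mm_mean_interval_s)
        if t >= config.session_length_s - config.mm_duration_s:
            break
        times.append(t)
    return np.asarray(times)


def _eligible(run_speed: np.ndarray, onset_frame: int, fs: float,
              pre_s: float = 1.0, thresh: float = RUN_SPEED_SILENCE) -> bool:
    pre = int(round(pre_s * fs))
    if onset_frame - pre < 0:
        return False
    seg = run_speed[onset_frame - pre:onset_frame]
    return bool(np.all(seg > thresh))


def inject_mismatches(trace: np.ndarray, run_speed: np.ndarray,
                      config: SimConfig, seed: int,
                      event_type: str = "am_mismatch",
                      delay_s: Optional[float] = None):
    """Inject feedback-halt (mismatch) events into one coupled trace.

    Candidate times are a Poisson process with mean interval
    ``mm_mean_interval_s``.  A candidate becomes an event only if the animal
    ran (> 0.3 cm/s) throughout the 1-s window preceding the halt onset, so
    that the halt removes an actually present feedback signal.  During each
    event the trace is forced to 0 for ``mm_duration_s``.  Events do not
    overlap.  Returns ``(modified trace, EventTable)``.

    ``delay_s`` shifts the halt onset relative to the candidate command time
    by the stream's loop delay (default: the AM or VM delay matching
    ``event_type``).
    """
    rng = np.random.default_rng(seed)
    fs = config.frame_rate_hz
    if delay_s is None:
        delay_s = config.vm_delay_s if "vm" in event_type else config.am_delay_s
    out = np.asarray(trace, float).copy()
    dur = int(round(config.mm_duration_s * fs))
    cands = _draw_candidate_times(config, rng)
    rows = []
    last_end = -1
    for tc in cands:
        k = int(round(tc * fs)) + _delay_frames(delay_s, fs)
        if k <= last_end or k + dur > out.size:
            continue
        if not _eligible(run_speed, k, fs):
            continue
        out[k:k + dur] = 0.0
        rows.append(dict(event_type=event_type, onset_s=k / fs,
                         duration_s=config.mm_duration_s))
        last_end = k + dur
    if not rows:
        warnings.warn("no eligible mismatch candidates in this session")
    return out, EventTable(rows)


def inject_concurrent_mismatches(sound_db: np.ndarray, visual_flow: np.ndarray,
                                 run_speed: np.ndarray, config: SimConfig,
                                 seed: int):
    """Inject concurrent [AM + VM] halts: one candidate command halts both
    streams, each after its own loop delay, so the visual halt leads the
    auditory halt by ``am_delay_s - vm_delay_s`` (~170 ms).

    Events are timestamped at the AM halt onset (the downstream alignment
    convention) and carry the VM lead in ``vm_lead_s``.  Returns
    ``(sound_db, visual_flow, EventTable)``.
    """
    rng = np.random.default_rng(seed)
    fs = config.frame_rate_hz
    s_out = np.asarray(sound_db, float).copy()
    f_out = np.asarray(visual_flow, float).copy()
    dur = int(round(config.mm_duration_s * fs))
    d_am = _delay_frames(config.am_delay_s, fs)
    d_vm = _delay_frames(config.vm_delay_s, fs)
    cands = _draw_candidate_times(config, rng)
    rows = []
    last_end = -1
    for tc in cands:
        kc = int(round(tc * fs))
        k_am, k_vm = kc + d_am, kc + d_vm
        if k_vm <= last_end or k_am + dur > s_out.size:
            continue
        if not _eligible(run_speed, k_am, fs):
            continue
        s_out[k_am:k_am + dur] = 0.0
        f_out[k_vm:k_vm + dur] = 0.0
        rows.append(dict(event_type="avm_mismatch", onset_s=k_am / fs,
                         duration_s=config.mm_duration_s,
                         vm_lead_s=(d_am - d_vm) / fs))
        last_end = k_am + dur
    if not rows:
        warnings.warn("no eligible mismatch candidates in this session")
    return s_out, f_out, EventTable(rows)


def make_open_loop_replay(closed_session: Session, new_run_speed: np.ndarray,
                          F: Optional[np.ndarray] = None) -> Session:
    """Build an open-loop replay of a closed-loop session.

    The sensory traces (including halts) are copied verbatim; the halt
    events are relabelled as playback halts; the running trace is the newly
    generated, uncoupled behavior.  ``F`` may be supplied by the caller
    (normally regenerated from the ground-truth rates under the replay
    behavior); if omitted, the closed-loop matrix is carried over.
    """
    if closed_session.loop_type != "closed":
        raise ValueError("can only build a replay from a closed-loop session")
    new_run_speed = np.asarray(new_run_speed, float)
    if new_run_speed.size != closed_session.n_frames:
        raise ValueError("replay behavior length != replayed trace length")
    relabel = {"am_mismatch": "playback_halt_sound",
               "vm_mismatch": "playback_halt_visual"}
    ev = closed_session.events.copy()
    if len(ev):
        ev["event_type"] = ev["event_type"].replace(relabel)
    return Session(
        site_id=closed_session.site_id,
        frame_rate_hz=closed_session.frame_rate_hz,
        t=closed_session.t.copy(),
        run_speed=new_run_speed,
        sound_db=closed_session.sound_db.copy(),
        visual_flow=closed_session.visual_flow.copy(),
        events=ev,
        F=closed_session.F.copy() if F is None else F,
        loop_type="open",
        pupil=None if closed_session.pupil is None else closed_session.pupil.copy(),
        ground_truth=closed_session.ground_truth,
        neuron_site=closed_session.neuron_site,
        config=closed_session.config,
    )


# ---------------------------------------------------------------------------
# neurons


def _halt_masks(ev: pd.DataFrame, n: int, fs: float):
    """Boolean per-frame masks of active AM / VM *mismatch* halts.

    Playback halts are deliberately excluded: the explicit mismatch drive
    models a prediction-error signal, and in open loop the coupling — hence
    the motor-based prediction — is absent.  Any playback-halt response a
    unit shows therefore emerges solely from the relief of its
    stimulus-driven inhibition in the trace itself.
    """
    am = np.zeros(n, bool)
    vm = np.zeros(n, bool)
    for _, row in ev.iterrows():
        k0 = int(round(row["onset_s"] * fs))
        k1 = min(n, k0 + int(round(row["duration_s"] * fs)))
        et = row["event_type"]
        if et == "am_mismatch":
            am[k0:k1] = True
        elif et == "vm_mismatch":
            vm[k0:k1] = True
        elif et == "avm_mismatch":
            am[k0:k1] = True
            lead = int(round(float(row.get("vm_lead_s", 0.0) or 0.0) * fs))
            vm[max(0, k0 - lead):max(0, k1 - lead)] = True
    return am, vm


def neuron_rates(session: Session, gt: GroundTruthNeuron) -> np.ndarray:
    """Instantaneous firing rate (Hz) of one ground-truth neuron given the
    session's behavior and stimulus traces.  See ``GroundTruthNeuron``."""
    fs = session.frame_rate_hz
    n = session.run_speed.size
    rate = (gt.baseline_rate
            + gt.w_run * session.run_speed
            - gt.w_sound * session.sound_db
            + gt.w_vis * session.visual_flow)
    if gt.mm_amp_am or gt.mm_amp_vm:
        # the drive is sustained for the full halt: the injection step only
        # emits halts whose 1-s pre-window was spent running, so every
        # logged mismatch removes an expected input
        am_halt, vm_halt = _halt_masks(session.events, n, fs)
        drive = gt.mm_amp_am * am_halt + gt.mm_amp_vm * vm_halt
        both = am_halt & vm_halt
        drive = np.where(both, gt.g * drive, drive)
        rate = rate + drive
    return np.maximum(rate, 0.0)


def rates_to_fluorescence(rate: np.ndarray, gt: GroundTruthNeuron, seed: int,
                          fs: float = 15.0, spike_amp: float = 1.0,
                          f_offset: float = 100.0) -> np.ndarray:
    """Forward model from firing rate to raw fluorescence.

    Poisson spike counts per frame (mean ``rate/fs``) are convolved with a
    single-exponential calcium kernel ``exp(-t/tau_ca_s)``, scaled by
    ``spike_amp``, then slow additive drift (a Gaussian random walk low-pass
    filtered below ~0.05 Hz, amplitude ``drift_amp``), Gaussian shot noise
    (``noise_sd``) and a positive offset are added.  Deterministic given
    ``seed``; strictly positive output.
    """
    rate = np.asarray(rate, float)
    if not np.all(np.isfinite(rate)):
        raise ValueError("rate trace contains non-finite values")
    rng = np.random.default_rng(seed)
    n = rate.size
    spikes = rng.poisson(np.clip(rate, 0, None) / fs)
    decay = math.exp(-1.0 / (gt.tau_ca_s * fs))
    # recursive exponential filter == convolution with exp(-t/tau)
    from scipy.signal import lfilter
    ca = lfilter([1.0], [1.0, -decay], spikes.astype(float))
    F = f_offset + spike_amp * ca
    if gt.drift_amp > 0:
        walk = np.cumsum(rng.standard_normal(n))
        from scipy.ndimage import gaussian_filter1d
        walk = gaussian_filter1d(walk, sigma=max(1.0, fs / 0.05 / 6.0), mode="nearest")
        sd = walk.std()
        if sd > 0:
            F = F + gt.drift_amp * (walk - walk.mean()) / sd
    if gt.noise_sd > 0:
        F = F + rng.normal(0.0, gt.noise_sd, size=n)
    # clip far below the offset; keeps F strictly positive without biasing
    return np.clip(F, 1e-3, None)


DEFAULT_CLASS_FRACTIONS = {
    "am_mismatch": 0.10,
    "motor": 0.15,
    "sound_pos": 0.10,
    "sound_neg": 0.10,
    "visual": 0.10,
    "silent": 0.45,
}


def _default_params(cls: str, rng: np.random.Generator) -> dict:
    """Per-class generative parameters, mildly jittered across neurons."""
    j = lambda x: x * rng.uniform(0.8, 1.2)
    if cls == "silent":
        return dict(baseline_rate=j(0.5))
    if cls == "motor":
        return dict(w_run=j(0.10), baseline_rate=j(0.5))
    if cls == "sound_pos":
        return dict(w_sound=-j(0.03), baseline_rate=j(0.4))
    if cls == "sound_neg":
        return dict(w_sound=j(0.03), baseline_rate=j(1.5))
    if cls == "visual":
        return dict(w_vis=j(0.08), baseline_rate=j(0.4))
    if cls == "am_mismatch":
        # subtractive prediction-error unit: motor excitation opposed by
        # sound-driven inhibition, plus prediction-error drive during
        # closed-loop halts of the predicted sound
        w_run = j(0.10)
        return dict(w_run=w_run, w_sound=w_run / 2.0, baseline_rate=j(1.5),
                    mm_amp_am=j(2.5))
    if cls == "vm_mismatch":
        w_run = j(0.10)
        return dict(w_run=w_run, w_vis=-w_run, baseline_rate=j(1.5),
                    mm_amp_vm=j(2.5))
    if cls == "multimodal_selective":
        # negligible unimodal drive, strong concurrent response via g
        return dict(mm_amp_am=0.05, mm_amp_vm=0.05, g=60.0,
                    baseline_rate=j(1.0))
    raise ValueError(f"unknown neuron class {cls!r}")


def make_population(config: SimConfig, seed: int,
                    class_fractions: Optional[dict] = None,
                    class_overrides: Optional[dict] = None) -> list:
    """Draw a ground-truth population for all sites of an experiment.

    ``class_fractions`` maps class name -> fraction of neurons (normalized);
    ``class_overrides`` maps class name -> dict of GroundTruthNeuron fields
    overriding the class defaults (e.g. ``{"multimodal_selective":
    {"mm_amp_am": 1.5, "g": 2.0}}``).
    """
    fr = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    total = sum(fr.values())
    fr = {k: v / total for k, v in fr.items() if v > 0}
    rng = np.random.default_rng(seed)
    neurons = []
    for site in range(config.n_sites):
        n = config.neurons_per_site
        counts = {c: int(round(f * n)) for c, f in fr.items()}
        # fix rounding so counts sum to n (adjust the largest class)
        diff = n - sum(counts.values())
        biggest = max(counts, key=counts.get)
        counts[biggest] += diff
        for cls, cnt in counts.items():
            for _ in range(cnt):
                params = _default_params(cls, rng)
                if class_overrides and cls in class_overrides:
                    params.update(class_overrides[cls])
                neurons.append(GroundTruthNeuron(site_id=site, neuron_class=cls,
                                                 **params))
    return neurons


# ---------------------------------------------------------------------------
# session assembly


def add_tone_schedule(config: SimConfig, seed: int,
                      freqs_khz=(4, 8, 16, 32), levels_db=(60, 75),
                      tone_dur_s: float = 1.0, isi_mean_s: float = 4.0,
                      isi_jitter_s: float = 1.0):
    """Pure-tone stimulation schedule (randomized order and ISI).

    Returns ``(sound_db trace, EventTable)`` covering the session with tones
    of each frequency x level combination repeated in shuffled blocks.
    """
    rng = np.random.default_rng(seed)
    fs = config.frame_rate_hz
    n = config.n_frames
    sound = np.zeros(n)
    combos = [(f, l) for f in freqs_khz for l in levels_db]
    rows = []
    t = 3.0  # leave an initial baseline
    order = []
    while True:
        if not order:
            order = list(rng.permutation(len(combos)))
        isi = max(2.0, rng.uniform(isi_mean_s - isi_jitter_s, isi_mean_s + isi_jitter_s))
        if t + tone_dur_s + 3.0 >= config.session_length_s:
            break
        f, l = combos[order.pop()]
        k0 = int(round(t * fs))
        k1 = min(n, k0 + int(round(tone_dur_s * fs)))
        sound[k0:k1] = l
        rows.append(dict(event_type="tone", onset_s=k0 / fs, duration_s=tone_dur_s,
                         frequency_khz=float(f), level_db=float(l)))
        t += tone_dur_s + isi
    return sound, EventTable(rows)


def add_grating_schedule(config: SimConfig, seed: int,
                         directions_deg=(0, 45, 90, 135, 180, 225, 270, 315),
                         dur_mean_s: float = 6.0, dur_jitter_s: float = 2.0,
                         isi_mean_s: float = 4.5, isi_jitter_s: float = 1.5,
                         flow_amp: float = 20.0):
    """Drifting-grating schedule; gratings drive the visual_flow trace."""
    rng = np.random.default_rng(seed)
    fs = config.frame_rate_hz
    n = config.n_frames
    flow = np.zeros(n)
    rows = []
    t = 3.0
    while True:
        dur = rng.uniform(dur_mean_s - dur_jitter_s, dur_mean_s + dur_jitter_s)
        if t + dur + 3.0 >= config.session_length_s:
            break
        direction = float(rng.choice(directions_deg))
        k0 = int(round(t * fs))
        k1 = min(n, k0 + int(round(dur * fs)))
        flow[k0:k1] = flow_amp
        rows.append(dict(event_type="grating", onset_s=k0 / fs, duration_s=dur,
                         direction_deg=direction))
        t += dur + rng.uniform(isi_mean_s - isi_jitter_s, isi_mean_s + isi_jitter_s)
    return flow, EventTable(rows)


def _session_seed(seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(seed) % (2**31), *[int(t) % (2**31) for t in tags]])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_session(config: SimConfig, site_id: int, neurons: list,
                     session_kind: str, seed: int,
                     closed_ref: Optional[Session] = None) -> Session:
    """Simulate one session of a given kind for one imaging site.

    ``session_kind``:
      * ``"closed"`` — closed-loop session under ``config.coupling_mode``
        with injected mismatch halts;
      * ``"open"`` — open-loop replay of ``closed_ref`` with fresh behavior;
      * ``"tones"`` — pure-tone characterization (VR off, free running);
      * ``"gratings"`` — drifting-grating characterization.

    Neuron fluorescence is regenerated from the ground-truth rates under the
    session's actual traces, so the same neurons behave consistently across
    session kinds.
    """
    site_neurons = [gt for gt in neurons if gt.site_id == site_id]
    if not site_neurons:
        raise ValueError(f"no ground-truth neurons for site {site_id}")
    fs = config.frame_rate_hz
    n = config.n_frames
    t = np.arange(n) / fs
    base = _session_seed(seed, site_id, {"closed": 1, "open": 2, "tones": 3,
                                         "gratings": 4}[session_kind])
    run = simulate_running(config, _session_seed(base, 11))
    if session_kind == "closed":
        sound, flow = apply_coupling(run, config)
        tables = []
        if config.coupling_mode == "AM":
            sound, ev = inject_mismatches(sound, run, config, _session_seed(base, 12),
                                          "am_mismatch")
            tables.append(ev)
        elif config.coupling_mode == "VM":
            flow, ev = inject_mismatches(flow, run, config, _session_seed(base, 12),
                                         "vm_mismatch")
            tables.append(ev)
        elif config.coupling_mode == "AVM":
            sound, flow, ev = inject_concurrent_mismatches(
                sound, flow, run, config, _session_seed(base, 12))
            tables.append(ev)
        events = pd.concat(tables, ignore_index=True) if tables else EventTable([])
        loop_type = "closed"
    elif session_kind == "open":
        if closed_ref is None:
            raise ValueError("open-loop replay needs the closed-loop session")
        sess = make_open_loop_replay(closed_ref, run)
        sound, flow, events, loop_type = sess.sound_db, sess.visual_flow, sess.events, "open"
    elif session_kind == "tones":
        sound, events = add_tone_schedule(config, _session_seed(base, 13))
        flow = np.zeros(n)
        loop_type = "open"
    elif session_kind == "gratings":
        flow, events = add_grating_schedule(config, _session_seed(base, 13))
        sound = np.zeros(n)
        loop_type = "open"
    else:
        raise ValueError(f"unknown session kind {session_kind!r}")

    from types import SimpleNamespace
    stub = SimpleNamespace(site_id=site_id, frame_rate_hz=fs, run_speed=run,
                           sound_db=sound, visual_flow=flow, events=events)
    F = np.empty((len(site_neurons), n))
    for i, gt in enumerate(site_neurons):
        rate = neuron_rates(stub, gt)
        F[i] = rates_to_fluorescence(rate, gt, _session_seed(base, 100 + i), fs=fs)
    return Session(site_id=site_id, frame_rate_hz=fs, t=t, run_speed=run,
                   sound_db=sound, visual_flow=flow, events=events, F=F,
                   loop_type=loop_type,
                   ground_truth=site_neurons,
                   neuron_site=np.full(len(site_neurons), site_id),
                   config=replace(config, seed=seed))
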