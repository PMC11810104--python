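"""End-to-end analysis presets over simulated (or loaded) session bundles.

Each preset mirrors one figure-level analysis:

* ``fig1_sensory`` — population responses to pure tones, drifting gratings
  and running onsets, with split-half ordered heatmaps;
* ``fig2_am`` — audiomotor mismatch: mismatch vs playback-halt timecourse,
  top-responder characterization (sound suppression, running-onset
  excitation, open-loop correlation quadrant), closed vs open loop running
  onsets, behavioral control;
* ``fig3_vm`` — the same logic for visuomotor mismatch on a population
  without visual drive (the negative control);
* ``fig4_avm`` — concurrent [AM+VM] mismatch vs the linear sum of the
  unimodal responses, with per-neuron selectivity classification;
* ``calibration`` — type-I error and power of the hierarchical bootstrap.

Every preset is deterministic given its seed: the global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence`` so stages can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import calibration as cal
from .events import EventTable, apply_inclusion_rules, classify_trial_state, \
    detect_running_onsets
from .hierboot import GroupedSample, hboot_test, timecourse_test
from .nonlinearity import classify_selectivity, linear_sum_traces
from .preprocess import compute_dff
from .responses import (align_trials, openloop_correlations,
                        select_top_responders, split_half_order,
                        trial_responses, TrialTensor)
from .synthgen import SimConfig, make_population, simulate_session

__all__ = ["RunConfig", "run_preset", "simulate_experiment", "stage_seed"]

PRESETS = ("fig1_sensory", "fig2_am", "fig3_vm", "fig4_avm", "calibration")

# populations used by the presets; fractions are normalized
POPULATIONS = {
    "fig1_sensory": None,                      # module default mixture
    "fig2_am": None,
    "fig3_vm": {"motor": 0.15, "sound_pos": 0.10, "sound_neg": 0.10,
                "silent": 0.65},               # no visual drive at all
    "fig4_avm": {"multimodal_selective": 0.60, "motor": 0.10, "silent": 0.30},
}

PRESET_KINDS = {
    "fig1_sensory": ("tones", "gratings"),
    "fig2_am": ("closed", "open", "tones"),
    "fig3_vm": ("closed", "open", "gratings"),
    "fig4_avm": ("closed",),
}


@dataclass
class RunConfig:
    """Configuration of one preset run (defaults echo the analysis
    parameters used throughout the package)."""

    preset: str = "fig2_am"
    seed: int = 0
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        n_sites=5, neurons_per_site=40))
    n_boot: int = 1000
    alpha: float = 0.05
    top_fraction: float = 0.05
    bin_frames: int = 5
    align_window: tuple = (-2.0, 5.0)
    response_window: tuple = (0.5, 2.5)
    late_window: tuple = (2.0, 4.0)
    interaction_gain: float = 2.0      # g for fig4 multimodal populations
    mm_amp: float = 1.5                # unimodal mismatch drive (Hz) for fig4
    lag_compensation: bool = True      # timing-match the VM trace in the sum
    class_fractions: Optional[dict] = None
    class_overrides: Optional[dict] = None
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")


def stage_seed(seed: int, *tags) -> int:
    """Deterministic per-stage child seed (tags may be ints or strings)."""
    ints = []
    for t in tags:
        if isinstance(t, str):
            import zlib
            ints.append(zlib.crc32(t.encode()) % (2**31))
        else:
            ints.append(int(t) % (2**31))
    ss = np.random.SeedSequence([int(seed) % (2**31), *ints])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# experiment assembly


def simulate_experiment(sim: SimConfig, seed: int, kinds,
                        class_fractions: Optional[dict] = None,
                        class_overrides: Optional[dict] = None) -> dict:
    """Simulate the session kinds of one experiment for every imaging site,
    with one shared ground-truth population."""
    neurons = make_population(sim, stage_seed(seed, "population"),
                              class_fractions, class_overrides)
    sites = {}
    for site in range(sim.n_sites):
        per = {}
        closed_ref = None
        for kind in kinds:
            per[kind] = simulate_session(sim, site, neurons, kind,
                                         stage_seed(seed, "sessions"),
                                         closed_ref=closed_ref)
            if kind == "closed":
                closed_ref = per[kind]
        sites[site] = per
    return {"neurons": neurons, "sites": sites, "sim": sim}


def _included_events(session, event_types=None) -> pd.DataFrame:
    ev = apply_inclusion_rules(session.events,
                               session.t[-1] + 1.0 / session.frame_rate_hz,
                               session.frame_rate_hz,
                               run_speed=session.run_speed)
    if event_types is not None:
        ev = ev[ev["event_type"].isin(event_types)]
    return ev[ev["included"].astype(bool)]


def _onset_events(session) -> pd.DataFrame:
    """Detected running onsets as an included-only event table."""
    onsets = detect_running_onsets(session.run_speed, session.frame_rate_hz)
    rows = [dict(event_type="running_onset", onset_s=float(t), duration_s=1.0,
                 state=classify_trial_state(session.run_speed, t,
                                            session.frame_rate_hz))
            for t in onsets]
    ev = apply_inclusion_rules(EventTable(rows),
                               session.t[-1] + 1.0 / session.frame_rate_hz,
                               session.frame_rate_hz,
                               run_speed=session.run_speed)
    return ev[ev["included"].astype(bool)]


def _site_tensor(session, dffm, events, window, alignment="") -> TrialTensor:
    return align_trials(dffm, events, window=window,
                        neuron_site=np.full(dffm.n_neurons, session.site_id),
                        alignment_event=alignment)


def _concat_traces(tensors) -> GroupedSample:
    """Concatenate per-site per-neuron mean traces into one grouped sample
    (keys = global neuron index)."""
    traces = np.concatenate([t.mean_traces() for t in tensors], axis=0)
    sites = np.concatenate([t.neuron_site for t in tensors])
    return GroupedSample(traces, sites, keys=np.arange(traces.shape[0]))


def _concat_scalars(tensors, window) -> GroupedSample:
    vals = np.concatenate([trial_responses(t, window).mean(axis=0)
                           for t in tensors])
    sites = np.concatenate([t.neuron_site for t in tensors])
    return GroupedSample(vals, sites, keys=np.arange(vals.size))


def _quadrant_stats(corrs: pd.DataFrame, selected: np.ndarray) -> dict:
    """Quadrant occupancy of selected neurons vs the full population.

    Quadrants of the (r_stim, r_run) plane; the mismatch-neuron prediction
    is the upper-left quadrant (r_stim < 0, r_run > 0).  The chi-square
    test compares the selected neurons' quadrant counts with the
    proportions of the full population (i.e. against selection being
    random with respect to the correlations).
    """
    r_stim = corrs["r_stim"].to_numpy()
    r_run = corrs["r_run"].to_numpy()
    quad = (r_stim < 0).astype(int) * 2 + (r_run > 0).astype(int)
    # 3 = upper-left (stim negative, run positive)
    pop_counts = np.bincount(quad, minlength=4).astype(float)
    pop_props = pop_counts / pop_counts.sum()
    sel_counts = np.bincount(quad[selected], minlength=4).astype(float)
    n_sel = sel_counts.sum()
    keep = pop_props > 0
    chi2, chi2_p = sps.chisquare(sel_counts[keep],
                                 f_exp=pop_props[keep] * n_sel)
    sel_frac_ul = float(sel_counts[3] / n_sel) if n_sel else np.nan
    return {
        "selected_fraction_upper_left": sel_frac_ul,
        "population_fraction_upper_left": float(pop_props[3]),
        "enrichment_upper_left": float(sel_frac_ul / pop_props[3])
        if pop_props[3] > 0 else np.inf,
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
    }


# ---------------------------------------------------------------------------
# presets


def _mismatch_preset(cfg: RunConfig, coupling: str) -> dict:
    """Shared logic of the fig2 (AM) and fig3 (VM) presets."""
    sim = dataclasses.replace(cfg.sim, coupling_mode=coupling)
    char_kind = "tones" if coupling == "AM" else "gratings"
    mm_type = "am_mismatch" if coupling == "AM" else "vm_mismatch"
    halt_type = ("playback_halt_sound" if coupling == "AM"
                 else "playback_halt_visual")
    fractions = cfg.class_fractions
    if fractions is None:
        fractions = POPULATIONS["fig2_am" if coupling == "AM" else "fig3_vm"]
    exp = simulate_experiment(sim, stage_seed(cfg.seed, "sim"),
                              ("closed", "open", char_kind), fractions,
                              cfg.class_overrides)
    mm_t, halt_t, char_t = [], [], []
    on_closed_t, on_open_t = [], []
    corr_frames = []
    behav_diffs = []
    for site, per in exp["sites"].items():
        d_closed = compute_dff(per["closed"].F, sim.frame_rate_hz)
        d_open = compute_dff(per["open"].F, sim.frame_rate_hz)
        d_char = compute_dff(per[char_kind].F, sim.frame_rate_hz)
        mm_t.append(_site_tensor(per["closed"], d_closed,
                                 _included_events(per["closed"], [mm_type]),
                                 cfg.align_window, mm_type))
        halt_t.append(_site_tensor(per["open"], d_open,
                                   _included_events(per["open"], [halt_type]),
                                   cfg.align_window, halt_type))
        char_t.append(_site_tensor(per[char_kind], d_char,
                                   _included_events(per[char_kind]),
                                   cfg.align_window, char_kind))
        on_closed_t.append(_site_tensor(per["closed"], d_closed,
                                        _onset_events(per["closed"]),
                                        cfg.align_window, "running_onset"))
        on_open_t.append(_site_tensor(per["open"], d_open,
                                      _onset_events(per["open"]),
                                      cfg.align_window, "running_onset"))
        corr_frames.append(openloop_correlations(d_open, per["open"]))
        behav_diffs.append((per["closed"].run_speed,
                            _included_events(per["closed"], [mm_type]), site))

    mm_traces = _concat_traces(mm_t)
    halt_traces = _concat_traces(halt_t)
    w = cfg.response_window
    mm_resp = _concat_scalars(mm_t, w)
    char_resp = _concat_scalars(char_t, w)
    onset_resp_open = _concat_scalars(on_open_t, w)
    late_closed = _concat_scalars(on_closed_t, cfg.late_window)
    late_open = _concat_scalars(on_open_t, cfg.late_window)
    corrs = pd.concat(corr_frames, ignore_index=True)

    # population mismatch response vs 0 and vs the playback halt
    tc_vs_zero = timecourse_test(mm_traces, None, fs=sim.frame_rate_hz,
                                 bin_frames=cfg.bin_frames, alpha=cfg.alpha,
                                 n_boot=cfg.n_boot,
                                 seed=stage_seed(cfg.seed, "tc0"),
                                 direction="a_gt_b", time_s=mm_t[0].time_s)
    tc_vs_halt = timecourse_test(mm_traces, halt_traces, fs=sim.frame_rate_hz,
                                 bin_frames=cfg.bin_frames, alpha=cfg.alpha,
                                 n_boot=cfg.n_boot,
                                 seed=stage_seed(cfg.seed, "tch"),
                                 paired=True, direction="a_gt_b",
                                 time_s=mm_t[0].time_s)

    # top mismatch responders: sensory and motor characterization
    mm_table = response_scalar_from_grouped(mm_resp, mm_t, w, mm_type)
    selected = select_top_responders(mm_table, cfg.top_fraction)
    sel_mask = np.zeros(mm_resp.n, bool)
    sel_mask[selected] = True
    char_sel = GroupedSample(char_resp.values[sel_mask],
                             mm_resp.site_id[sel_mask])
    onset_sel = GroupedSample(onset_resp_open.values[sel_mask],
                              mm_resp.site_id[sel_mask])
    char_test = hboot_test(char_sel, None, direction="a_lt_b",
                           n_boot=cfg.n_boot,
                           seed=stage_seed(cfg.seed, "charsel"))
    onset_test = hboot_test(onset_sel, None, direction="a_gt_b",
                            n_boot=cfg.n_boot,
                            seed=stage_seed(cfg.seed, "onsel"))
    quad = _quadrant_stats(corrs, selected)

    # closed vs open loop running-onset contrast in the late window
    late_test = hboot_test(late_closed, late_open, direction="a_lt_b",
                           n_boot=cfg.n_boot,
                           seed=stage_seed(cfg.seed, "late"), paired=True)

    # behavioral control: running speed around mismatch onsets, pooled
    # across sites (sites -> trials)
    behav = _behavior_pooled(behav_diffs, sim.frame_rate_hz, cfg.n_boot,
                             stage_seed(cfg.seed, "behav"))

    # ground-truth recovery (only available on simulated data)
    gt_classes = np.array([g.neuron_class for g in exp["neurons"]])
    planted = np.flatnonzero(gt_classes == mm_type)
    n_planted = planted.size
    sel_set = set(selected.tolist())
    precision = (len(sel_set & set(planted.tolist())) / len(sel_set)
                 if sel_set else np.nan)
    matched = select_top_responders(
        mm_table, max(cfg.top_fraction, n_planted / mm_resp.n)) \
        if n_planted else np.empty(0, int)
    recall_matched = (len(set(matched.tolist()) & set(planted.tolist()))
                      / n_planted if n_planted else np.nan)

    return {
        "preset": "fig2_am" if coupling == "AM" else "fig3_vm",
        "coupling": coupling,
        "n_neurons": int(mm_resp.n),
        "n_sites": int(sim.n_sites),
        "mm_mean_trace": mm_traces.values.mean(axis=0).tolist(),
        "halt_mean_trace": halt_traces.values.mean(axis=0).tolist(),
        "bin_time_s": (tc_vs_zero.bin_time_s.tolist()
                       if tc_vs_zero.bin_time_s is not None else None),
        "mm_vs_zero_p": np.asarray(tc_vs_zero.p_value).tolist(),
        "mm_vs_zero_sig": tc_vs_zero.sig_mask.astype(int).tolist(),
        "mm_vs_halt_p": np.asarray(tc_vs_halt.p_value).tolist(),
        "mm_vs_halt_sig": tc_vs_halt.sig_mask.astype(int).tolist(),
        "top_fraction": cfg.top_fraction,
        "selected": selected.tolist(),
        "selected_char_response_mean": float(char_resp.values[sel_mask].mean()),
        "selected_char_p": float(char_test.p_value),
        "selected_onset_response_mean": float(onset_resp_open.values[sel_mask].mean()),
        "selected_onset_p": float(onset_test.p_value),
        "quadrant": quad,
        "late_closed_mean": float(late_closed.values.mean()),
        "late_open_mean": float(late_open.values.mean()),
        "late_closed_lt_open_p": float(late_test.p_value),
        "behav_control_p": float(behav.p_value),
        "gt_n_planted": int(n_planted),
        "gt_precision_top": float(precision) if precision == precision else None,
        "gt_recall_matched_fraction": float(recall_matched)
        if recall_matched == recall_matched else None,
    }


def response_scalar_from_grouped(grouped: GroupedSample, tensors, window,
                                 condition: str):
    """Build a ResponseTable view over concatenated per-site tensors."""
    from .responses import ResponseTable

    n_trials = min(t.n_trials for t in tensors)
    return ResponseTable(response=grouped.values, n_trials=max(2, n_trials),
                         site_id=grouped.site_id, window=window,
                         condition=condition)


def _behavior_pooled(behav_items, fs, n_boot, seed):
    """Pooled behavioral control across sites (sites -> trials)."""
    diffs, sites = [], []
    for trace, ev, site in behav_items:
        for _, row in ev.iterrows():
            k = int(round(row["onset_s"] * fs))
            r0, r1 = k + int(round(0.5 * fs)), k + int(round(1.0 * fs))
            b0, b1 = k - int(round(0.5 * fs)), k
            if b0 < 0 or r1 > trace.size:
                continue
            diffs.append(trace[r0:r1].mean() - trace[b0:b1].mean())
            sites.append(site)
    sample = GroupedSample(np.asarray(diffs), np.asarray(sites))
    return hboot_test(sample, None, direction="two_sided", n_boot=n_boot,
                      seed=seed)


def _fig1_preset(cfg: RunConfig) -> dict:
    sim = dataclasses.replace(cfg.sim, coupling_mode="none")
    exp = simulate_experiment(sim, stage_seed(cfg.seed, "sim"),
                              ("tones", "gratings"), cfg.class_fractions,
                              cfg.class_overrides)
    out = {"preset": "fig1_sensory", "n_sites": int(sim.n_sites)}
    for kind, etype in (("tones", "tone"), ("gratings", "grating")):
        tensors, onset_tensors = [], []
        for site, per in exp["sites"].items():
            d = compute_dff(per[kind].F, sim.frame_rate_hz)
            tensors.append(_site_tensor(per[kind], d,
                                        _included_events(per[kind], [etype]),
                                        cfg.align_window, etype))
            onset_tensors.append(_site_tensor(per[kind], d,
                                              _onset_events(per[kind]),
                                              cfg.align_window, "running_onset"))
        traces = _concat_traces(tensors)
        tc = timecourse_test(traces, None, fs=sim.frame_rate_hz,
                             bin_frames=cfg.bin_frames, alpha=cfg.alpha,
                             n_boot=cfg.n_boot,
                             seed=stage_seed(cfg.seed, "tc", etype),
                             direction="two_sided", time_s=tensors[0].time_s)
        order, heat, r1, r2 = split_half_order(tensors[0])
        on_traces = _concat_traces(onset_tensors)
        tc_on = timecourse_test(on_traces, None, fs=sim.frame_rate_hz,
                                bin_frames=cfg.bin_frames, alpha=cfg.alpha,
                                n_boot=cfg.n_boot,
                                seed=stage_seed(cfg.seed, "tcon", etype),
                                direction="a_gt_b", time_s=tensors[0].time_s)
        out[etype] = {
            "mean_trace": traces.values.mean(axis=0).tolist(),
            "sig": tc.sig_mask.astype(int).tolist(),
            "split_half_rank_corr": float(sps.spearmanr(r1, r2).statistic),
            "onset_sig": tc_on.sig_mask.astype(int).tolist(),
            "onset_mean_trace": on_traces.values.mean(axis=0).tolist(),
        }
    return out


def _compensate_vm_lead(tensor: TrialTensor, frames: int) -> TrialTensor:
    """Shift a VM-mismatch tensor earlier by the VM loop lead and re-apply
    the baseline subtraction, so the unimodal VM response has the timing it
    has within a concurrent (AM-aligned) mismatch trial."""
    from .nonlinearity import shift_earlier
    from .responses import BASELINE_WINDOW, _window_frames

    data = shift_earlier(tensor.data, frames)
    offsets = np.round(tensor.time_s * tensor.fs - 0.5).astype(int)
    base = _window_frames(BASELINE_WINDOW, tensor.fs, offsets)
    data = data - data[:, :, base].mean(axis=2, keepdims=True)
    return TrialTensor(data=data, time_s=tensor.time_s, fs=tensor.fs,
                       alignment_event=tensor.alignment_event,
                       trial_meta=tensor.trial_meta,
                       neuron_site=tensor.neuron_site)


def _fig4_preset(cfg: RunConfig) -> dict:
    fractions = cfg.class_fractions or POPULATIONS["fig4_avm"]
    overrides = cfg.class_overrides
    if overrides is None:
        overrides = {"multimodal_selective": {
            "mm_amp_am": cfg.mm_amp, "mm_amp_vm": cfg.mm_amp,
            "g": cfg.interaction_gain}}
    sims = {m: dataclasses.replace(cfg.sim, coupling_mode=m)
            for m in ("AM", "VM", "AVM")}
    # one shared population across the three paradigms
    neurons = make_population(cfg.sim, stage_seed(cfg.seed, "population"),
                              fractions, overrides)
    tensors = {m: [] for m in sims}
    for m, sim in sims.items():
        for site in range(sim.n_sites):
            sess = simulate_session(sim, site, neurons, "closed",
                                    stage_seed(cfg.seed, "sess", m))
            d = compute_dff(sess.F, sim.frame_rate_hz)
            etype = {"AM": "am_mismatch", "VM": "vm_mismatch",
                     "AVM": "avm_mismatch"}[m]
            tensors[m].append(_site_tensor(sess, d,
                                           _included_events(sess, [etype]),
                                           cfg.align_window, etype))
    if cfg.lag_compensation:
        lead = (round(cfg.sim.am_delay_s * cfg.sim.frame_rate_hz)
                - round(cfg.sim.vm_delay_s * cfg.sim.frame_rate_hz))
        tensors["VM"] = [_compensate_vm_lead(t, lead) for t in tensors["VM"]]
    w = cfg.response_window
    conc = _concat_scalars(tensors["AVM"], w)
    r_am = _concat_scalars(tensors["AM"], w)
    r_vm = _concat_scalars(tensors["VM"], w)
    r_sum = GroupedSample(r_am.values + r_vm.values, r_am.site_id, r_am.keys)
    tr_c = _concat_traces(tensors["AVM"])
    tr_sum_vals = linear_sum_traces(
        np.concatenate([t.mean_traces() for t in tensors["AM"]]),
        np.concatenate([t.mean_traces() for t in tensors["VM"]]))
    tr_sum = GroupedSample(tr_sum_vals, tr_c.site_id, tr_c.keys)

    def ptest(a, b, tag):
        return hboot_test(a, b, direction="a_gt_b", n_boot=cfg.n_boot,
                          seed=stage_seed(cfg.seed, tag), paired=True)

    vs_am = ptest(conc, r_am, "c_vs_am")
    vs_vm = ptest(conc, r_vm, "c_vs_vm")
    vs_sum = ptest(conc, r_sum, "c_vs_sum")
    tc_sum = timecourse_test(tr_c, tr_sum, fs=cfg.sim.frame_rate_hz,
                             bin_frames=cfg.bin_frames, alpha=cfg.alpha,
                             n_boot=cfg.n_boot,
                             seed=stage_seed(cfg.seed, "tc_sum"),
                             paired=True, direction="a_gt_b",
                             time_s=tensors["AVM"][0].time_s)
    denom = r_sum.values.mean()
    ratio = float(conc.values.mean() / denom) if denom != 0 else float("inf")

    # per-neuron selectivity, per site (trial counts differ between sites)
    recs = []
    fr_acc = {c: 0 for c in ("concurrent_only", "sum_only", "both", "neither")}
    n_tot = 0
    for i, (tc_, ta, tv) in enumerate(zip(tensors["AVM"], tensors["AM"],
                                          tensors["VM"])):
        r, fr = classify_selectivity(tc_, ta, tv, alpha=cfg.alpha,
                                     seed=stage_seed(cfg.seed, "sel", i))
        recs.extend(r)
        for c in fr_acc:
            fr_acc[c] += fr[c] * fr["n_classified"]
        n_tot += fr["n_classified"]
    fractions_out = {c: fr_acc[c] / n_tot for c in fr_acc}

    gt_classes = np.array([g.neuron_class for g in neurons])
    return {
        "preset": "fig4_avm",
        "n_neurons": int(conc.n),
        "interaction_gain": cfg.interaction_gain,
        "ratio_concurrent_over_sum": ratio,
        "p_concurrent_gt_am": float(vs_am.p_value),
        "p_concurrent_gt_vm": float(vs_vm.p_value),
        "p_concurrent_gt_sum": float(vs_sum.p_value),
        "bins_concurrent_gt_sum_sig": tc_sum.sig_mask.astype(int).tolist(),
        "selectivity_fractions": fractions_out,
        "gt_fraction_multimodal": float(
            np.mean(gt_classes == "multimodal_selective")),
        "mean_resp_concurrent": float(conc.values.mean()),
        "mean_resp_sum": float(r_sum.values.mean()),
    }


def run_preset(cfg: RunConfig) -> dict:
    """Execute one preset and (optionally) write its stats bundle.

    Returns the stats dict; with ``cfg.out_dir`` set, writes
    ``stats.json`` (sorted keys, so identical runs are byte-identical).
    """
    if cfg.preset == "calibration":
        stats = cal.calibration_table(n_boot=cfg.n_boot,
                                      seed=stage_seed(cfg.seed, "calib"))
        stats["preset"] = "calibration"
    elif cfg.preset == "fig1_sensory":
        stats = _fig1_preset(cfg)
    elif cfg.preset == "fig2_am":
        stats = _mismatch_preset(cfg, "AM")
    elif cfg.preset == "fig3_vm":
        stats = _mismatch_preset(cfg, "VM")
    elif cfg.preset == "fig4_avm":
        stats = _fig4_preset(cfg)
    else:  # pragma: no cover - guarded by RunConfig
        raise ValueError(cfg.preset)
    stats["seed"] = cfg.seed
    stats["n_boot"] = cfg.n_boot
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "stats.json").write_text(
            json.dumps(stats, indent=2, sort_keys=True))
    return stats
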