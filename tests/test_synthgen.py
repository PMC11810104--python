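"""Generator: behavior, coupling, mismatch injection, neuron forward model."""

import dataclasses
import math

import numpy as np
import pytest

from mmpipe.events import detect_running_onsets
from mmpipe.synthgen import (SimConfig, GroundTruthNeuron, apply_coupling,
                             inject_mismatches, inject_concurrent_mismatches,
                             make_open_loop_replay, make_population,
                             neuron_rates, rates_to_fluorescence,
                             simulate_running, simulate_session, sound_mapping)


class TestRunning:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(session_length_s=120)
        assert np.array_equal(simulate_running(cfg, 7), simulate_running(cfg, 7))
        assert not np.array_equal(simulate_running(cfg, 7), simulate_running(cfg, 8))

    def test_zero_bout_rate_gives_flat_trace(self):
        cfg = SimConfig(session_length_s=120, bout_rate_per_min=0.0)
        assert not simulate_running(cfg, 0).any()

    def test_too_short_session_raises(self):
        cfg = SimConfig(session_length_s=1.0)
        with pytest.raises(ValueError, match="too short"):
            simulate_running(cfg, 0)

    def test_speed_trace_shape_and_positivity(self):
        cfg = SimConfig(session_length_s=600)
        v = simulate_running(cfg, 3)
        assert v.size == cfg.n_frames
        assert (v >= 0).all()
        assert v.max() <= 48.0  # peaks drawn in 5-40 cm/s plus wobble

    def test_default_session_contains_onsets(self):
        """600 s of default behavior must yield several clean running
        onsets under the 3 cm/s / 3-s pre-mean rule."""
        cfg = SimConfig(session_length_s=600)
        v = simulate_running(cfg, 5)
        assert detect_running_onsets(v, cfg.frame_rate_hz).size >= 3


class TestCoupling:
    def test_reference_speed_maps_to_reference_level(self):
        cfg = SimConfig()
        assert sound_mapping(np.array([30.0]), cfg)[0] == pytest.approx(60.0)

    def test_zero_speed_is_silence(self):
        cfg = SimConfig()
        assert sound_mapping(np.array([0.0]), cfg)[0] == 0.0
        cfg_db = dataclasses.replace(cfg, mapping="linear_db")
        assert sound_mapping(np.array([0.0]), cfg_db)[0] == 0.0

    def test_pressure_mapping_closed_form(self):
        # pressure proportional to speed: 15 cm/s -> 60 + 20*log10(0.5) dB
        cfg = SimConfig(mapping="linear_pressure")
        expect = 60.0 + 20.0 * math.log10(15.0 / 30.0)
        assert sound_mapping(np.array([15.0]), cfg)[0] == pytest.approx(expect, abs=1e-9)

    def test_delay_realized_as_frame_shift(self):
        """Cross-correlation of speed and sound peaks at the AM loop delay
        (round(0.26 s * 15 Hz) = 4 frames), noise off."""
        cfg = SimConfig(mapping="linear_db", session_length_s=300,
                        coupling_mode="AM")
        v = simulate_running(cfg, 9)
        sound, _ = apply_coupling(v, cfg)
        lags = np.arange(0, 10)
        xc = [np.corrcoef(v[: v.size - k], sound[k:])[0, 1] for k in lags]
        assert lags[int(np.argmax(xc))] == round(cfg.am_delay_s * cfg.frame_rate_hz)

    def test_vm_delay_and_gain(self):
        cfg = SimConfig(coupling_mode="VM", visual_gain=2.0)
        v = simulate_running(cfg, 9)
        _, flow = apply_coupling(v, cfg)
        k = round(cfg.vm_delay_s * cfg.frame_rate_hz)
        assert np.allclose(flow[k:], 2.0 * v[: v.size - k])
        assert np.allclose(flow[:k], 0.0)


class TestMismatchInjection:
    def test_stationary_mouse_gets_no_mismatches(self):
        cfg = SimConfig(session_length_s=300)
        v = np.zeros(cfg.n_frames)
        sound, _ = apply_coupling(v, cfg)
        with pytest.warns(UserWarning, match="no eligible"):
            _, ev = inject_mismatches(sound, v, cfg, 3)
        assert len(ev) == 0

    def test_steady_running_event_count_poissonian(self):
        """~40 events expected for 600 s at a 15-s mean interval (+-2 SD)."""
        cfg = SimConfig(session_length_s=600, mapping="linear_db")
        v = np.full(cfg.n_frames, 20.0)
        sound, _ = apply_coupling(v, cfg)
        counts = [len(inject_mismatches(sound, v, cfg, seed)[1])
                  for seed in range(8)]
        expect = 600 / 15
        assert abs(np.mean(counts) - expect) < 2 * math.sqrt(expect)

    def test_trace_zero_during_every_event(self):
        cfg = SimConfig(session_length_s=600, mapping="linear_db")
        v = np.full(cfg.n_frames, 20.0)
        sound, _ = apply_coupling(v, cfg)
        out, ev = inject_mismatches(sound, v, cfg, 4)
        fs = cfg.frame_rate_hz
        for _, row in ev.iterrows():
            k0 = int(round(row["onset_s"] * fs))
            k1 = k0 + int(round(row["duration_s"] * fs))
            assert (out[k0:k1] == 0.0).all()

    def test_eligibility_pre_window_running(self):
        """Every emitted event must be preceded by 1 s of speed > 0.3."""
        cfg = SimConfig(session_length_s=600)
        v = simulate_running(cfg, 6)
        sound, _ = apply_coupling(v, cfg)
        out, ev = inject_mismatches(sound, v, cfg, 7)
        fs = cfg.frame_rate_hz
        assert len(ev) > 0
        for _, row in ev.iterrows():
            k0 = int(round(row["onset_s"] * fs))
            assert (v[k0 - int(fs):k0] > 0.3).all()

    def test_events_do_not_overlap(self):
        cfg = SimConfig(session_length_s=600, mapping="linear_db")
        v = np.full(cfg.n_frames, 20.0)
        sound, _ = apply_coupling(v, cfg)
        _, ev = inject_mismatches(sound, v, cfg, 8)
        onsets = ev["onset_s"].to_numpy()
        assert (np.diff(onsets) >= cfg.mm_duration_s).all()

    def test_concurrent_halts_vm_leads_am(self):
        cfg = SimConfig(session_length_s=600, coupling_mode="AVM")
        v = np.full(cfg.n_frames, 20.0)
        sound, flow = apply_coupling(v, cfg)
        s2, f2, ev = inject_concurrent_mismatches(sound, flow, v, cfg, 5)
        fs = cfg.frame_rate_hz
        lead = round(cfg.am_delay_s * fs) - round(cfg.vm_delay_s * fs)
        assert len(ev) > 0
        for _, row in ev.iterrows():
            k_am = int(round(row["onset_s"] * fs))
            assert (s2[k_am:k_am + 15] == 0).all()
            assert (f2[k_am - lead:k_am - lead + 15] == 0).all()
            assert row["vm_lead_s"] == pytest.approx(lead / fs)


class TestOpenLoopReplay:
    def _closed(self, seed=0):
        cfg = SimConfig(session_length_s=240, n_sites=1, neurons_per_site=4)
        neurons = make_population(cfg, seed)
        return simulate_session(cfg, 0, neurons, "closed", seed)

    def test_halts_relabelled_as_playback(self):
        sess = self._closed(1)
        n_mm = (sess.events["event_type"] == "am_mismatch").sum()
        replay = make_open_loop_replay(sess, np.zeros(sess.n_frames))
        assert (replay.events["event_type"] == "playback_halt_sound").sum() == n_mm
        assert replay.loop_type == "open"
        assert np.array_equal(replay.sound_db, sess.sound_db)

    def test_replay_behavior_uncorrelated_with_sound(self):
        cfg = SimConfig(session_length_s=600, n_sites=1, neurons_per_site=4)
        neurons = make_population(cfg, 2)
        closed = simulate_session(cfg, 0, neurons, "closed", 3)
        new_run = simulate_running(cfg, 991)
        replay = make_open_loop_replay(closed, new_run)
        r = np.corrcoef(replay.run_speed, replay.sound_db)[0, 1]
        assert abs(r) < 0.1

    def test_replay_of_replay_rejected(self):
        sess = self._closed(4)
        replay = make_open_loop_replay(sess, np.zeros(sess.n_frames))
        with pytest.raises(ValueError, match="closed-loop"):
            make_open_loop_replay(replay, np.zeros(sess.n_frames))

    def test_length_mismatch_rejected(self):
        sess = self._closed(5)
        with pytest.raises(ValueError, match="length"):
            make_open_loop_replay(sess, np.zeros(10))


class TestNeuronModel:
    def test_silent_unit_with_zero_baseline(self, closed_am_session):
        gt = GroundTruthNeuron(site_id=0, neuron_class="silent",
                               baseline_rate=0.0)
        assert not neuron_rates(closed_am_session, gt).any()

    def test_subtractive_unit_toy_trace(self):
        """During an AM halt while running, the rate of a subtractive unit
        rises by exactly the removed inhibition w_sound * sound_db."""
        from types import SimpleNamespace

        from mmpipe.events import EventTable

        fs = 15.0
        v = np.full(6, 20.0)
        sound = np.array([50.0, 50.0, 0.0, 0.0, 50.0, 50.0])
        sess = SimpleNamespace(frame_rate_hz=fs, run_speed=v, sound_db=sound,
                               visual_flow=np.zeros(6), events=EventTable([]))
        gt = GroundTruthNeuron(site_id=0, neuron_class="am_mismatch",
                               w_run=0.1, w_sound=0.05, baseline_rate=1.0)
        r = neuron_rates(sess, gt)
        # hand evaluation: 1 + 0.1*20 - 0.05*sound
        assert np.allclose(r, [0.5, 0.5, 3.0, 3.0, 0.5, 0.5])

    def test_interaction_gain_unity_is_linear(self):
        """g=1: concurrent-halt rate excursion equals the sum of the
        unimodal excursions exactly (noise-free rate level)."""
        from types import SimpleNamespace

        from mmpipe.events import EventTable

        fs = 15.0
        n = 60
        v = np.full(n, 20.0)
        events_am = EventTable([dict(event_type="am_mismatch", onset_s=1.0,
                                     duration_s=1.0)])
        events_vm = EventTable([dict(event_type="vm_mismatch", onset_s=1.0,
                                     duration_s=1.0)])
        events_both = EventTable([dict(event_type="avm_mismatch", onset_s=1.0,
                                       duration_s=1.0, vm_lead_s=0.0)])
        mk = lambda ev: SimpleNamespace(frame_rate_hz=fs, run_speed=v,
                                        sound_db=np.zeros(n),
                                        visual_flow=np.zeros(n), events=ev)
        gt = GroundTruthNeuron(site_id=0, neuron_class="multimodal_selective",
                               mm_amp_am=0.7, mm_amp_vm=0.4, g=1.0,
                               baseline_rate=1.0)
        exc = lambda ev: neuron_rates(mk(ev), gt) - 1.0
        total = exc(events_am) + exc(events_vm)
        assert np.abs(exc(events_both) - total).max() < 1e-9

    def test_interaction_gain_scales_concurrent_only(self):
        from types import SimpleNamespace

        from mmpipe.events import EventTable

        ev = EventTable([dict(event_type="avm_mismatch", onset_s=1.0,
                              duration_s=1.0, vm_lead_s=0.0)])
        sess = SimpleNamespace(frame_rate_hz=15.0, run_speed=np.full(60, 20.0),
                               sound_db=np.zeros(60), visual_flow=np.zeros(60),
                               events=ev)
        gt = GroundTruthNeuron(site_id=0, neuron_class="multimodal_selective",
                               mm_amp_am=0.5, mm_amp_vm=0.5, g=3.0,
                               baseline_rate=0.0)
        assert neuron_rates(sess, gt).max() == pytest.approx(3.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown neuron class"):
            GroundTruthNeuron(site_id=0, neuron_class="mystery")


class TestFluorescenceModel:
    def _gt(self, **kw):
        defaults = dict(site_id=0, neuron_class="silent", noise_sd=0.0,
                        drift_amp=0.0)
        defaults.update(kw)
        return GroundTruthNeuron(**defaults)

    def test_zero_rate_no_noise_is_constant_offset(self):
        F = rates_to_fluorescence(np.zeros(100), self._gt(), 0, fs=15.0)
        assert np.allclose(F, F[0])
        assert (F > 0).all()

    def test_single_spike_kernel_decay(self):
        """tau = 0.6 s at 15 Hz: each frame decays by exp(-1/9)."""
        rate = np.zeros(50)
        rate[10] = 1e9  # force a spike burst at frame 10
        F = rates_to_fluorescence(rate, self._gt(tau_ca_s=0.6), 1, fs=15.0)
        tail = F[11:20] - F[0]
        ratios = tail[1:] / tail[:-1]
        assert np.allclose(ratios, math.exp(-1.0 / 9.0), rtol=1e-6)

    def test_doubling_rate_doubles_mean_response(self):
        """Kernel-driven mean ΔF above offset is linear in rate (Monte
        Carlo over 100 seeds, noise off)."""
        gt = self._gt()
        r1 = np.full(300, 2.0)
        m1 = np.mean([rates_to_fluorescence(r1, gt, s, fs=15.0).mean()
                      for s in range(100)])
        m2 = np.mean([rates_to_fluorescence(2 * r1, gt, s + 500, fs=15.0).mean()
                      for s in range(100)])
        offset = rates_to_fluorescence(np.zeros(300), gt, 0, fs=15.0)[0]
        assert (m2 - offset) == pytest.approx(2 * (m1 - offset), rel=0.05)

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rates_to_fluorescence(np.array([1.0, np.nan]), self._gt(), 0)

    def test_deterministic_given_seed(self):
        gt = GroundTruthNeuron(site_id=0, neuron_class="silent")
        a = rates_to_fluorescence(np.full(200, 3.0), gt, 42, fs=15.0)
        b = rates_to_fluorescence(np.full(200, 3.0), gt, 42, fs=15.0)
        assert np.array_equal(a, b)


class TestSessionAssembly:
    def test_identical_config_and_seed_identical_session(self, small_sim):
        neurons = make_population(small_sim, 1)
        a = simulate_session(small_sim, 0, neurons, "closed", 2)
        b = simulate_session(small_sim, 0, neurons, "closed", 2)
        assert np.array_equal(a.F, b.F)
        assert np.array_equal(a.run_speed, b.run_speed)
        assert a.events.equals(b.events)

    def test_population_fractions_and_overrides(self, small_sim):
        neurons = make_population(
            small_sim, 0, {"motor": 0.5, "silent": 0.5},
            {"motor": {"w_run": 0.33}})
        classes = [n.neuron_class for n in neurons]
        assert classes.count("motor") == 6 and classes.count("silent") == 6
        assert all(n.w_run == 0.33 for n in neurons
                   if n.neuron_class == "motor")

    def test_session_traces_positive_and_aligned(self, closed_am_session):
        s = closed_am_session
        assert (s.F > 0).all()
        assert s.F.shape[1] == s.t.size == s.run_speed.size
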