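"""Trial alignment, scalar responses, selection, correlations."""

import numpy as np
import pytest

from conftest import make_tensor
from mmpipe.events import EventTable
from mmpipe.preprocess import DffMatrix
from mmpipe.responses import (ResponseTable, align_trials, behavioral_control,
                              openloop_correlations, response_scalar,
                              select_top_responders, split_half_order,
                              trial_responses)


def _dff(x, fs=15.0):
    x = np.atleast_2d(np.asarray(x, float))
    return DffMatrix(dff=x, fs=fs, f0=np.ones(x.shape[0]),
                     baseline_percentile=8.0, window_s=66.0)


def _events(onsets, etype="am_mismatch"):
    return EventTable([dict(event_type=etype, onset_s=float(t),
                            duration_s=1.0) for t in onsets])


class TestAlignTrials:
    def test_constant_dff_gives_zero_tensor(self):
        d = _dff(np.full((2, 600), 0.7))
        t = align_trials(d, _events([10.0, 20.0]))
        assert np.allclose(t.data, 0.0)
        assert t.n_trials == 2 and t.n_neurons == 2

    def test_boxcar_recovered_at_event_time(self):
        fs = 15.0
        x = np.zeros((1, 600))
        k = int(10.0 * fs)
        x[0, k:k + int(fs)] = 1.0        # unit boxcar on [10, 11) s
        t = align_trials(_dff(x), _events([10.0]))
        in_box = (t.time_s >= 0) & (t.time_s < 1.0)
        assert np.allclose(t.data[0, 0, in_box], 1.0)
        assert np.allclose(t.data[0, 0, ~in_box], 0.0)

    def test_baseline_window_zero_mean_invariant(self, rng):
        x = rng.normal(0, 1, (3, 1200))
        t = align_trials(_dff(x), _events([20.0, 40.0, 60.0]))
        base = (t.time_s >= -0.5) & (t.time_s < 0)
        assert np.abs(t.data[:, :, base].mean(axis=2)).max() < 1e-9

    def test_edge_event_dropped_with_warning(self):
        d = _dff(np.ones((1, 300)))
        with pytest.warns(UserWarning, match="dropped"):
            t = align_trials(d, _events([1.0, 10.0]))
        assert t.n_trials == 1

    def test_avm_vm_lead_frame_arithmetic(self):
        # a VM lead of 0.17 s is 3 frames ahead of time zero at 15 Hz
        fs = 15.0
        x = np.zeros((1, 600))
        k_am = int(20.0 * fs)
        x[0, k_am - 3:k_am] = 1.0  # VM-halt marker 3 frames before AM onset
        ev = EventTable([dict(event_type="avm_mismatch", onset_s=20.0,
                              duration_s=1.0, vm_lead_s=0.17)])
        t = align_trials(_dff(x), ev)
        lead_frames = round(0.17 * fs)
        assert lead_frames == 3
        marked = np.flatnonzero(t.data[0, 0] > 0.5)
        zero_ix = np.flatnonzero(t.time_s > 0)[0]
        assert np.array_equal(marked, np.arange(zero_ix - 3, zero_ix))


class TestResponseScalar:
    def test_zero_tensor_zero_response(self):
        t = make_tensor(np.zeros((3, 2, 105)))
        r = response_scalar(t)
        assert np.allclose(r.response, 0.0)
        assert r.n_trials == 3

    def test_full_window_boxcar_response_one(self):
        # fs=10: window [0.5, 2.5) covers frames 25..44 of a [-2, 5) snippet
        data = np.zeros((2, 1, 70))
        data[:, :, 25:45] = 1.0
        t = make_tensor(data, fs=10.0)
        assert response_scalar(t).response[0] == pytest.approx(1.0)

    def test_half_window_boxcar_response_half(self):
        data = np.zeros((2, 1, 70))
        data[:, :, 25:35] = 1.0          # covers [0.5, 1.5) only
        t = make_tensor(data, fs=10.0)
        assert response_scalar(t).response[0] == pytest.approx(0.5)

    def test_linearity(self, rng):
        a = make_tensor(rng.normal(0, 1, (4, 3, 105)))
        b = make_tensor(rng.normal(0, 1, (4, 3, 105)))
        lhs = response_scalar(
            make_tensor(2 * a.data + 3 * b.data)).response
        rhs = (2 * response_scalar(a).response
               + 3 * response_scalar(b).response)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_empty_tensor_rejected(self):
        t = make_tensor(np.zeros((2, 1, 105)))
        t.data = t.data[:0]
        with pytest.raises(ValueError, match="empty"):
            response_scalar(t)


class TestSplitHalf:
    def test_identical_trials_identical_ordering(self):
        trial = np.zeros((1, 4, 105))
        trial[0, :, 40:70] = np.array([3.0, 1.0, 4.0, 2.0])[:, None]
        t = make_tensor(np.repeat(trial, 6, axis=0))
        order, heat, r1, r2 = split_half_order(t, smooth_neurons=1)
        np.testing.assert_array_equal(order, [2, 0, 3, 1])
        np.testing.assert_allclose(r1, r2)

    def test_no_signal_no_ordering_bias(self, rng):
        from scipy.stats import spearmanr

        t = make_tensor(rng.normal(0, 1, (40, 500, 105)))
        order, heat, r1, r2 = split_half_order(t)
        rho = spearmanr(np.argsort(np.argsort(-r1)), r2).statistic
        assert abs(rho) < 0.1

    def test_planted_gradient_monotone_heatmap(self, rng):
        amp = np.linspace(0, 2, 30)
        data = rng.normal(0, 0.01, (10, 30, 105))
        data[:, :, 40:70] += amp[None, :, None]
        t = make_tensor(data)
        order, heat, r1, r2 = split_half_order(t, smooth_neurons=1)
        heat_resp = heat[:, 40:70].mean(axis=1)
        assert (np.diff(heat_resp) <= 1e-3).all()

    def test_single_trial_rejected(self):
        t = make_tensor(np.zeros((1, 2, 105)))
        with pytest.raises(ValueError, match="2 trials"):
            split_half_order(t)


class TestTopResponders:
    def _table(self, resp):
        return ResponseTable(response=np.asarray(resp, float), n_trials=5,
                             site_id=np.zeros(len(resp), int))

    def test_exact_count_and_membership(self, rng):
        r = rng.normal(0, 1, 100)
        sel = select_top_responders(self._table(r), 0.05)
        assert sel.size == 5
        assert set(sel) == set(np.argsort(-np.abs(r))[:5])

    def test_ties_broken_by_index(self):
        sel = select_top_responders(self._table(np.ones(100)), 0.05)
        np.testing.assert_array_equal(sel, np.arange(5))

    def test_absolute_value_selection(self):
        r = [-9.0, 5.0, 1.0, 0.0, 0.5, -0.2, 0.1, 0.3]
        sel = select_top_responders(self._table(r), 0.25)
        assert set(sel) == {0, 1}

    def test_selection_nesting(self, rng):
        t = self._table(rng.normal(0, 1, 200))
        s5 = set(select_top_responders(t, 0.05))
        s10 = set(select_top_responders(t, 0.10))
        s20 = set(select_top_responders(t, 0.20))
        assert s5 <= s10 <= s20

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_top_responders(self._table(np.ones(10)), 0.0)
        with pytest.raises(ValueError):
            select_top_responders(self._table(np.ones(10)), 1.5)


class TestOpenLoopCorrelations:
    def _session(self, run, sound):
        from types import SimpleNamespace

        return SimpleNamespace(loop_type="open", run_speed=run,
                               sound_db=sound, visual_flow=np.zeros(run.size))

    def test_perfect_correlations(self, rng):
        run = rng.random(2000)
        sound = rng.random(2000) * 60
        d = _dff(np.vstack([run, -sound]))
        out = openloop_correlations(d, self._session(run, sound))
        assert out["r_run"][0] == pytest.approx(1.0)
        assert out["r_stim"][1] == pytest.approx(-1.0)

    def test_white_noise_near_zero(self, rng):
        run = rng.random(9000)
        sound = rng.random(9000) * 60
        d = _dff(rng.normal(0, 1, (20, 9000)))
        out = openloop_correlations(d, self._session(run, sound))
        assert np.abs(out.to_numpy()).max() < 0.1

    def test_closed_loop_session_rejected(self):
        from types import SimpleNamespace

        d = _dff(np.ones((1, 100)))
        with pytest.raises(ValueError, match="open-loop"):
            openloop_correlations(d, SimpleNamespace(loop_type="closed"))

    def test_zero_variance_regressor_nan(self, rng):
        run = rng.random(500)
        d = _dff(rng.random((2, 500)) + 1)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = openloop_correlations(d, self._session(run, np.zeros(500)))
        assert out["r_stim"].isna().all()


class TestBehavioralControl:
    def test_constant_trace_not_significant(self):
        res = behavioral_control(np.full(9000, 5.0),
                                 _events([100.0, 200.0, 300.0]), 15.0,
                                 n_boot=500, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_speed_dip_detected(self, rng):
        fs = 15.0
        v = np.full(9000, 10.0) + rng.normal(0, 0.1, 9000)
        onsets = np.arange(50.0, 550.0, 25.0)
        for t in onsets:
            k = int(t * fs)
            v[k:k + 15] -= 3.0           # speed drops during the event
        res = behavioral_control(v, _events(onsets), fs, n_boot=1000, seed=1)
        assert res.p_value < 0.05
        assert res.boot_means.mean() < 0

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError, match="no included"):
            behavioral_control(np.ones(100), _events([]), 15.0)
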