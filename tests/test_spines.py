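"""Spine connection candidates, confirmation and branch boosting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alloptical import GeneratorConfig, make_dendrite_recording
from alloptical.spines import (
    SpineTrialResponse,
    boosting_index,
    confirm_connection,
    find_candidate_connections,
    spine_delta_r,
)
from alloptical.traces import dff


def _stim_log(stim_frames, targets=None, dur=2):
    stim_frames = np.asarray(stim_frames)
    if targets is None:
        targets = [()] * len(stim_frames)
    return pd.DataFrame(
        {
            "stim_frame": stim_frames,
            "stim_end_frame": stim_frames + dur,
            "target_ids": targets,
        }
    )


class TestDeltaR:
    def test_flat_trace_zero(self):
        log = _stim_log([20, 60])
        r = spine_delta_r(np.full((2, 100), 0.4), log)
        assert np.allclose(r.delta_r, 0.0)

    def test_step_response(self):
        tr = np.zeros(100)
        tr[32:] = 0.4  # step at stimulation offset
        r = spine_delta_r(tr, _stim_log([30]))
        assert r.delta_r[0, 0] == pytest.approx(0.4)

    def test_artifact_frames_in_neither_window(self):
        tr = np.zeros(100)
        tr[30:32] = 99.0  # artifact during stimulation only
        r = spine_delta_r(tr, _stim_log([30]))
        assert r.delta_r[0, 0] == 0.0

    def test_clipped_trials_dropped(self):
        r = spine_delta_r(np.zeros((1, 50)), _stim_log([5, 30]))
        assert r.delta_r.shape[1] == 1

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        tr = rng.normal(size=(3, 200))
        log = _stim_log([50, 120])
        a = spine_delta_r(tr, log).delta_r
        b = spine_delta_r(tr + 5.0, log).delta_r
        assert np.allclose(a, b)


class TestCandidates:
    @staticmethod
    def _resp(dr, targets):
        dr = np.asarray(dr, float)
        return SpineTrialResponse(dr, dr.mean(axis=0), _stim_log(
            40 * np.arange(dr.shape[1]) + 20, targets))

    def test_direct_reliability_count(self):
        # spine 0 has 10 independent trials (0..9); target 7 on 3 of them,
        # target 9 on 1; trials 10..19 are quiet. ∆R_mean is engineered to be
        # slightly negative on trials 0..18 (below its mean + 0.5 s.d.) with
        # one high-∆R_mean trial so its s.d. is non-degenerate.
        dr0 = np.r_[np.ones(10), np.zeros(10)]
        drm = np.r_[np.full(19, -0.05), [0.2]]
        dr1 = 2 * drm - dr0
        targets = [(7,) if t in (0, 1, 2) else ((9,) if t == 3 else ())
                   for t in range(20)]
        cands = find_candidate_connections(self._resp([dr0, dr1], targets))
        pairs = set(zip(cands.target_id, cands.spine_id))
        assert (7, 0) in pairs
        assert (9, 0) not in pairs
        best = cands.query("target_id == 7 and spine_id == 0").best_reliability
        assert best.iloc[0] == pytest.approx(0.3)

    def test_global_coactivity_yields_no_candidates(self):
        # both spines active only together -> ∆R_mean exceeds even the loosest
        # quiet threshold (mean + 1.5 s.d.) on every high-∆R trial
        dr = np.r_[np.full(3, 3.0), np.zeros(12)]
        targets = [(3,) if t < 3 else () for t in range(15)]
        cands = find_candidate_connections(self._resp([dr, dr], targets))
        assert len(cands) == 0

    def test_candidate_set_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        dr = rng.normal(size=(4, 30))
        targets = [tuple(rng.integers(0, 10, 3)) for _ in range(30)]
        resp = self._resp(dr, targets)
        strict = find_candidate_connections(
            resp, dr_sds=(2.0,), drmean_sds=(0.5,), reliability_pcts=(20.0,)
        )
        loose = find_candidate_connections(
            resp, dr_sds=(2.0, 1.0), drmean_sds=(0.5, 1.0),
            reliability_pcts=(20.0, 10.0),
        )
        s = set(zip(strict.target_id, strict.spine_id)) if len(strict) else set()
        l = set(zip(loose.target_id, loose.spine_id)) if len(loose) else set()
        assert s.issubset(l)

    def test_true_connection_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = dataclasses.replace(
                GeneratorConfig(), seed=seed, n_targets=30, targets_per_stim=10
            )
            rec = make_dendrite_recording(cfg)
            tgt, sp = rec.ground_truth["connections"][0]
            win = int(round(90 * rec.frame_rate))
            sd = dff(rec.spine_traces, window=win, stride=50, presmooth=10)
            search = rec.stim_log.iloc[rec.ground_truth["search_trials"]]
            cands = find_candidate_connections(spine_delta_r(sd, search))
            pairs = set(zip(cands.target_id, cands.spine_id)) if len(cands) else set()
            hits += (tgt, sp) in pairs
        assert hits >= 9

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            find_candidate_connections(self._resp(np.zeros((2, 5)), [()] * 5))


class TestConfirm:
    def test_identical_pre_post_unconfirmed(self):
        c = confirm_connection(np.ones(10), np.ones(10))
        assert c.p_value == 1.0 and not c.confirmed

    def test_uniform_positive_difference_exact_p(self):
        c = confirm_connection(np.zeros(20), np.full(20, 0.3))
        assert c.p_value == pytest.approx(2.0 / 2**20)
        assert c.confirmed

    def test_negative_response_never_confirmed(self):
        c = confirm_connection(np.full(20, 0.3), np.zeros(20))
        assert c.p_value < 0.01 and not c.confirmed

    def test_null_confirmation_rate_at_test_level(self):
        rng = np.random.default_rng(0)
        confirmed = 0
        n = 200
        for _ in range(n):
            pre = rng.normal(size=12)
            post = rng.normal(size=12)
            confirmed += confirm_connection(pre, post).confirmed
        assert confirmed / n <= 0.015

    def test_embedded_connection_confirmed_from_recording(self):
        cfg = dataclasses.replace(GeneratorConfig(), seed=11)
        rec = make_dendrite_recording(cfg)
        tgt, sp = rec.ground_truth["connections"][0]
        win = int(round(90 * rec.frame_rate))
        sd = dff(rec.spine_traces, window=win, stride=50, presmooth=10)
        conf = rec.stim_log.iloc[rec.ground_truth["confirmation_trials"]]
        r = spine_delta_r(sd, conf)
        pre = np.zeros(r.delta_r.shape[1])
        c = confirm_connection(pre, r.delta_r[sp], tgt, sp)
        assert c.confirmed

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            confirm_connection(np.zeros(5), np.ones(5))


class TestBoosting:
    @staticmethod
    def _log(n, amp_stim, amp_ref):
        frames = 30 * np.arange(n) + 15
        log = _stim_log(frames)
        stim_tr = np.zeros(30 * n + 30)
        ref_tr = np.zeros_like(stim_tr)
        for f, a_s, a_r in zip(log.stim_end_frame, amp_stim, amp_ref):
            stim_tr[f : f + 7] = a_s
            ref_tr[f : f + 7] = a_r
        return stim_tr, ref_tr, log

    def test_identical_rois_give_unit_bi_and_null_test(self):
        amps = np.linspace(0.5, 1.5, 12)
        s, r, log = self._log(12, amps, amps)
        res = boosting_index(s, r, log, np.arange(6), np.arange(6, 12))
        assert np.allclose(res.bi_stim, 1.0) and np.allclose(res.bi_blank, 1.0)
        assert res.mean_increase_pct == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_ratio_example(self):
        s, r, log = self._log(10, np.full(10, 1.2), np.full(10, 1.0))
        res = boosting_index(s, r, log, np.arange(5), np.arange(5, 10))
        assert np.allclose(res.bi_stim, 1.2)

    def test_scale_invariance_to_common_gain(self):
        rng = np.random.default_rng(0)
        amps = rng.uniform(0.5, 1.5, 16)
        s, r, log = self._log(16, amps * 1.1, amps)
        a = boosting_index(s, r, log, np.arange(8), np.arange(8, 16))
        b = boosting_index(3 * s, 3 * r, log, np.arange(8), np.arange(8, 16))
        assert a.mean_increase_pct == pytest.approx(b.mean_increase_pct)

    def test_subfloor_reference_trials_excluded(self):
        amps = np.full(12, 1.0)
        ref = amps.copy()
        ref[3] = 0.001
        s, r, log = self._log(12, amps, ref)
        res = boosting_index(s, r, log, np.arange(6), np.arange(6, 12))
        assert res.n_excluded == 1

    def test_generator_default_boosting_recovered(self):
        from alloptical.studies import boosting_recovery

        out = boosting_recovery(n_recordings=10, seed=42)
        assert out["value"] == pytest.approx(10.8, abs=3.0)
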