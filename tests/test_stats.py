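"""Dwell statistics, permutation inference, BH, and pattern change."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazemorph.heatmaps import Heatmap
from gazemorph.io import RoiRect
from gazemorph.kinematics import SaccadeEvent
from gazemorph.stats import (
    baseline_normalize,
    baseline_pattern_variation,
    bh_adjust,
    bootstrap_ci,
    face_detection_metrics,
    ipsi_contra_difference,
    paired_difference_test,
    pattern_change_index,
    permutation_test,
    roi_dwell_time,
)

from conftest import make_trial


def _hm(values):
    g = np.asarray(values, dtype=float).reshape(2, 2)
    return Heatmap(g, 1.0, (-1.0, -1.0), (2.0, 2.0))


ROI = RoiRect("eye", -1.0, 1.0, -1.0, 1.0)


class TestDwell:
    def test_continuous_dwell(self):
        w = pd.DataFrame({"t_ms": np.arange(2000), "x_dva": 0.0, "y_dva": 0.0})
        assert roi_dwell_time(w, ROI) == pytest.approx(2.000)

    def test_never_inside(self):
        w = pd.DataFrame({"t_ms": np.arange(100), "x_dva": 5.0, "y_dva": 5.0})
        assert roi_dwell_time(w, ROI) == 0.0

    def test_constructed_trajectory(self):
        # inside for 1250 samples in two visits, outside elsewhere
        t = np.arange(3000)
        x = np.full(3000, 9.0)
        x[100:1000] = 0.0   # 900 ms inside
        x[2000:2350] = 0.5  # 350 ms inside, last inside sample gets 1 ms
        w = pd.DataFrame({"t_ms": t, "x_dva": x, "y_dva": 0.0})
        assert roi_dwell_time(w, ROI) == pytest.approx(1.250)


class TestIpsiContra:
    def test_zero_and_sign_flip(self):
        rec = pd.DataFrame({"t_right_eye": [1.0, 2.0], "t_left_eye": [1.0, 0.5]})
        d_r = ipsi_contra_difference(rec, "right")
        d_l = ipsi_contra_difference(rec, "left")
        np.testing.assert_allclose(d_r, [0.0, 1.5])
        np.testing.assert_allclose(d_l, -d_r)

    def test_baseline_rejected(self):
        with pytest.raises(ValueError):
            ipsi_contra_difference(pd.DataFrame(), "none")


class TestBaselineNormalize:
    def _records(self, deltas, dates, hemisphere=None):
        df = pd.DataFrame(
            {
                "session_id": [f"s{i}" for i in range(len(deltas))],
                "session_date": dates,
                "t_right_eye": np.asarray(deltas, dtype=float),
                "t_left_eye": 0.0,
            }
        )
        if hemisphere:
            df["hemisphere"] = hemisphere
        return df

    def test_matching_bias_cancels(self):
        d0 = dt.date(2022, 3, 1)
        inj = self._records([0.5], [d0], hemisphere="right")
        base = self._records([0.5, 0.5], [d0 - dt.timedelta(days=5), d0 + dt.timedelta(days=5)])
        out = baseline_normalize(inj, base)
        assert out["delta_ipsi_contra_norm"].iloc[0] == pytest.approx(0.0)

    def test_left_hemisphere_sign(self):
        d0 = dt.date(2022, 3, 1)
        inj = self._records([-0.5], [d0], hemisphere="left")  # left eye favored
        base = self._records([0.5], [d0 - dt.timedelta(days=3)])
        out = baseline_normalize(inj, base)
        # observer-referenced -0.5 - 0.5 = -1.0, ipsi (left) = +1.0
        assert out["delta_ipsi_contra_norm"].iloc[0] == pytest.approx(1.0)

    def test_empty_window_errors(self):
        d0 = dt.date(2022, 3, 1)
        inj = self._records([0.5], [d0], hemisphere="right")
        base = self._records([0.5], [d0 - dt.timedelta(days=60)])
        with pytest.raises(ValueError, match="baseline"):
            baseline_normalize(inj, base)


class TestPermutation:
    def test_identical_constant_groups(self):
        res = permutation_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.observed == 0.0
        assert res.p_perm == 1.0

    def test_exact_enumeration_matches_brute_force(self):
        a, b = [0.0, 0.0, 0.0], [10.0, 10.0, 10.0]
        res = permutation_test(a, b)
        assert res.exact and res.n_resamples == 20
        assert res.p_perm == pytest.approx(2 / 20)
        # independent brute force over all 20 splits
        pooled = np.array(a + b)
        obs = abs(np.mean(a) - np.mean(b))
        hits = 0
        for comb in itertools.combinations(range(6), 3):
            ia = list(comb)
            ib = [i for i in range(6) if i not in comb]
            if abs(pooled[ia].mean() - pooled[ib].mean()) >= obs - 1e-12:
                hits += 1
        assert res.p_perm == pytest.approx(hits / 20)

    def test_monte_carlo_null_calibration(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(0, 1, 25)
            b = rng.normal(0, 1, 25)
            res = permutation_test(a, b, n_resamples=400, seed=rng)
            rejections += res.p_perm < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.025)

    def test_n_resamples_validated(self):
        with pytest.raises(ValueError):
            permutation_test([1.0] * 30, [2.0] * 30, n_resamples=0)


class TestPairedDifference:
    def test_symmetric_deltas_null(self):
        res = paired_difference_test([-1.0, 1.0, -2.0, 2.0])
        assert res.p_perm == 1.0

    def test_exact_sign_flip_all_ones(self):
        res = paired_difference_test([1.0] * 10)
        assert res.exact and res.n_resamples == 1024
        assert res.p_perm == pytest.approx(2 / 1024)

    def test_power_at_generator_regime(self):
        # effect 1.0 s, trial noise 0.5 s, n = 100: overwhelming evidence
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(10):
            d = rng.normal(1.0, 0.5, 100)
            res = paired_difference_test(d, n_resamples=10_000, seed=rng)
            hits += res.p_perm < 0.001
        assert hits == 10


class TestBH:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_and_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_dominates_raw_and_preserves_order(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # step-up adjustment is monotone in the sorted-p order
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPatternChange:
    def test_index_is_one_when_trial_equals_condition_mean(self):
        hi = _hm([1, 0, 0, 0])
        assert pattern_change_index(hi, hi, _hm([0.5, 0.5, 0, 0])) == pytest.approx(1.0, abs=1e-12)

    def test_index_zero_when_distances_equal(self):
        hi = _hm([1, 0, 0, 0])
        other = _hm([0, 1, 0, 0])
        assert pattern_change_index(hi, other, other) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_negative_case(self):
        hi = _hm([1, 0, 0, 0])
        hbar = _hm([0, 1, 0, 0])
        grand = _hm([0.5, 0.5, 0, 0])
        # (sqrt(0.5) - sqrt(2)) / sqrt(0.5) = -1
        assert pattern_change_index(hi, hbar, grand) == pytest.approx(-1.0, abs=1e-12)

    def test_undefined_when_trial_equals_grand_mean(self):
        hi = _hm([1, 0, 0, 0])
        assert np.isnan(pattern_change_index(hi, _hm([0, 1, 0, 0]), hi))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_one_and_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hi, hbar, grand = (_hm(rng.random(4)) for _ in range(3))
        idx = pattern_change_index(hi, hbar, grand)
        dg = np.sqrt(np.sum((hi.grid - grand.grid) ** 2))
        dc = np.sqrt(np.sum((hi.grid - hbar.grid) ** 2))
        assert idx == pytest.approx((dg - dc) / dg, abs=1e-12)
        assert idx <= 1.0 + 1e-12

    def test_baseline_variation_zero_for_identical_trials(self):
        # hbar == grand == hi: both distances zero, variation is exactly 0
        hi = _hm([1, 2, 3, 4])
        out = baseline_pattern_variation({"img": [hi, _hm([1, 2, 3, 4])]}, seed=0)
        assert len(out) >= 1
        np.testing.assert_allclose(out, 0.0)

    def test_injected_shift_raises_index_above_baseline_band(self):
        rng = np.random.default_rng(2)
        base = {"img": [_hm(rng.normal(1, 0.05, 4)) for _ in range(12)]}
        null_idx = baseline_pattern_variation(base, seed=0)
        shifted = {"img": [_hm(rng.normal(1, 0.05, 4) + [2, 0, 0, 0]) for _ in range(12)]}
        from gazemorph.stats import pattern_change_indices

        inj_idx = pattern_change_indices(shifted, base)
        assert inj_idx.mean() > null_idx.mean() + 0.2


class TestFaceDetection:
    POLY = np.array([[-2.0, -2.0], [2.0, -2.0], [2.0, 2.0], [-2.0, 2.0]])

    def test_gaze_inside_from_onset(self):
        tr = make_trial(np.arange(1000), np.zeros(1000), np.zeros(1000))
        m = face_detection_metrics(tr, [], self.POLY)
        assert m["found"] and m["latency_ms"] == 0.0
        assert m["frac_time_on_face"] == 1.0

    def test_latency_from_first_landing_saccade(self):
        n = 2000
        x = np.full(n, 8.0)
        x[500:] = 0.0
        tr = make_trial(np.arange(n), x, np.zeros(n))
        sacc = [SaccadeEvent(440, 500, 8.0, 200.0, (8.0, 0.0), (0.0, 0.0), np.pi)]
        m = face_detection_metrics(tr, sacc, self.POLY)
        assert m["found"] and m["latency_ms"] == 500.0

    def test_never_on_face(self):
        tr = make_trial(np.arange(500), np.full(500, 9.0), np.full(500, 9.0))
        m = face_detection_metrics(tr, [], self.POLY)
        assert not m["found"]
        assert m["frac_time_on_face"] == 0.0


def test_bootstrap_ci_covers_mean():
    rng = np.random.default_rng(3)
    v = rng.normal(2.0, 1.0, 200)
    lo, hi = bootstrap_ci(v, n_resamples=2000, seed=0)
    assert lo < v.mean() < hi
    assert lo < 2.0 < hi
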