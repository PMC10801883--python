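"""Saccade detection, fixation segmentation, and main-sequence fits."""

import numpy as np
import pandas as pd
import pytest

from gazemorph.io import Condition
from gazemorph.kinematics import (
    MainSequenceRegressor,
    SaccadeDetector,
    compare_main_sequences,
    detect_saccades,
    fit_main_sequence,
    segment_fixations,
    velocity_profile,
)
from gazemorph.synth import GeneratorSpec, generate_face_layout, generate_scanpath

from conftest import make_trial


def _samples(x, y, t=None):
    n = len(x)
    t = np.arange(n) if t is None else t
    return pd.DataFrame(
        {"t_ms": t, "x_dva": x, "y_dva": y, "on_image": np.ones(n, dtype=bool)}
    )


class TestVelocityProfile:
    def test_stationary_trace_speed_zero(self):
        v = velocity_profile(_samples(np.zeros(100), np.zeros(100)))
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_linear_drift_recovers_speed(self):
        t = np.arange(200)
        v = velocity_profile(_samples(0.01 * t, np.zeros(200)))  # 10 dva/s
        np.testing.assert_allclose(v[5:-5], 10.0, rtol=1e-6)

    def test_raised_cosine_peak_recovered_within_5pct(self):
        # analytic profile: v(t) = (Vp/2)(1 - cos(2 pi t / D)), peak Vp
        D, amp = 80, 8.0
        vp_true = 2000.0 * amp / D  # dva/s
        tau = np.arange(0, D + 1) / D
        x = amp * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))
        pad = np.zeros(100)
        xx = np.concatenate([pad, x, np.full(100, amp)])
        v = velocity_profile(_samples(xx, np.zeros(len(xx))))
        assert np.nanmax(v) == pytest.approx(vp_true, rel=0.05)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            velocity_profile(_samples(np.full(10, np.nan), np.full(10, np.nan)))


def _trial_with_saccade(noise_sd=0.005, amp=8.0, onset=2000, dur=70, seed=0):
    rng = np.random.default_rng(seed)
    n_pre, n_view = 1000, 5000
    x = np.zeros(n_pre + n_view)
    tau = np.arange(1, dur + 1) / dur
    prof = amp * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))
    x[n_pre + onset : n_pre + onset + dur] = prof
    x[n_pre + onset + dur :] = amp
    x += rng.normal(0, noise_sd, len(x))
    t = np.arange(-n_pre, n_view)
    return make_trial(t, x, rng.normal(0, noise_sd, len(x)))


class TestSaccadeDetection:
    def test_noiseless_fixation_gives_zero_saccades(self):
        tr = make_trial(np.arange(-1000, 3000), np.zeros(4000), np.zeros(4000))
        with pytest.warns(UserWarning, match="degenerate fixation"):
            evs = detect_saccades(tr.viewing_samples, tr.fixation_samples)
        assert evs == []

    def test_single_saccade_onset_offset_within_5ms(self):
        tr = _trial_with_saccade()
        evs = detect_saccades(tr.viewing_samples, tr.fixation_samples)
        assert len(evs) == 1
        ev = evs[0]
        assert abs(ev.onset_ms - 2000) <= 5
        assert abs(ev.offset_ms - 2069) <= 5
        assert ev.amplitude == pytest.approx(8.0, abs=0.1)

    def test_count_matches_generator_truth(self):
        spec = GeneratorSpec(seed=42)
        rng = np.random.default_rng(42)
        lm, _ = generate_face_layout(spec, 0, rng)
        exact = 0
        n = 100
        for _ in range(n):
            tr, gt = generate_scanpath(spec, lm, Condition(), rng)
            evs = detect_saccades(tr.viewing_samples, tr.fixation_samples)
            exact += len(evs) == len(gt.saccades)
        assert exact / n >= 0.95

    def test_intervals_disjoint_ordered_and_shift_invariant(self):
        tr = _trial_with_saccade(seed=1)
        evs = detect_saccades(tr.viewing_samples, tr.fixation_samples)
        for a, b in zip(evs, evs[1:]):
            assert a.offset_ms < b.onset_ms
        shifted = tr.samples.copy()
        shifted["t_ms"] = shifted["t_ms"] + 12345
        det = SaccadeDetector().fit(shifted[shifted["t_ms"] < 12345])
        evs2 = det.detect(shifted[shifted["t_ms"] >= 12345])
        assert [(e.onset_ms - 12345, e.offset_ms - 12345) for e in evs2] == [
            (e.onset_ms, e.offset_ms) for e in evs
        ]

    def test_amplitude_translation_invariant(self):
        tr = _trial_with_saccade(seed=2)
        evs = detect_saccades(tr.viewing_samples, tr.fixation_samples)
        moved = tr.samples.copy()
        moved["x_dva"] += 3.0
        moved["y_dva"] -= 2.0
        det = SaccadeDetector().fit(moved[moved["t_ms"] < 0])
        evs2 = det.detect(moved[moved["t_ms"] >= 0])
        assert len(evs) == len(evs2)
        for a, b in zip(evs, evs2):
            assert a.amplitude == pytest.approx(b.amplitude, abs=1e-9)

    def test_error_rates_monotone_in_noise(self):
        spec0 = GeneratorSpec(seed=9)
        rng = np.random.default_rng(9)
        lm, _ = generate_face_layout(spec0, 0, rng)
        mismatch = []
        for noise in (0.02, 0.12, 0.35):
            spec = GeneratorSpec(seed=9, gaze_noise_sd=noise)
            bad = 0
            n = 25
            for _ in range(n):
                tr, gt = generate_scanpath(spec, lm, Condition(), rng)
                evs = detect_saccades(tr.viewing_samples, tr.fixation_samples)
                bad += abs(len(evs) - len(gt.saccades))
            mismatch.append(bad / n)
        assert mismatch[0] <= mismatch[1] <= mismatch[2]


class TestFixationSegments:
    def test_no_saccades_one_segment(self):
        tr = make_trial(np.arange(2000), np.full(2000, 1.5), np.full(2000, -0.5))
        segs = segment_fixations(tr.samples, [])
        assert len(segs) == 1
        assert segs[0].centroid == pytest.approx((1.5, -0.5))

    def test_one_saccade_two_segments(self):
        tr = _trial_with_saccade()
        evs = detect_saccades(tr.viewing_samples, tr.fixation_samples)
        segs = segment_fixations(tr.viewing_samples, evs)
        assert len(segs) == 2
        assert segs[0].end_ms < evs[0].onset_ms
        assert segs[1].start_ms > evs[0].offset_ms


class TestMainSequence:
    def test_exact_linear_data(self):
        fit = MainSequenceRegressor().fit([1.0, 5.0, 10.0], [30.0, 150.0, 300.0])
        assert fit.beta_ == pytest.approx(30.0)
        assert fit.r_squared_ == pytest.approx(1.0)
        fit2 = MainSequenceRegressor().fit([10.0, 20.0], [300.0, 600.0])
        assert fit2.beta_ == pytest.approx(30.0)

    def test_slope_equals_independent_least_squares(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(1, 12, 500)
        PV = 30.0 * A * (1 + rng.normal(0, 0.15, 500))
        reg = MainSequenceRegressor().fit(A, PV)
        # independent oracle: through-origin normal equations via lstsq
        slope = np.linalg.lstsq(A[:, None], PV, rcond=None)[0][0]
        assert reg.beta_ == pytest.approx(slope, abs=1e-9)
        assert reg.beta_ == pytest.approx(30.0, rel=0.02)

    def test_all_zero_amplitude_raises(self):
        with pytest.raises(ValueError):
            MainSequenceRegressor().fit([0.0, 0.0], [1.0, 2.0])

    def test_compare_identical_groups_null(self):
        from gazemorph.kinematics import SaccadeEvent

        rng = np.random.default_rng(1)
        def mk(beta, n, rng):
            out = []
            for _ in range(n):
                a = rng.uniform(1, 10)
                out.append(
                    SaccadeEvent(0, 10, a, beta * a * (1 + rng.normal(0, 0.1)), (0, 0), (a, 0), 0.0)
                )
            return out

        g = mk(30, 50, rng)
        res = compare_main_sequences(g, list(g), n_resamples=500, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_perm > 0.9

        ga = mk(30, 200, rng)
        gb = mk(45, 200, rng)
        res2 = compare_main_sequences(ga, gb, n_resamples=2000, seed=0)
        assert res2.p_perm < 0.01
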