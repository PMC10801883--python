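"""Saccade/fixation segmentation and main-sequence analysis.

Saccades are detected with a velocity threshold referenced to the trial's
own pre-stimulus fixation: with m and s the median and SD of eye speed in
the 1-s central fixation, samples exceeding ``m + k_on * s`` (default
k_on = 6) seed candidate saccades, which are then extended to the nearest
samples where speed falls below ``m + k_off * s`` (default k_off = 2).

The main sequence is the stereotyped amplitude/peak-velocity law; here it
is modeled as the through-origin regression ``PV = beta * A`` whose
least-squares slope has the closed form ``beta = sum(A*PV) / sum(A^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from gazemorph.io import bridge_gaps

__all__ = [
    "SaccadeEvent",
    "FixationSegment",
    "MainSequenceFit",
    "SaccadeDetector",
    "MainSequenceRegressor",
    "velocity_profile",
    "detect_saccades",
    "segment_fixations",
    "fit_main_sequence",
    "compare_main_sequences",
]


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade.

    Amplitude is the Euclidean start-to-end displacement in dva; peak
    velocity is the maximum eye speed within the event in dva/s.
    """

    onset_ms: int
    offset_ms: int
    amplitude: float
    peak_velocity: float
    start_point: tuple[float, float]
    end_point: tuple[float, float]
    direction: float  # radians, atan2(dy, dx)

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class FixationSegment:
    start_ms: int
    end_ms: int
    centroid: tuple[float, float]

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class MainSequenceFit:
    beta: float
    r_squared: float
    n_saccades: int


def velocity_profile(samples: pd.DataFrame, smooth_ms: int = 5) -> np.ndarray:
    """Per-sample eye speed in dva/s.

    Positions are smoothed with a centered ``smooth_ms``-sample moving
    average, then differentiated with central differences (one-sided at the
    trace ends).  Any window or difference touching a missing sample yields
    NaN, so speeds adjacent to dropouts are undefined rather than invented.
    """
    if len(samples) < 3:
        raise ValueError("velocity profile needs at least 3 samples")
    t = samples["t_ms"].to_numpy(dtype=float)
    xy = samples[["x_dva", "y_dva"]].to_numpy(dtype=float)
    if np.all(np.isnan(xy[:, 0])):
        raise ValueError("all samples missing; no velocity defined")

    if smooth_ms > 1:
        w = int(smooth_ms)
        kernel = np.ones(w) / w
        sm = np.empty_like(xy)
        for k in (0, 1):
            # 'same' convolution propagates NaN through any touched window;
            # edges are averaged over the available (zero-padded) extent,
            # corrected by the actual kernel mass.
            mass = np.convolve(np.ones(len(xy)), kernel, mode="same")
            sm[:, k] = np.convolve(xy[:, k], kernel, mode="same") / mass
    else:
        sm = xy

    n = len(sm)
    v = np.full((n, 2), np.nan)
    dt_c = (t[2:] - t[:-2]) / 1000.0  # s
    v[1:-1] = (sm[2:] - sm[:-2]) / dt_c[:, None]
    v[0] = (sm[1] - sm[0]) / ((t[1] - t[0]) / 1000.0)
    v[-1] = (sm[-1] - sm[-2]) / ((t[-1] - t[-2]) / 1000.0)
    return np.hypot(v[:, 0], v[:, 1])


class SaccadeDetector(BaseEstimator):
    """Median + k*SD velocity-threshold saccade detector.

    ``fit`` estimates the fixation-noise velocity statistics (median and SD
    of speed) from pre-stimulus fixation samples; ``detect`` segments a
    trace into saccade events against those thresholds.

    Parameters
    ----------
    k_on : onset threshold multiplier (median + k_on * SD), default 6.
    k_off : event-extension multiplier (median + k_off * SD), default 2.
    min_duration_ms : discard events shorter than this, default 8.
    merge_gap_ms : merge events separated by at most this gap, default 10.
    smooth_ms : moving-average window for the velocity estimator, default 5.
    abs_floor_dva_s : absolute onset-threshold floor used when the fixation
        window is degenerate (zero speed variance), default 30 dva/s.
    min_fixation_samples : required valid fixation speed samples, default 100.
    """

    def __init__(
        self,
        k_on: float = 6.0,
        k_off: float = 2.0,
        min_duration_ms: int = 8,
        merge_gap_ms: int = 10,
        smooth_ms: int = 5,
        abs_floor_dva_s: float = 30.0,
        min_fixation_samples: int = 100,
    ):
        self.k_on = k_on
        self.k_off = k_off
        self.min_duration_ms = min_duration_ms
        self.merge_gap_ms = merge_gap_ms
        self.smooth_ms = smooth_ms
        self.abs_floor_dva_s = abs_floor_dva_s
        self.min_fixation_samples = min_fixation_samples

    def fit(self, fixation_samples: pd.DataFrame, y=None) -> "SaccadeDetector":
        """Estimate fixation-speed median and SD from pre-stimulus samples."""
        v = velocity_profile(fixation_samples, smooth_ms=self.smooth_ms)
        v = v[np.isfinite(v)]
        if len(v) < self.min_fixation_samples:
            raise ValueError(
                f"fixation window has {len(v)} valid samples; "
                f"need >= {self.min_fixation_samples}"
            )
        self.median_ = float(np.median(v))
        self.sd_ = float(np.std(v))
        if self.sd_ == 0.0:
            import warnings

            warnings.warn(
                "degenerate fixation window (zero speed variance); "
                "falling back to absolute velocity floor",
                stacklevel=2,
            )
            self.threshold_on_ = self.abs_floor_dva_s
            self.threshold_off_ = self.abs_floor_dva_s / 3.0
        else:
            self.threshold_on_ = self.median_ + self.k_on * self.sd_
            self.threshold_off_ = self.median_ + self.k_off * self.sd_
        return self

    def detect(self, samples: pd.DataFrame) -> list[SaccadeEvent]:
        """Segment a trace into saccade events using the fitted thresholds."""
        if not hasattr(self, "threshold_on_"):
            raise RuntimeError("detector not fitted; call fit on the fixation window first")
        v = velocity_profile(samples, smooth_ms=self.smooth_ms)
        t = samples["t_ms"].to_numpy()
        xy = samples[["x_dva", "y_dva"]].to_numpy(dtype=float)
        valid = np.isfinite(v)
        above_on = valid & (v > self.threshold_on_)
        above_off = valid & (v >= self.threshold_off_)

        # seed runs above the onset threshold, then extend through samples
        # still above the offset threshold (never across invalid samples)
        intervals: list[tuple[int, int]] = []
        n = len(v)
        i = 0
        while i < n:
            if not above_on[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and above_on[j + 1]:
                j += 1
            a = i
            while a - 1 >= 0 and above_off[a - 1]:
                a -= 1
            b = j
            while b + 1 < n and above_off[b + 1]:
                b += 1
            intervals.append((a, b))
            i = b + 1

        # merge events separated by at most merge_gap_ms
        merged: list[tuple[int, int]] = []
        for a, b in intervals:
            if merged and t[a] - t[merged[-1][1]] <= self.merge_gap_ms:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))

        events: list[SaccadeEvent] = []
        for a, b in merged:
            if t[b] - t[a] < self.min_duration_ms:
                continue
            if np.any(~np.isfinite(xy[a])) or np.any(~np.isfinite(xy[b])):
                continue
            dx = xy[b, 0] - xy[a, 0]
            dy = xy[b, 1] - xy[a, 1]
            seg_v = v[a : b + 1]
            pv = float(np.nanmax(seg_v)) if np.any(np.isfinite(seg_v)) else 0.0
            events.append(
                SaccadeEvent(
                    onset_ms=int(t[a]),
                    offset_ms=int(t[b]),
                    amplitude=float(np.hypot(dx, dy)),
                    peak_velocity=pv,
                    start_point=(float(xy[a, 0]), float(xy[a, 1])),
                    end_point=(float(xy[b, 0]), float(xy[b, 1])),
                    direction=float(np.arctan2(dy, dx)),
                )
            )
        return events

    # alias so the estimator composes with transformer-style call sites
    transform = detect


def detect_saccades(
    samples: pd.DataFrame,
    fixation_samples: pd.DataFrame,
    k_on: float = 6.0,
    k_off: float = 2.0,
    **kwargs,
) -> list[SaccadeEvent]:
    """Fit thresholds on the fixation window and detect saccades in a trace."""
    det = SaccadeDetector(k_on=k_on, k_off=k_off, **kwargs)
    det.fit(fixation_samples)
    return det.detect(samples)


def segment_fixations(
    samples: pd.DataFrame,
    saccades: list[SaccadeEvent],
    max_gap_ms: int = 500,
) -> list[FixationSegment]:
    """Complement of the saccade intervals within on-image viewing time.

    Segments are split at non-bridged gaps (dropouts / off-image runs of
    blink scale or longer); the centroid is the mean gaze over the segment's
    valid samples.
    """
    ann = bridge_gaps(samples, max_gap_ms=max_gap_ms)
    t = ann["t_ms"].to_numpy()
    viewing = ann["viewing"].to_numpy()
    in_saccade = np.zeros(len(ann), dtype=bool)
    for ev in saccades:
        in_saccade |= (t >= ev.onset_ms) & (t <= ev.offset_ms)
    fix_mask = viewing & ~in_saccade

    from gazemorph.io import _runs

    xy = ann[["x_dva", "y_dva"]].to_numpy(dtype=float)
    segments: list[FixationSegment] = []
    for a, b in _runs(fix_mask):
        if b - a < 2:
            continue
        cx = float(np.nanmean(xy[a:b, 0]))
        cy = float(np.nanmean(xy[a:b, 1]))
        segments.append(FixationSegment(start_ms=int(t[a]), end_ms=int(t[b - 1]), centroid=(cx, cy)))
    return segments


class MainSequenceRegressor(RegressorMixin, BaseEstimator):
    """Through-origin main-sequence regression PV = beta * A.

    The slope has the closed form ``beta = sum(A*PV) / sum(A^2)``.  R^2 is
    computed about the mean of PV (not about zero), the conservative
    convention for a through-origin model.
    """

    def fit(self, X, y) -> "MainSequenceRegressor":
        A = np.asarray(X, dtype=float).reshape(-1)
        PV = np.asarray(y, dtype=float).reshape(-1)
        if len(A) != len(PV) or len(A) < 2:
            raise ValueError("need at least 2 (amplitude, peak velocity) pairs")
        if np.all(A == 0):
            raise ValueError("all amplitudes are zero; slope undefined")
        self.beta_ = float(np.sum(A * PV) / np.sum(A * A))
        resid = PV - self.beta_ * A
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((PV - PV.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_saccades_ = int(len(A))
        return self

    def predict(self, X) -> np.ndarray:
        A = np.asarray(X, dtype=float).reshape(-1)
        return self.beta_ * A


def _amp_pv(saccades) -> tuple[np.ndarray, np.ndarray]:
    A = np.array([s.amplitude for s in saccades], dtype=float)
    PV = np.array([s.peak_velocity for s in saccades], dtype=float)
    keep = (A > 0) & np.isfinite(PV)
    return A[keep], PV[keep]


def fit_main_sequence(saccades) -> MainSequenceFit:
    """Fit PV = beta * A to a set of saccade events."""
    A, PV = _amp_pv(saccades)
    reg = MainSequenceRegressor().fit(A, PV)
    return MainSequenceFit(beta=reg.beta_, r_squared=reg.r_squared_, n_saccades=reg.n_saccades_)


def compare_main_sequences(
    saccades_a,
    saccades_b,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator = 0,
):
    """Permutation test on the difference of main-sequence slopes.

    Saccade group labels are permuted; the statistic is
    ``beta_a - beta_b`` computed by the closed-form slope in each group.
    Returns a :class:`gazemorph.stats.StatResult`.
    """
    from gazemorph.stats import StatResult, _two_sided_p

    Aa, Pa = _amp_pv(saccades_a)
    Ab, Pb = _amp_pv(saccades_b)
    if len(Aa) < 2 or len(Ab) < 2:
        raise ValueError("both groups need >= 2 saccades with positive amplitude")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def delta_beta(A1, P1, A2, P2):
        return np.sum(A1 * P1) / np.sum(A1 * A1) - np.sum(A2 * P2) / np.sum(A2 * A2)

    observed = float(delta_beta(Aa, Pa, Ab, Pb))
    A = np.concatenate([Aa, Ab])
    PV = np.concatenate([Pa, Pb])
    na = len(Aa)
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        perm = rng.permutation(len(A))
        ia, ib = perm[:na], perm[na:]
        null[i] = delta_beta(A[ia], PV[ia], A[ib], PV[ib])
    p = _two_sided_p(observed, null)
    return StatResult(observed=observed, p_perm=p, n_resamples=n_resamples)
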