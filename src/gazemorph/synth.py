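"""Synthetic free-viewing experiments with ground truth.

The generator emulates the statistical structure of macaque free viewing of
face images at 1,000 Hz:

* 26-landmark face layouts (a fixed template plus per-image shape jitter
  and a per-image position offset), each with a left-right mirrored twin;
* scanpaths alternating fixations and saccades: fixation targets are drawn
  from ROI saliency weights producing the Yarbus-T concentration on eyes,
  nose and mouth; saccade speed follows a raised-cosine profile whose peak
  obeys the main sequence PV = beta * A with multiplicative noise;
* a configurable observer-referenced right-eye baseline bias and, for
  injection conditions, an extra ipsilateral-eye effect calibrated in
  seconds of expected dwell difference per trial;
* blink gaps (< 500 ms of missing samples) and additive gaze noise;
* session/condition counts shaped like the study design (8 injection
  condition combinations: site x hemisphere x volume), with baseline
  sessions interleaved so every injection session has baselines within
  +/-31 days.

Every trial carries ground truth: the emitted saccade events, per-trial eye
ROI dwell counted directly off the emitted samples, and the per-condition
programmed effect.  All randomness flows from ``GeneratorSpec.seed``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

from gazemorph.io import (
    LANDMARK_LABELS,
    Condition,
    LandmarkSet,
    RoiRect,
    Trial,
    mirror_landmarks,
)
from gazemorph.kinematics import SaccadeEvent

__all__ = [
    "ConditionSpec",
    "GeneratorSpec",
    "GroundTruth",
    "Experiment",
    "face_template",
    "generate_face_layout",
    "generate_scanpath",
    "generate_experiment",
    "eye_rois_from_landmarks",
]

#: landmark template: a frontal primate-like face, screen-centered dva.
_TEMPLATE: dict[str, tuple[float, float]] = {
    "left_temple": (-5.5, 5.0),
    "right_temple": (5.5, 5.0),
    "left_cheek": (-6.0, 0.0),
    "right_cheek": (6.0, 0.0),
    "left_jaw": (-4.0, -5.5),
    "right_jaw": (4.0, -5.5),
    "forehead_center": (0.0, 7.5),
    "chin": (0.0, -7.0),
    "left_brow_center": (-3.0, 4.0),
    "right_brow_center": (3.0, 4.0),
    "left_eye_outer": (-4.0, 2.5),
    "left_eye_inner": (-2.0, 2.5),
    "left_eye_top": (-3.0, 3.1),
    "left_eye_bottom": (-3.0, 1.9),
    "right_eye_outer": (4.0, 2.5),
    "right_eye_inner": (2.0, 2.5),
    "right_eye_top": (3.0, 3.1),
    "right_eye_bottom": (3.0, 1.9),
    "nose_bridge": (0.0, 2.0),
    "nose_tip": (0.0, -0.5),
    "nose_left": (-1.0, -1.0),
    "nose_right": (1.0, -1.0),
    "mouth_left": (-1.8, -3.5),
    "mouth_right": (1.8, -3.5),
    "mouth_top": (0.0, -3.0),
    "mouth_bottom": (0.0, -4.2),
}

_OUTLINE = (
    "forehead_center",
    "right_temple",
    "right_cheek",
    "right_jaw",
    "chin",
    "left_jaw",
    "left_cheek",
    "left_temple",
)

#: eye-ROI size rule: square of side roi_scale * inter-corner eye width
EYE_ROI_SCALE = 1.6


def face_template() -> np.ndarray:
    """The canonical 26-point face template in canonical label order."""
    return np.array([_TEMPLATE[label] for label in LANDMARK_LABELS], dtype=float)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition with its session count and programmed
    ipsilateral-eye effect (expected extra dwell on the ipsi eye, seconds)."""

    site: str
    hemisphere: str
    volume_ul: int
    n_sessions: int
    ipsi_effect_s: float

    @property
    def condition(self) -> Condition:
        return Condition(
            phase="injection",
            site=self.site,
            hemisphere=self.hemisphere,
            volume_ul=self.volume_ul,
        )


def _default_conditions() -> tuple[ConditionSpec, ...]:
    """Injection grid shaped like the study design (one animal's counts):
    face patch and control sites, both hemispheres, 5 and 10 uL."""
    return (
        ConditionSpec("face_patch", "left", 10, 4, 1.4),
        ConditionSpec("face_patch", "right", 10, 4, 1.4),
        ConditionSpec("control", "left", 10, 5, 0.25),
        ConditionSpec("control", "right", 10, 6, 0.25),
        ConditionSpec("face_patch", "left", 5, 3, 0.0),
        ConditionSpec("face_patch", "right", 5, 3, 0.0),
        ConditionSpec("control", "left", 5, 2, 0.0),
        ConditionSpec("control", "right", 5, 1, 0.0),
    )


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic experiment.

    Defaults mirror the study conditions: 28 x 21 dva images shown for 10 s
    at 1,000 Hz, mirrored image pairs, a ~1.1-s observer-right-eye baseline
    bias, a 1.4-s face-patch 10-uL ipsilateral effect, and main-sequence
    slope beta = 30 (dva/s per dva).  ``roi_weights`` are relative saliency
    weights for fixation-target placement (eyes/nose/mouth/other-face/
    off-face); the eye weights are tilted to realize the programmed biases.
    """

    seed: int = 0
    n_images: int = 8  # unique images; mirrored twins double the set
    image_extent: tuple[float, float] = (28.0, 21.0)
    shape_jitter_sd: float = 0.3
    # faces are placed off-center (up to +/-7 dva horizontally) so the face
    # does not always cover the central fixation point and the initial
    # saccade-to-face latency is a real quantity on a fraction of trials
    center_offset_range: tuple[float, float] = (7.0, 1.5)
    roi_weights: dict = field(
        default_factory=lambda: {
            "left_eye": 1.5,
            "right_eye": 1.5,
            "nose": 1.8,
            "mouth": 1.2,
            "face_other": 1.2,
            # faces dominate looking time in face trials (>96% of dwell)
            "off_face": 0.25,
        }
    )
    right_eye_baseline_bias_s: float = 1.1
    conditions: tuple[ConditionSpec, ...] = field(default_factory=_default_conditions)
    n_baseline_sessions: int = 14
    trials_per_session: int = 10
    fixation_median_ms: float = 320.0
    fixation_sigma_log: float = 0.4
    main_sequence_beta: float = 30.0
    velocity_noise_sd: float = 0.15
    gaze_noise_sd: float = 0.02
    blink_rate_per_trial: float = 0.5
    blink_dur_range_ms: tuple[int, int] = (150, 450)
    sampling_hz: int = 1000
    trial_len_s: float = 10.0
    min_saccade_dva: float = 1.5

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.roi_weights.values()) or sum(self.roi_weights.values()) <= 0:
            raise ValueError("roi weights must be >= 0 with positive sum")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")


@dataclass
class GroundTruth:
    """Per-trial generator truth for downstream oracles."""

    saccades: list[SaccadeEvent]
    dwell_right_eye_s: float
    dwell_left_eye_s: float
    dwell_face_s: float
    target_delta_rl_s: float  # programmed E[right - left] dwell for the trial
    beta: float


@dataclass
class Experiment:
    """A complete synthetic dataset."""

    trials: list[Trial]
    landmarks: dict[str, LandmarkSet]
    rois_by_image: dict[str, dict[str, RoiRect]]
    design: pd.DataFrame  # one row per session
    ground_truth: dict[str, GroundTruth]  # by trial_id
    spec: GeneratorSpec


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------


def eye_rois_from_landmarks(points: np.ndarray, scale: float = EYE_ROI_SCALE) -> dict[str, RoiRect]:
    """Square eye ROIs centered on the eye landmarks.

    The side equals ``scale`` times the inter-corner eye width, the default
    rule for the mean-face eye rectangles.
    """

    def roi(prefix: str) -> RoiRect:
        idx = [LANDMARK_LABELS.index(f"{prefix}_{p}") for p in ("outer", "inner", "top", "bottom")]
        pts = points[idx]
        cx, cy = pts.mean(axis=0)
        width = abs(pts[0, 0] - pts[1, 0])
        half = scale * width / 2.0
        return RoiRect(f"{prefix}", cx - half, cx + half, cy - half, cy + half)

    return {"left_eye": roi("left_eye"), "right_eye": roi("right_eye")}


def _polygon_from(points: np.ndarray) -> np.ndarray:
    return np.array([points[LANDMARK_LABELS.index(lbl)] for lbl in _OUTLINE])


def generate_face_layout(
    spec: GeneratorSpec, image_index: int, rng: np.random.Generator
) -> tuple[LandmarkSet, LandmarkSet]:
    """One jittered face layout and its mirrored twin.

    The layout is the template plus a per-image center offset and i.i.d.
    landmark jitter; geometry that degenerates (self-intersecting face
    outline) is resampled up to a retry cap.
    """
    image_id = f"img{image_index:03d}"
    for _ in range(20):
        offset = np.array(
            [
                rng.uniform(-spec.center_offset_range[0], spec.center_offset_range[0]),
                rng.uniform(-spec.center_offset_range[1], spec.center_offset_range[1]),
            ]
        )
        points = face_template() + offset + rng.normal(0.0, spec.shape_jitter_sd, size=(26, 2))
        points = np.round(points, 4)
        poly = _polygon_from(points)
        if _ShapelyPolygon(poly).is_valid:
            lm = LandmarkSet(image_id=image_id, points=points, face_polygon=poly)
            twin = mirror_landmarks(lm, image_id=image_id + "m")
            return lm, twin
    raise RuntimeError(f"image {image_index}: could not generate a simple face outline")


# ---------------------------------------------------------------------------
# scanpaths
# ---------------------------------------------------------------------------


def _time_shares(
    spec: GeneratorSpec, condition: Condition, ipsi_effect_s: float | None = None
) -> dict[str, float]:
    """Target share of trial time per ROI, realizing the programmed biases.

    Fixation visits are drawn so each ROI's expected share of attributed
    trial time equals its share here; the programmed observer-referenced
    dwell difference (baseline bias plus the signed ipsi effect) converts
    to a share tilt of ``delta = target_s / (2 * trial_len_s)`` between the
    two eyes.
    """
    w = dict(spec.roi_weights)
    total = sum(w.values())
    p = {k: v / total for k, v in w.items()}
    target = _target_delta_rl(spec, condition, ipsi_effect_s)
    delta = target / (2.0 * spec.trial_len_s)
    p_re = p["right_eye"] + delta
    p_le = p["left_eye"] - delta
    if p_le < 0.01 or p_re < 0.01:
        raise ValueError("programmed eye bias too large for the ROI weights")
    rest = 1.0 - p_re - p_le
    rest0 = 1.0 - p["right_eye"] - p["left_eye"]
    out = {k: v * rest / rest0 for k, v in p.items() if k not in ("left_eye", "right_eye")}
    out["right_eye"] = p_re
    out["left_eye"] = p_le
    return out


def _visit_probabilities(shares: dict[str, float]) -> dict[str, float]:
    """Invert the no-repeat visit chain so stationary shares match targets.

    Successive fixation ROIs are drawn without immediate repeats with
    transition probability ``q(j -> k) = p_k / (1 - p_j)``; the stationary
    visit distribution is then proportional to ``p_k (1 - p_k)``.  This
    solves ``p_k (1 - p_k) = lambda * s_k`` for p by fixed-point iteration
    so that realized time shares equal the requested ``shares``.
    """
    names = sorted(shares)
    s = np.array([shares[k] for k in names], dtype=float)
    s = s / s.sum()
    p = s.copy()
    for _ in range(200):
        p_new = s / (1.0 - p)
        p_new = p_new / p_new.sum()
        if np.max(np.abs(p_new - p)) < 1e-12:
            p = p_new
            break
        p = p_new
    pi = p * (1.0 - p)
    pi = pi / pi.sum()
    if np.max(np.abs(pi - s)) > 1e-6:
        raise ValueError("programmed ROI shares too concentrated for the visit chain")
    return dict(zip(names, p))


def _target_delta_rl(spec: GeneratorSpec, condition: Condition, ipsi_effect_s: float | None = None) -> float:
    """Programmed observer-referenced E[right - left] dwell (seconds)."""
    delta = spec.right_eye_baseline_bias_s
    if condition.phase == "injection":
        if ipsi_effect_s is None:
            ipsi_effect_s = next(
                (
                    c.ipsi_effect_s
                    for c in spec.conditions
                    if c.condition == condition
                ),
                0.0,
            )
        delta += ipsi_effect_s if condition.hemisphere == "right" else -ipsi_effect_s
    return delta


def _sample_target(
    roi: str,
    landmarks: LandmarkSet,
    rng: np.random.Generator,
    spec: GeneratorSpec,
) -> np.ndarray:
    """Draw a fixation target for an ROI in the image's own frame.

    Eye targets use a clipped Gaussian confined well inside the eye ROI so
    dwell programmed for an eye is actually counted there; off-face targets
    are rejection-sampled outside the face outline.
    """
    pts = landmarks.points

    def center(labels) -> np.ndarray:
        return np.mean([landmarks.point(l) for l in labels], axis=0)

    if roi in ("left_eye", "right_eye"):
        # kept well inside the eye ROI so programmed eye dwell is counted
        # there even after piecewise-affine distortion of jittered faces
        c = center([f"{roi}_{p}" for p in ("outer", "inner", "top", "bottom")])
        t = c + rng.normal(0.0, 0.5, size=2)
        return np.clip(t, c - 1.0, c + 1.0)
    if roi == "nose":
        c = center(["nose_bridge", "nose_tip", "nose_left", "nose_right"])
        t = c + rng.normal(0.0, 0.6, size=2)
        return np.clip(t, c - 1.0, c + 1.0)
    if roi == "mouth":
        c = center(["mouth_left", "mouth_right", "mouth_top", "mouth_bottom"])
        t = c + rng.normal(0.0, 0.6, size=2)
        return np.clip(t, c - 1.1, c + 1.1)
    if roi == "face_other":
        anchors = ["forehead_center", "left_cheek", "right_cheek", "chin"]
        c = landmarks.point(anchors[rng.integers(len(anchors))])
        # pull anchors toward the face interior and keep scatter off the eyes
        interior = c + 0.25 * (center(["nose_tip"]) - c)
        t = interior + rng.normal(0.0, 0.4, size=2)
        return t
    if roi == "off_face":
        from matplotlib.path import Path as _P

        path = _P(landmarks.face_polygon)
        w, h = spec.image_extent
        for _ in range(100):
            t = np.array([rng.uniform(-w / 2 + 1, w / 2 - 1), rng.uniform(-h / 2 + 1, h / 2 - 1)])
            if not path.contains_point(t):
                return t
        return np.array([w / 2 - 2.0, h / 2 - 2.0])
    raise ValueError(f"unknown roi {roi}")


def _lognormal_duration_ms(spec: GeneratorSpec, rng: np.random.Generator) -> int:
    d = rng.lognormal(np.log(spec.fixation_median_ms), spec.fixation_sigma_log)
    return int(np.clip(d, 80, 1500))


def generate_scanpath(
    spec: GeneratorSpec,
    layout: LandmarkSet,
    condition: Condition,
    rng: np.random.Generator,
    trial_id: str = "t000",
    monkey_id: str = "M1",
    session_id: str = "S000",
    session_date: _dt.date = _dt.date(2022, 1, 3),
    ipsi_effect_s: float | None = None,
) -> tuple[Trial, GroundTruth]:
    """Generate one trial and its ground truth.

    The trial covers the 1-s pre-stimulus central fixation ([-1000, 0) ms)
    followed by ``trial_len_s`` seconds of free viewing; positions are at
    1 ms resolution with additive Gaussian gaze noise, rounded to the I/O
    precision so file round trips are exact.
    """
    n_pre = 1000
    n_view = int(round(spec.trial_len_s * spec.sampling_hz))
    shares = _time_shares(spec, condition, ipsi_effect_s)
    visit_p = _visit_probabilities(shares)
    roi_names = sorted(shares)
    share_p = np.array([shares[k] for k in roi_names])
    chain_p = np.array([visit_p[k] for k in roi_names])

    xs = np.empty(n_view)
    ys = np.empty(n_view)
    truth_saccades: list[SaccadeEvent] = []

    pos = np.zeros(2)  # gaze starts at the central fixation point
    t = 0
    # initial latency fixation at the center before the first saccade
    latency = int(rng.uniform(200, 400))
    end = min(latency, n_view)
    xs[:end] = pos[0]
    ys[:end] = pos[1]
    t = end

    sacc_dur_nominal_ms = 2000.0 / spec.main_sequence_beta
    current_roi: int | None = None
    while t < n_view:
        remaining = n_view - t
        if remaining < sacc_dur_nominal_ms + 50:
            xs[t:] = pos[0]
            ys[t:] = pos[1]
            t = n_view
            break
        # no-repeat visit chain: successive fixations target distinct ROIs
        if current_roi is None:
            k = rng.choice(len(roi_names), p=share_p)
        else:
            q = chain_p.copy()
            q[current_roi] = 0.0
            q /= q.sum()
            k = rng.choice(len(roi_names), p=q)
        roi = roi_names[k]
        target = None
        for _ in range(50):
            cand = _sample_target(roi, layout, rng, spec)
            if np.linalg.norm(cand - pos) >= spec.min_saccade_dva:
                target = cand
                break
        if target is None:
            # current gaze sits inside the chosen ROI; hold fixation instead
            dur = min(_lognormal_duration_ms(spec, rng), remaining)
            xs[t : t + dur] = pos[0]
            ys[t : t + dur] = pos[1]
            t += dur
            continue

        amp = float(np.linalg.norm(target - pos))
        pv = spec.main_sequence_beta * amp * (1.0 + rng.normal(0.0, spec.velocity_noise_sd))
        pv = max(pv, 1e-3)
        dur_ms = max(int(round(2000.0 * amp / pv)), 10)
        if dur_ms > remaining - 20:
            xs[t:] = pos[0]
            ys[t:] = pos[1]
            t = n_view
            break
        tau = np.arange(1, dur_ms + 1) / dur_ms
        s = amp * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))
        direction = (target - pos) / amp
        xs[t : t + dur_ms] = pos[0] + direction[0] * s
        ys[t : t + dur_ms] = pos[1] + direction[1] * s
        true_pv = 2000.0 * amp / dur_ms  # peak of the raised-cosine profile, dva/s
        truth_saccades.append(
            SaccadeEvent(
                onset_ms=t,
                offset_ms=t + dur_ms - 1,
                amplitude=amp,
                peak_velocity=true_pv,
                start_point=(float(pos[0]), float(pos[1])),
                end_point=(float(target[0]), float(target[1])),
                direction=float(np.arctan2(direction[1], direction[0])),
            )
        )
        t += dur_ms
        pos = target.copy()
        current_roi = k
        dur = min(_lognormal_duration_ms(spec, rng), n_view - t)
        xs[t : t + dur] = pos[0]
        ys[t : t + dur] = pos[1]
        t += dur

    # additive gaze noise over the whole viewing period
    xs += rng.normal(0.0, spec.gaze_noise_sd, size=n_view)
    ys += rng.normal(0.0, spec.gaze_noise_sd, size=n_view)

    # blink gaps: missing samples, each strictly shorter than 500 ms,
    # placed away from true saccades so detection truth stays intact
    missing = np.zeros(n_view, dtype=bool)
    n_blinks = rng.poisson(spec.blink_rate_per_trial)
    sacc_spans = [(ev.onset_ms, ev.offset_ms) for ev in truth_saccades]
    for _ in range(n_blinks):
        dur = int(rng.integers(spec.blink_dur_range_ms[0], spec.blink_dur_range_ms[1]))
        start = int(rng.integers(500, n_view - dur - 500))
        span = (start - 10, start + dur + 10)
        if any(a <= span[1] and b >= span[0] for a, b in sacc_spans):
            continue
        missing[start : start + dur] = True

    # assemble the full sample table (pre-stimulus fixation + viewing)
    t_ms = np.arange(-n_pre, n_view, dtype=np.int64)
    x = np.concatenate([rng.normal(0.0, spec.gaze_noise_sd, size=n_pre), xs])
    y = np.concatenate([rng.normal(0.0, spec.gaze_noise_sd, size=n_pre), ys])
    x = np.round(x, 4)
    y = np.round(y, 4)
    w, h = spec.image_extent
    on_image = (
        (t_ms >= 0)
        & (np.abs(x) <= w / 2)
        & (np.abs(y) <= h / 2)
    )
    x_out = x.copy()
    y_out = y.copy()
    view_missing = np.concatenate([np.zeros(n_pre, dtype=bool), missing])
    x_out[view_missing] = np.nan
    y_out[view_missing] = np.nan
    on_image = on_image & ~view_missing
    samples = pd.DataFrame({"t_ms": t_ms, "x_dva": x_out, "y_dva": y_out, "on_image": on_image})

    trial = Trial(
        trial_id=trial_id,
        monkey_id=monkey_id,
        session_id=session_id,
        session_date=session_date,
        condition=condition,
        image_id=layout.image_id,
        image_extent=spec.image_extent,
        samples=samples,
        fixation_window=(-n_pre, 0),
    )

    # ground-truth dwell counted directly off the emitted viewing samples
    rois = eye_rois_from_landmarks(layout.points)
    vmask = (t_ms >= 0) & ~np.isnan(x_out)
    inside_r = rois["right_eye"].contains(x_out[vmask], y_out[vmask])
    inside_l = rois["left_eye"].contains(x_out[vmask], y_out[vmask])
    from matplotlib.path import Path as _P

    on_face = _P(layout.face_polygon).contains_points(
        np.column_stack([x_out[vmask], y_out[vmask]])
    )
    truth = GroundTruth(
        saccades=truth_saccades,
        dwell_right_eye_s=float(inside_r.sum()) / 1000.0,
        dwell_left_eye_s=float(inside_l.sum()) / 1000.0,
        dwell_face_s=float(on_face.sum()) / 1000.0,
        target_delta_rl_s=_target_delta_rl(spec, condition, ipsi_effect_s),
        beta=spec.main_sequence_beta,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def generate_experiment(spec: GeneratorSpec) -> Experiment:
    """Generate a complete experiment: layouts, sessions, trials, truth.

    Sessions are scheduled on a rolling calendar that interleaves baseline
    and injection sessions, so every injection session has baseline sessions
    within +/-31 days (exercising baseline normalization downstream).
    """
    rng = np.random.default_rng(spec.seed)

    layouts: dict[str, LandmarkSet] = {}
    for i in range(spec.n_images):
        lm, twin = generate_face_layout(spec, i, rng)
        layouts[lm.image_id] = lm
        layouts[twin.image_id] = twin
    image_ids = sorted(layouts)
    rois_by_image = {iid: eye_rois_from_landmarks(layouts[iid].points) for iid in image_ids}

    # session schedule: injections split into blocks, each opened by a
    # baseline session, with dates tight enough that every injection lies
    # within the +/-31-day baseline-normalization window
    injection_sessions: list[ConditionSpec] = []
    for c in spec.conditions:
        injection_sessions.extend([c] * c.n_sessions)
    n_b, n_i = spec.n_baseline_sessions, len(injection_sessions)
    slots: list[tuple[str, ConditionSpec | None, int]] = []
    day = 0
    if n_b == 0:
        for c in injection_sessions:
            slots.append(("injection", c, day))
            day += 2
    else:
        block = -(-n_i // n_b) if n_i else 0  # ceil
        step = 2 if block <= 15 else 1
        ii = 0
        for j in range(n_b):
            slots.append(("baseline", None, day))
            day += step
            for _ in range(block):
                if ii < n_i:
                    slots.append(("injection", injection_sessions[ii], day))
                    ii += 1
                    day += step
            day += step

    start = _dt.date(2022, 1, 3)
    trials: list[Trial] = []
    truth: dict[str, GroundTruth] = {}
    design_rows = []
    for k, (phase, cspec, day_k) in enumerate(slots):
        date = start + _dt.timedelta(days=day_k)
        if phase == "baseline":
            condition = Condition()
            session_id = f"S{k:03d}b"
        else:
            condition = cspec.condition
            session_id = f"S{k:03d}i"
        design_rows.append(
            {
                "session_id": session_id,
                "session_date": date.isoformat(),
                "phase": condition.phase,
                "site": condition.site,
                "hemisphere": condition.hemisphere,
                "volume_ul": condition.volume_ul,
                "n_trials": spec.trials_per_session,
            }
        )
        for j in range(spec.trials_per_session):
            image_id = image_ids[rng.integers(len(image_ids))]
            trial_id = f"{session_id}_t{j:03d}"
            tr, gt = generate_scanpath(
                spec,
                layouts[image_id],
                condition,
                rng,
                trial_id=trial_id,
                monkey_id="M1",
                session_id=session_id,
                session_date=date,
            )
            trials.append(tr)
            truth[trial_id] = gt
    design = pd.DataFrame(design_rows)
    return Experiment(
        trials=trials,
        landmarks=layouts,
        rois_by_image=rois_by_image,
        design=design,
        ground_truth=truth,
        spec=spec,
    )
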