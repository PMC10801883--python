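"""Trial-structured eye-trace, landmark, and ROI I/O plus inclusion rules.

File formats are plain tab-separated text so every artifact is inspectable
and diff-able:

* trace table: one row per sample — ``trial_id, t_ms, x_dva, y_dva, on_image``;
* trial metadata table: one row per trial — identifiers, session date,
  condition (phase/site/hemisphere/volume), image id and extent, and the
  pre-stimulus fixation window;
* landmark table: ``image_id, point_index, label, x_dva, y_dva, role`` with
  ``role`` either ``landmark`` or ``face_polygon``.

Missing samples (tracker dropout, blinks) are stored as NaN gaze with
``on_image`` false and are never interpolated.  Gaze coordinates are written
with :data:`GAZE_DECIMALS` decimals; timestamps are integer milliseconds.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: decimal places kept for gaze coordinates on disk
GAZE_DECIMALS = 4

#: default inclusion threshold: cumulative on-image viewing must exceed 7 s
MIN_ON_IMAGE_S = 7.0

#: off-image / missing runs shorter than this are treated as blinks
MAX_GAP_MS = 500

#: canonical order of the 26 face landmarks; identical across all images so
#: point k always corresponds to the same facial feature
LANDMARK_LABELS: tuple[str, ...] = (
    "left_temple",
    "right_temple",
    "left_cheek",
    "right_cheek",
    "left_jaw",
    "right_jaw",
    "forehead_center",
    "chin",
    "left_brow_center",
    "right_brow_center",
    "left_eye_outer",
    "left_eye_inner",
    "left_eye_top",
    "left_eye_bottom",
    "right_eye_outer",
    "right_eye_inner",
    "right_eye_top",
    "right_eye_bottom",
    "nose_bridge",
    "nose_tip",
    "nose_left",
    "nose_right",
    "mouth_left",
    "mouth_right",
    "mouth_top",
    "mouth_bottom",
)

N_LANDMARKS = len(LANDMARK_LABELS)  # 26

TRACE_COLUMNS = ["trial_id", "t_ms", "x_dva", "y_dva", "on_image"]
META_COLUMNS = [
    "trial_id",
    "monkey_id",
    "session_id",
    "session_date",
    "phase",
    "site",
    "hemisphere",
    "volume_ul",
    "image_id",
    "img_w_dva",
    "img_h_dva",
    "fix_start_ms",
    "fix_end_ms",
]


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class TrialValidationError(ValueError):
    """A trial violates a structural invariant (e.g. non-monotone time)."""


@dataclass(frozen=True)
class Condition:
    """Experimental condition of a trial.

    ``baseline`` trials have no injection: site/hemisphere are ``none`` and
    volume is 0.  Injection trials combine a site (``face_patch`` or
    ``control``), a hemisphere (``left``/``right``) and a muscimol volume in
    microliters (5 or 10).
    """

    phase: str = "baseline"
    site: str = "none"
    hemisphere: str = "none"
    volume_ul: int = 0

    def __post_init__(self) -> None:
        if self.phase not in ("baseline", "injection"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.site not in ("face_patch", "control", "none"):
            raise ValueError(f"unknown site {self.site!r}")
        if self.hemisphere not in ("left", "right", "none"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.phase == "baseline":
            if self.site != "none" or self.hemisphere != "none" or self.volume_ul != 0:
                raise ValueError("baseline condition must have site/hemisphere none, volume 0")
        else:
            if self.site == "none" or self.hemisphere == "none":
                raise ValueError("injection condition needs a site and hemisphere")
            if self.volume_ul not in (5, 10):
                raise ValueError("injection volume must be 5 or 10 uL")

    @property
    def label(self) -> str:
        if self.phase == "baseline":
            return "baseline"
        return f"{self.site}_{self.volume_ul}uL_{self.hemisphere}"


@dataclass
class Trial:
    """One free-viewing trial: gaze samples plus metadata.

    ``samples`` is a DataFrame with columns ``t_ms`` (int, strictly
    increasing), ``x_dva``, ``y_dva`` (float, NaN for dropout) and
    ``on_image`` (bool).  Time 0 is image onset; the pre-stimulus central
    fixation occupies ``fixation_window`` (typically [-1000, 0) ms).
    """

    trial_id: str
    monkey_id: str
    session_id: str
    session_date: _dt.date
    condition: Condition
    image_id: str
    image_extent: tuple[float, float] = (28.0, 21.0)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    fixation_window: tuple[int, int] = (-1000, 0)

    def validate(self) -> None:
        if self.image_extent[0] <= 0 or self.image_extent[1] <= 0:
            raise TrialValidationError(f"{self.trial_id}: non-positive image extent")
        if len(self.samples) == 0:
            raise TrialValidationError(f"{self.trial_id}: trial has no samples")
        t = self.samples["t_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise TrialValidationError(f"{self.trial_id}: timestamps not strictly increasing")

    @property
    def viewing_samples(self) -> pd.DataFrame:
        """Post-onset samples (t >= 0)."""
        return self.samples[self.samples["t_ms"] >= 0]

    @property
    def fixation_samples(self) -> pd.DataFrame:
        """Samples in the pre-stimulus fixation window."""
        lo, hi = self.fixation_window
        m = (self.samples["t_ms"] >= lo) & (self.samples["t_ms"] < hi)
        return self.samples[m]


@dataclass
class LandmarkSet:
    """26 corresponding landmark points for one face image, plus the face
    outline polygon, all in screen-centered dva."""

    image_id: str
    points: np.ndarray  # (26, 2)
    labels: tuple[str, ...] = LANDMARK_LABELS
    face_polygon: np.ndarray | None = None  # (m, 2), simple polygon

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise SchemaError(
                f"{self.image_id}: expected {N_LANDMARKS} landmark points, "
                f"got shape {self.points.shape}"
            )
        if tuple(self.labels) != LANDMARK_LABELS:
            raise SchemaError(f"{self.image_id}: landmark labels not in canonical order")
        if self.face_polygon is not None:
            self.face_polygon = np.asarray(self.face_polygon, dtype=float)

    def point(self, label: str) -> np.ndarray:
        return self.points[LANDMARK_LABELS.index(label)]


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned rectangle ROI in mean-face (or image) dva coordinates."""

    name: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"ROI {self.name}: degenerate rectangle")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Closed-rectangle membership test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------


def _condition_from_row(row: pd.Series) -> Condition:
    return Condition(
        phase=str(row["phase"]),
        site=str(row["site"]),
        hemisphere=str(row["hemisphere"]),
        volume_ul=int(row["volume_ul"]),
    )


def read_trials(
    traces_path, meta_path
) -> tuple[list[Trial], dict[str, str]]:
    """Read trials from a trace table and its sidecar metadata table.

    Returns ``(trials, flagged)`` where ``flagged`` maps trial ids that
    failed validation (duplicated/non-monotone timestamps, missing metadata)
    to a description; valid trials are returned regardless.
    """
    traces = pd.read_csv(traces_path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if missing:
        raise SchemaError(f"trace table missing required column(s): {', '.join(missing)}")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"trial_id": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata table missing required column(s): {', '.join(missing)}")

    if len(traces) == 0:
        logger.warning("empty trace table at %s", traces_path)
        return [], {}

    traces["trial_id"] = traces["trial_id"].astype(str)
    meta_by_id = {str(r["trial_id"]): r for _, r in meta.iterrows()}

    trials: list[Trial] = []
    flagged: dict[str, str] = {}
    for trial_id, g in traces.groupby("trial_id", sort=True):
        g = g.sort_values("t_ms", kind="stable")
        t = g["t_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            flagged[trial_id] = "duplicated or non-monotone timestamps"
            continue
        row = meta_by_id.get(trial_id)
        if row is None:
            flagged[trial_id] = "no metadata row"
            continue
        try:
            condition = _condition_from_row(row)
        except ValueError as exc:
            flagged[trial_id] = f"bad condition: {exc}"
            continue
        samples = pd.DataFrame(
            {
                "t_ms": t.astype(np.int64),
                "x_dva": g["x_dva"].to_numpy(dtype=float),
                "y_dva": g["y_dva"].to_numpy(dtype=float),
                "on_image": g["on_image"].to_numpy().astype(bool),
            }
        )
        trials.append(
            Trial(
                trial_id=trial_id,
                monkey_id=str(row["monkey_id"]),
                session_id=str(row["session_id"]),
                session_date=_dt.date.fromisoformat(str(row["session_date"])),
                condition=condition,
                image_id=str(row["image_id"]),
                image_extent=(float(row["img_w_dva"]), float(row["img_h_dva"])),
                samples=samples,
                fixation_window=(int(row["fix_start_ms"]), int(row["fix_end_ms"])),
            )
        )
    return trials, flagged


def write_trials(trials, traces_path, meta_path) -> None:
    """Write trials to a trace table and metadata table.

    Inverse of :func:`read_trials`: reading the written files reproduces the
    trials exactly (integer timestamps; gaze rounded to ``GAZE_DECIMALS``).
    Invalid trials (e.g. zero samples) are rejected before anything is
    written.
    """
    for tr in trials:
        tr.validate()
    trace_frames = []
    meta_rows = []
    for tr in trials:
        s = tr.samples
        trace_frames.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "t_ms": s["t_ms"].astype(np.int64),
                    "x_dva": s["x_dva"].round(GAZE_DECIMALS),
                    "y_dva": s["y_dva"].round(GAZE_DECIMALS),
                    "on_image": s["on_image"].astype(int),
                }
            )
        )
        meta_rows.append(
            {
                "trial_id": tr.trial_id,
                "monkey_id": tr.monkey_id,
                "session_id": tr.session_id,
                "session_date": tr.session_date.isoformat(),
                "phase": tr.condition.phase,
                "site": tr.condition.site,
                "hemisphere": tr.condition.hemisphere,
                "volume_ul": tr.condition.volume_ul,
                "image_id": tr.image_id,
                "img_w_dva": tr.image_extent[0],
                "img_h_dva": tr.image_extent[1],
                "fix_start_ms": tr.fixation_window[0],
                "fix_end_ms": tr.fixation_window[1],
            }
        )
    if trace_frames:
        pd.concat(trace_frames, ignore_index=True).to_csv(traces_path, sep="\t", index=False)
    else:
        pd.DataFrame(columns=TRACE_COLUMNS).to_csv(traces_path, sep="\t", index=False)
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# blink bridging and trial inclusion
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, stop) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def bridge_gaps(samples: pd.DataFrame, max_gap_ms: int = MAX_GAP_MS) -> pd.DataFrame:
    """Annotate blink-scale interruptions of viewing.

    Adds two boolean columns to a copy of ``samples``:

    * ``viewing`` — on-image with valid gaze;
    * ``bridged`` — member of a non-viewing run strictly shorter than
      ``max_gap_ms`` (a natural blink).  Bridged runs count as continuous
      viewing for trial inclusion, but their samples carry no fabricated
      gaze and are never used for heatmaps or statistics.
    """
    out = samples.copy()
    valid = ~(out["x_dva"].isna() | out["y_dva"].isna())
    viewing = out["on_image"].to_numpy(dtype=bool) & valid.to_numpy()
    out["viewing"] = viewing
    bridged = np.zeros(len(out), dtype=bool)
    t = out["t_ms"].to_numpy()
    for start, stop in _runs(~viewing):
        # run duration measured on the time axis, nominal 1 ms per sample
        dur = t[stop - 1] - t[start] + 1
        if dur < max_gap_ms:
            bridged[start:stop] = True
    out["bridged"] = bridged
    return out


def on_image_viewing_time_s(trial: Trial, max_gap_ms: int = MAX_GAP_MS) -> float:
    """Cumulative on-image viewing time in seconds after blink bridging.

    Counts post-onset viewing samples plus bridged-gap samples at the nominal
    1 ms period.
    """
    post = trial.viewing_samples
    if len(post) == 0:
        return 0.0
    ann = bridge_gaps(post, max_gap_ms=max_gap_ms)
    counted = ann["viewing"].to_numpy() | ann["bridged"].to_numpy()
    return float(counted.sum()) / 1000.0


def filter_trials(
    trials,
    min_on_image_s: float = MIN_ON_IMAGE_S,
    max_gap_ms: int = MAX_GAP_MS,
) -> tuple[list[Trial], list[dict]]:
    """Apply the viewing-time inclusion rule.

    Keeps trials whose cumulative on-image time (with blink-scale gaps
    bridged) strictly exceeds ``min_on_image_s`` seconds.  Returns
    ``(kept, exclusion_log)``; the log has one record per excluded trial so
    kept + excluded always partitions the input.
    """
    if min_on_image_s < 0:
        raise ValueError("min_on_image_s must be >= 0")
    kept: list[Trial] = []
    log: list[dict] = []
    for tr in trials:
        t_view = on_image_viewing_time_s(tr, max_gap_ms=max_gap_ms)
        if t_view > min_on_image_s:
            kept.append(tr)
        else:
            log.append(
                {"trial_id": tr.trial_id, "on_image_s": t_view, "threshold_s": min_on_image_s}
            )
    return kept, log


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


def read_landmarks(path) -> dict[str, LandmarkSet]:
    """Read a landmark table into per-image :class:`LandmarkSet` objects."""
    df = pd.read_csv(path, sep="\t", dtype={"image_id": str})
    required = ["image_id", "point_index", "label", "x_dva", "y_dva", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"landmark table missing column(s): {', '.join(missing)}")
    out: dict[str, LandmarkSet] = {}
    for image_id, g in df.groupby("image_id", sort=True):
        lm = g[g["role"] == "landmark"].sort_values("point_index")
        if len(lm) != N_LANDMARKS:
            raise SchemaError(
                f"image {image_id}: expected {N_LANDMARKS} landmark points, got {len(lm)}"
            )
        labels = tuple(lm["label"])
        if labels != LANDMARK_LABELS:
            raise SchemaError(f"image {image_id}: landmark labels not in canonical order")
        poly = g[g["role"] == "face_polygon"].sort_values("point_index")
        out[image_id] = LandmarkSet(
            image_id=str(image_id),
            points=lm[["x_dva", "y_dva"]].to_numpy(dtype=float),
            face_polygon=(
                poly[["x_dva", "y_dva"]].to_numpy(dtype=float) if len(poly) else None
            ),
        )
    return out


def write_landmarks(landmark_sets: dict[str, LandmarkSet], path) -> None:
    rows = []
    for image_id in sorted(landmark_sets):
        lm = landmark_sets[image_id]
        for i, (label, (x, y)) in enumerate(zip(lm.labels, lm.points)):
            rows.append((image_id, i, label, round(x, GAZE_DECIMALS), round(y, GAZE_DECIMALS), "landmark"))
        if lm.face_polygon is not None:
            for i, (x, y) in enumerate(lm.face_polygon):
                rows.append((image_id, i, "face_polygon", round(x, GAZE_DECIMALS), round(y, GAZE_DECIMALS), "face_polygon"))
    pd.DataFrame(
        rows, columns=["image_id", "point_index", "label", "x_dva", "y_dva", "role"]
    ).to_csv(path, sep="\t", index=False)


def _mirror_label(label: str) -> str:
    if label.startswith("left_"):
        return "right_" + label[5:]
    if label.startswith("right_"):
        return "left_" + label[6:]
    if label.endswith("_left"):
        return label[:-5] + "_right"
    if label.endswith("_right"):
        return label[:-6] + "_left"
    return label


def mirror_landmarks(
    lm: LandmarkSet, axis_x: float = 0.0, image_id: str | None = None
) -> LandmarkSet:
    """Left-right flip of a landmark set about the vertical line x = axis_x.

    In the screen-centered convention the image midline is x = 0, so the
    default mirrors about the image's own vertical midline.  Left/right
    semantic labels are swapped and the points reordered so the canonical
    label order (hence the cross-image correspondence) is preserved;
    applying the mirror twice is the exact identity.
    """
    mirrored = np.empty_like(lm.points)
    for i, label in enumerate(lm.labels):
        j = LANDMARK_LABELS.index(_mirror_label(label))
        p = lm.points[i]
        mirrored[j] = (2.0 * axis_x - p[0], p[1])
    poly = None
    if lm.face_polygon is not None:
        poly = lm.face_polygon.copy()
        poly[:, 0] = 2.0 * axis_x - poly[:, 0]
        poly = poly[::-1].copy()  # keep orientation after reflection
    return LandmarkSet(
        image_id=image_id if image_id is not None else lm.image_id + "_mirror",
        points=mirrored,
        face_polygon=poly,
    )
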