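"""Looking-time, pattern-change, and permutation statistics.

The behavioral statistics quantify how neural inactivation reshapes gaze:

* dwell time inside eye ROIs on the mean face, expressed observer-referenced
  (right eye minus left eye) or injection-referenced (ipsilateral minus
  contralateral eye, where a right-hemisphere injection makes the
  observer-right eye ipsilateral);
* baseline normalization: the observer-referenced bias measured in baseline
  sessions within +/-31 days of an injection session is subtracted before
  re-expressing the effect ipsi/contra;
* the pattern change index
  ``(d(h_i, Hgrand) - d(h_i, hbar)) / d(h_i, Hgrand)`` comparing each
  trial's analysis heatmap to the same-stimulus condition mean (hbar) and
  same-stimulus grand mean over condition + baseline trials (Hgrand);
* permutation inference (two-sided, add-one Monte Carlo p-values; exact
  enumeration for small problems) with Benjamini-Hochberg correction across
  a comparison family, and nonparametric bootstrap CIs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from statsmodels.stats.multitest import multipletests

from gazemorph.heatmaps import Heatmap, average_heatmaps, heatmap_distance
from gazemorph.io import RoiRect

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "roi_dwell_time",
    "ipsi_contra_difference",
    "baseline_normalize",
    "permutation_test",
    "paired_difference_test",
    "bh_adjust",
    "bootstrap_ci",
    "pattern_change_index",
    "baseline_pattern_variation",
    "face_detection_metrics",
]

DEFAULT_N_RESAMPLES = 10_000
BASELINE_WINDOW_DAYS = 31


@dataclass
class StatResult:
    """An observed statistic with its permutation p-value and metadata."""

    observed: float
    p_perm: float
    n_resamples: int
    exact: bool = False
    p_adj: float | None = None
    ci95: tuple[float, float] | None = None
    seed: int | None = None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _two_sided_p(observed: float, null: np.ndarray) -> float:
    """Add-one two-sided Monte Carlo p-value: never exactly zero."""
    hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    return (1 + hits) / (1 + len(null))


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------


def _sample_durations_ms(t_ms: np.ndarray) -> np.ndarray:
    """Interval each sample covers: time to the next sample, last = 1 ms."""
    if len(t_ms) == 0:
        return np.zeros(0)
    d = np.empty(len(t_ms))
    d[:-1] = np.diff(t_ms)
    d[-1] = 1.0
    return d


def roi_dwell_time(warped_gaze: pd.DataFrame, roi: RoiRect, require_in_mesh: bool = True) -> float:
    """Seconds of dwell inside a closed rectangle in the mean-face frame.

    Each sample contributes the interval up to the next sample (the final
    sample contributes the nominal 1-ms period).  Out-of-mesh samples carry
    unwarped coordinates, so they are excluded by default.
    """
    g = warped_gaze
    if require_in_mesh and "in_mesh" in g.columns:
        g = g[g["in_mesh"]]
    if len(g) == 0:
        return 0.0
    dur = _sample_durations_ms(g["t_ms"].to_numpy(dtype=float))
    inside = roi.contains(g["x_dva"].to_numpy(), g["y_dva"].to_numpy())
    return float(dur[inside].sum()) / 1000.0


def ipsi_contra_difference(records: pd.DataFrame, hemisphere: str) -> pd.Series:
    """Per-trial ipsi-minus-contra eye dwell difference in seconds.

    ``records`` must carry observer-referenced ``t_right_eye`` and
    ``t_left_eye`` columns.  A right-hemisphere injection makes the
    observer-right eye ipsilateral, so the difference is
    ``t_right_eye - t_left_eye``; for a left-hemisphere injection the sign
    flips.  Baseline data (no hemisphere) is rejected: use the
    observer-referenced bias directly instead.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right' (baseline has no ipsi/contra)")
    delta_rl = records["t_right_eye"] - records["t_left_eye"]
    return delta_rl if hemisphere == "right" else -delta_rl


def baseline_normalize(
    injection_records: pd.DataFrame,
    baseline_records: pd.DataFrame,
    window_days: int = BASELINE_WINDOW_DAYS,
) -> pd.DataFrame:
    """Subtract the local baseline viewing bias from injection-trial deltas.

    Both inputs need ``session_id``, ``session_date`` (datetime.date) and
    observer-referenced ``t_right_eye`` / ``t_left_eye`` per trial;
    injection records additionally need ``hemisphere``.  For each injection
    session the mean right-minus-left bias over all baseline trials within
    ``+/-window_days`` is subtracted, and the result re-expressed
    ipsilateral-minus-contralateral.  Raises if an injection session has no
    baseline session in its window.
    """
    base = baseline_records.copy()
    base["delta_rl"] = base["t_right_eye"] - base["t_left_eye"]
    out = injection_records.copy()
    out["delta_rl"] = out["t_right_eye"] - out["t_left_eye"]
    norm = np.empty(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        gap = (base["session_date"] - row["session_date"]).map(lambda d: abs(d.days))
        in_window = base[gap <= window_days]
        if len(in_window) == 0:
            raise ValueError(
                f"injection session {row['session_id']}: no baseline session "
                f"within +/-{window_days} days"
            )
        bias = float(in_window["delta_rl"].mean())
        d = row["delta_rl"] - bias
        norm[i] = d if row["hemisphere"] == "right" else -d
    out["delta_ipsi_contra_norm"] = norm
    return out


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------


def permutation_test(
    values_a,
    values_b,
    statistic=None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed=0,
    exact_cap: int = 20_000,
) -> StatResult:
    """Two-sample permutation test on trial-level values.

    The null pools both groups and re-splits at the original group sizes.
    When the number of distinct splits is at most ``exact_cap`` the null is
    enumerated exactly and ``p = #{|null| >= |observed|} / #splits``;
    otherwise ``n_resamples`` Monte Carlo splits are drawn and the add-one
    two-sided p-value is reported.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    mean_diff = statistic is None
    if mean_diff:
        statistic = lambda x, y: float(np.mean(x) - np.mean(y))
    observed = float(statistic(a, b))
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)

    n_splits = math.comb(n, na)
    if n_splits <= exact_cap:
        null = np.empty(n_splits)
        idx_all = frozenset(range(n))
        for k, comb in enumerate(itertools.combinations(range(n), na)):
            ia = np.fromiter(comb, dtype=int)
            ib = np.fromiter(idx_all.difference(comb), dtype=int)
            null[k] = statistic(pooled[ia], pooled[ib])
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        return StatResult(observed=observed, p_perm=p, n_resamples=n_splits, exact=True)

    rng = _rng(seed)
    perms = np.argsort(rng.random((n_resamples, n)), axis=1)
    vals = pooled[perms]
    if mean_diff:
        # vectorized fast path for the difference-of-means statistic
        null = vals[:, :na].mean(axis=1) - vals[:, na:].mean(axis=1)
    else:
        null = np.array([statistic(row[:na], row[na:]) for row in vals])
    p = _two_sided_p(observed, null)
    return StatResult(observed=observed, p_perm=p, n_resamples=n_resamples, exact=False)


def paired_difference_test(
    deltas,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed=0,
    exact_cap: int = 2**20,
) -> StatResult:
    """One-sample sign-flip permutation test for mean delta = 0.

    Exact enumeration over all 2^n sign patterns when feasible (then
    ``p = #{|null| >= |observed|} / 2^n``); otherwise add-one Monte Carlo.
    """
    d = np.asarray(deltas, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    observed = float(np.mean(d))
    n = len(d)
    if 2**n <= exact_cap:
        bits = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1) * 2 - 1
        null = (bits * d).mean(axis=1)
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        return StatResult(observed=observed, p_perm=p, n_resamples=2**n, exact=True)
    rng = _rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_resamples, n))
    null = (signs * d).mean(axis=1)
    p = _two_sided_p(observed, null)
    return StatResult(observed=observed, p_perm=p, n_resamples=n_resamples, exact=False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_ci(
    values,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed=0,
    statistic=np.mean,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI over trials for a summary statistic."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = _rng(seed)
    idx = rng.integers(0, len(v), size=(n_resamples, len(v)))
    boot = np.asarray([statistic(v[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(boot, alpha)), float(np.quantile(boot, 1 - alpha)))


def two_sample_shift_ci(
    values_a,
    values_b,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed=0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``mean(a) - mean(b)``.

    Both samples are resampled, so the interval reflects estimation noise in
    the reference group as well (used for baseline-normalized effects,
    where the subtracted baseline bias is itself estimated from trials).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    rng = _rng(seed)
    ia = rng.integers(0, len(a), size=(n_resamples, len(a)))
    ib = rng.integers(0, len(b), size=(n_resamples, len(b)))
    boot = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(boot, alpha)), float(np.quantile(boot, 1 - alpha)))


# ---------------------------------------------------------------------------
# pattern change
# ---------------------------------------------------------------------------


def pattern_change_index(
    trial_hm: Heatmap, condition_mean_hm: Heatmap, grand_mean_hm: Heatmap
) -> float:
    """Per-trial pattern change index.

    ``(d(h_i, Hgrand) - d(h_i, hbar)) / d(h_i, Hgrand)`` where ``hbar`` is
    the same-stimulus mean heatmap within the trial's condition and
    ``Hgrand`` the same-stimulus grand mean over the condition plus
    baseline trials.  The index is 1 when the trial matches its condition
    mean exactly but differs from the grand mean, 0 when both distances are
    equal, and negative when the trial sits farther from its condition mean
    than from the grand mean.  Undefined (NaN, trial to be excluded) when
    ``d(h_i, Hgrand) = 0``.
    """
    d_grand = heatmap_distance(trial_hm, grand_mean_hm)
    d_cond = heatmap_distance(trial_hm, condition_mean_hm)
    if d_grand == 0.0:
        if d_cond == 0.0:
            return 0.0  # equal distances (both zero): no pattern change
        logger.warning("pattern change index undefined: trial equals grand mean")
        return float("nan")
    return (d_grand - d_cond) / d_grand


def pattern_change_indices(
    trial_hms_by_stimulus: dict[str, list[Heatmap]],
    baseline_hms_by_stimulus: dict[str, list[Heatmap]],
) -> np.ndarray:
    """Pattern change indices for every trial of an injection condition.

    For each stimulus, ``hbar`` is the mean over that stimulus's condition
    trials and ``Hgrand`` the mean over condition + baseline trials of the
    same stimulus.  Undefined indices are dropped.
    """
    out: list[float] = []
    for stim, hms in trial_hms_by_stimulus.items():
        base = baseline_hms_by_stimulus.get(stim, [])
        if not hms:
            continue
        hbar = average_heatmaps(hms)
        grand = average_heatmaps(list(hms) + list(base))
        for h in hms:
            idx = pattern_change_index(h, hbar, grand)
            if np.isfinite(idx):
                out.append(idx)
    return np.asarray(out)


def baseline_pattern_variation(
    baseline_hms_by_stimulus: dict[str, list[Heatmap]],
    seed=0,
) -> np.ndarray:
    """Expected natural variation of the pattern change index.

    Baseline trials of each stimulus are split in half at random; one half
    plays the role of an injection condition (its mean is ``hbar``) while
    the grand mean is taken over all baseline trials of the stimulus.
    The returned per-trial indices form the injection-free reference band.
    Stimuli with fewer than 2 baseline trials are skipped with a warning.
    """
    rng = _rng(seed)
    out: list[float] = []
    for stim, hms in baseline_hms_by_stimulus.items():
        if len(hms) < 2:
            logger.warning("stimulus %s: single baseline trial, skipped", stim)
            continue
        order = rng.permutation(len(hms))
        half = [hms[i] for i in order[: max(1, len(hms) // 2)]]
        hbar = average_heatmaps(half)
        grand = average_heatmaps(hms)
        for h in half:
            idx = pattern_change_index(h, hbar, grand)
            if np.isfinite(idx):
                out.append(idx)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# face detection
# ---------------------------------------------------------------------------


def face_detection_metrics(trial, saccades, face_polygon: np.ndarray) -> dict:
    """Did the animal find the face, how fast, and how long did it dwell?

    * ``found`` — gaze entered the face polygon at any point after onset;
    * ``latency_ms`` — time from image onset to the end of the first
      saccade landing inside the polygon (0 by convention when gaze is
      already on the face at onset; NaN when never found);
    * ``frac_time_on_face`` — dwell inside the polygon over total on-image
      dwell.
    """
    path = _MplPath(np.asarray(face_polygon, dtype=float))
    view = trial.viewing_samples
    valid = view["on_image"].to_numpy(dtype=bool)
    valid &= np.isfinite(view["x_dva"].to_numpy()) & np.isfinite(view["y_dva"].to_numpy())
    v = view[valid]
    if len(v) == 0:
        return {"found": False, "latency_ms": float("nan"), "frac_time_on_face": 0.0}
    inside = path.contains_points(v[["x_dva", "y_dva"]].to_numpy())
    frac = float(inside.mean())
    found = bool(inside.any())
    if not found:
        return {"found": False, "latency_ms": float("nan"), "frac_time_on_face": 0.0}
    if inside[0] and int(v["t_ms"].iloc[0]) <= 1:
        latency = 0.0
    else:
        latency = float("nan")
        for ev in sorted(saccades, key=lambda e: e.onset_ms):
            if ev.offset_ms < 0:
                continue
            if path.contains_points([ev.end_point])[0]:
                latency = float(ev.offset_ms)
                break
        if not np.isfinite(latency):
            # gaze drifted in without a qualifying saccade; first in-polygon time
            latency = float(v["t_ms"].to_numpy()[inside][0])
    return {"found": True, "latency_ms": latency, "frac_time_on_face": frac}
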