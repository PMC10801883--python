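"""Fixation heatmaps and heatmap arithmetic.

Two recipes are supported:

* a display heatmap at a configurable native resolution (default
  20 px/deg), accumulating one count per 1-ms gaze sample (so total mass is
  dwell time in ms) and smoothing with an isotropic Gaussian of SD 0.25 dva;
* an analysis heatmap obtained by mass-preserving down-sampling to
  5 px/deg (140 x 105 pixels for the standard 28 x 21 dva image) followed
  by a Gaussian of SD 2.5 px.

Samples lying inside saccades larger than 1 dva are excluded before
accumulation, so a heatmap reflects fixational gaze only.

Grids are stored with row 0 at the *bottom* (y increasing with row index),
matching the screen-centered dva frame; renderers flip for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "Heatmap",
    "build_fixation_heatmap",
    "saccade_exclusion_mask",
    "resample_for_analysis",
    "heatmap_distance",
    "average_heatmaps",
    "difference_heatmap",
]

#: analysis-resolution constants: 5 px/deg and SD 2.5 px
ANALYSIS_PX_PER_DEG = 5
ANALYSIS_SIGMA_PX = 2.5

#: display-heatmap defaults: 20 px/deg native grid, SD 0.25 dva
DISPLAY_PX_PER_DEG = 20
DISPLAY_SIGMA_DVA = 0.25

#: saccades with amplitude above this are stripped from the traces
SACCADE_EXCLUDE_AMP_DVA = 1.0


@dataclass
class Heatmap:
    """Gridded gaze density with an explicit dva <-> pixel mapping.

    ``origin`` is the dva coordinate of the grid's lower-left corner;
    cell (row, col) covers
    ``[origin + col/ppd, origin + (col+1)/ppd) x [... row ...)``.
    """

    grid: np.ndarray  # (n_rows, n_cols), non-negative
    px_per_deg: float
    origin: tuple[float, float]
    extent: tuple[float, float]  # (width, height) dva

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        n_rows = int(round(self.extent[1] * self.px_per_deg))
        n_cols = int(round(self.extent[0] * self.px_per_deg))
        if self.grid.shape != (n_rows, n_cols):
            raise ValueError(
                f"grid shape {self.grid.shape} inconsistent with extent "
                f"{self.extent} at {self.px_per_deg} px/deg (expected {(n_rows, n_cols)})"
            )

    @property
    def mass(self) -> float:
        return float(self.grid.sum())

    def same_grid(self, other: "Heatmap") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and self.px_per_deg == other.px_per_deg
            and np.allclose(self.origin, other.origin)
        )

    def bin_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map dva coordinates to (row, col); also return an in-grid mask."""
        col = np.floor((np.asarray(x) - self.origin[0]) * self.px_per_deg).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) * self.px_per_deg).astype(int)
        ok = (col >= 0) & (col < self.grid.shape[1]) & (row >= 0) & (row < self.grid.shape[0])
        return row, col, ok


def empty_grid(
    extent: tuple[float, float],
    px_per_deg: float = DISPLAY_PX_PER_DEG,
    origin: tuple[float, float] | None = None,
) -> Heatmap:
    """Zero heatmap covering ``extent``, centered at the origin by default."""
    if origin is None:
        origin = (-extent[0] / 2.0, -extent[1] / 2.0)
    n_rows = int(round(extent[1] * px_per_deg))
    n_cols = int(round(extent[0] * px_per_deg))
    return Heatmap(np.zeros((n_rows, n_cols)), px_per_deg, origin, extent)


def saccade_exclusion_mask(
    samples: pd.DataFrame,
    saccades,
    exclude_amp_dva: float = SACCADE_EXCLUDE_AMP_DVA,
) -> np.ndarray:
    """True for samples inside saccades with amplitude > ``exclude_amp_dva``."""
    t = samples["t_ms"].to_numpy()
    mask = np.zeros(len(samples), dtype=bool)
    for ev in saccades:
        if ev.amplitude > exclude_amp_dva:
            mask |= (t >= ev.onset_ms) & (t <= ev.offset_ms)
    return mask


def build_fixation_heatmap(
    trial,
    saccades,
    sigma_dva: float = DISPLAY_SIGMA_DVA,
    exclude_amp_dva: float = SACCADE_EXCLUDE_AMP_DVA,
    px_per_deg: float = DISPLAY_PX_PER_DEG,
    smooth: bool = True,
) -> Heatmap:
    """Accumulate a trial's fixational gaze into a smoothed heatmap.

    One count per on-image sample (nominal 1 ms), after removing samples
    inside saccades larger than ``exclude_amp_dva``.  Smoothing uses a
    zero-padded Gaussian with a unit-sum kernel, so total mass is conserved
    for interior sources.  Raises if no usable samples remain.
    """
    view = trial.viewing_samples
    keep = view["on_image"].to_numpy(dtype=bool)
    keep &= np.isfinite(view["x_dva"].to_numpy()) & np.isfinite(view["y_dva"].to_numpy())
    keep &= ~saccade_exclusion_mask(view, saccades, exclude_amp_dva)
    pts = view[keep]
    if len(pts) == 0:
        raise ValueError(f"trial {trial.trial_id}: no usable samples for heatmap")
    hm = empty_grid(trial.image_extent, px_per_deg=px_per_deg)
    row, col, ok = hm.bin_indices(pts["x_dva"].to_numpy(), pts["y_dva"].to_numpy())
    np.add.at(hm.grid, (row[ok], col[ok]), 1.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        import logging

        logging.getLogger(__name__).debug(
            "trial %s: %d off-grid samples dropped", trial.trial_id, n_dropped
        )
    if smooth and sigma_dva > 0:
        hm.grid = gaussian_filter(hm.grid, sigma=sigma_dva * px_per_deg, mode="constant")
    return hm


def resample_for_analysis(
    hm: Heatmap,
    px_per_deg: int = ANALYSIS_PX_PER_DEG,
    sigma_px: float = ANALYSIS_SIGMA_PX,
) -> Heatmap:
    """Mass-preserving down-sample to the analysis grid, then smooth.

    The source resolution must be an integer multiple of the target so each
    analysis cell is the exact sum of a block of source cells.  For the
    standard 28 x 21 dva image at 5 px/deg the output is 140 x 105.
    """
    factor = hm.px_per_deg / px_per_deg
    if factor < 1:
        raise ValueError(
            f"target resolution {px_per_deg} px/deg finer than source {hm.px_per_deg}"
        )
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("source px_per_deg must be an integer multiple of the target")
    f = int(round(factor))
    n_rows, n_cols = hm.grid.shape
    block = hm.grid.reshape(n_rows // f, f, n_cols // f, f).sum(axis=(1, 3))
    out = Heatmap(block, px_per_deg, hm.origin, hm.extent)
    if sigma_px > 0:
        out.grid = gaussian_filter(out.grid, sigma=sigma_px, mode="constant")
    return out


def heatmap_distance(u: Heatmap, v: Heatmap) -> float:
    """Euclidean distance between two heatmaps on identical grids:
    d(u, v) = sqrt(sum_i (u_i - v_i)^2)."""
    if not u.same_grid(v):
        raise ValueError("heatmap grids do not match")
    return float(np.sqrt(np.sum((u.grid - v.grid) ** 2)))


def average_heatmaps(hms, weights=None) -> Heatmap:
    """Weighted per-cell mean of heatmaps on a common grid."""
    hms = list(hms)
    if not hms:
        raise ValueError("cannot average zero heatmaps")
    first = hms[0]
    for h in hms[1:]:
        if not first.same_grid(h):
            raise ValueError("heatmap grids do not match")
    if weights is None:
        w = np.ones(len(hms))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(hms) or w.sum() <= 0:
            raise ValueError("bad weights")
    stack = np.stack([h.grid for h in hms])
    mean = np.tensordot(w / w.sum(), stack, axes=1)
    return Heatmap(mean, first.px_per_deg, first.origin, first.extent)


def difference_heatmap(post_avg: Heatmap, base_avg: Heatmap) -> np.ndarray:
    """Cellwise post - base change map (signed array on the shared grid)."""
    if not post_avg.same_grid(base_avg):
        raise ValueError("heatmap grids do not match")
    return post_avg.grid - base_avg.grid


def heatmap_from_points(
    x: np.ndarray,
    y: np.ndarray,
    extent: tuple[float, float],
    px_per_deg: float = DISPLAY_PX_PER_DEG,
    sigma_dva: float = DISPLAY_SIGMA_DVA,
) -> Heatmap:
    """Heatmap directly from point coordinates (used for warped gaze)."""
    hm = empty_grid(extent, px_per_deg=px_per_deg)
    row, col, ok = hm.bin_indices(np.asarray(x), np.asarray(y))
    np.add.at(hm.grid, (row[ok], col[ok]), 1.0)
    if sigma_dva > 0:
        hm.grid = gaussian_filter(hm.grid, sigma=sigma_dva * px_per_deg, mode="constant")
    return hm
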