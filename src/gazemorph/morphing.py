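"""Landmark-based piecewise-affine morphing onto an average face.

The average face shape is the pointwise mean of the 26 corresponding
landmarks over all face images.  A Delaunay triangulation is computed once
on the mean shape, and its vertex-index topology is transferred to every
individual face, guaranteeing corresponding triangles.  Each triangle pair
(source face -> mean face) defines an affine map ``T`` solving
``T @ [x; y; 1] = [x'; y'; 1]`` at the three vertices; a gaze point is
warped by the map of the source triangle containing it.

Points outside the source convex hull have no defining triangle; they are
flagged ``in_mesh = False`` and returned unwarped so off-face dwell can be
analyzed separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from sklearn.base import BaseEstimator, TransformerMixin

from gazemorph.io import LandmarkSet

__all__ = [
    "MeanShape",
    "TriangleMesh",
    "PiecewiseAffineWarp",
    "compute_mean_shape",
    "triangulate",
    "triangle_affine",
    "warp_points",
    "warp_trial_gaze",
]

#: barycentric tolerance for point-in-triangle tests
_BARY_TOL = 1e-9


@dataclass
class MeanShape:
    """Average landmark configuration over a set of face images."""

    points: np.ndarray  # (26, 2)
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class TriangleMesh:
    """Triangulation topology: index triples into a landmark point set.

    The same triples are evaluated at each face's own landmark coordinates,
    so triangle i always covers the same facial region on every face.
    """

    vertex_indices: np.ndarray  # (n_tri, 3) int

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=int)

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def triangles_at(self, points: np.ndarray) -> np.ndarray:
        """Triangle vertex coordinates (n_tri, 3, 2) for a given point set."""
        return np.asarray(points, dtype=float)[self.vertex_indices]


def compute_mean_shape(landmark_sets) -> MeanShape:
    """Pointwise arithmetic mean of corresponding landmarks.

    All sets must carry the canonical 26-point ordering; the k-th mean point
    is the mean of the k-th point over sources.
    """
    sets = list(landmark_sets)
    if not sets:
        raise ValueError("need at least one landmark set")
    for lm in sets:
        if tuple(lm.labels) != tuple(sets[0].labels):
            raise ValueError("landmark sets have inconsistent point ordering")
    stack = np.stack([lm.points for lm in sets])
    return MeanShape(points=stack.mean(axis=0), source_ids=tuple(lm.image_id for lm in sets))


def triangulate(shape: MeanShape | np.ndarray) -> TriangleMesh:
    """Delaunay triangulation of the mean shape (topology computed once).

    Triangles are brought to a deterministic order (sorted vertex triples)
    so downstream boundary tie-breaking by lowest triangle index is
    reproducible.
    """
    points = shape.points if isinstance(shape, MeanShape) else np.asarray(shape, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(points)
    except Exception as exc:  # qhull raises on degenerate input
        raise ValueError(f"degenerate point set; triangulation failed: {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("collinear point set; no triangles")
    simplices = np.sort(tri.simplices, axis=1)
    order = np.lexsort((simplices[:, 2], simplices[:, 1], simplices[:, 0]))
    return TriangleMesh(vertex_indices=simplices[order])


def triangle_affine(src_tri: np.ndarray, dst_tri: np.ndarray) -> np.ndarray:
    """Affine map (3x3 homogeneous matrix) sending one triangle to another.

    Solves ``T @ S = D`` where S and D stack the source/destination
    vertices as homogeneous columns; T is exact at the three vertices and
    has bottom row (0, 0, 1).
    """
    src = np.asarray(src_tri, dtype=float)
    dst = np.asarray(dst_tri, dtype=float)
    S = np.vstack([src.T, np.ones(3)])
    D = np.vstack([dst.T, np.ones(3)])
    if abs(np.linalg.det(S)) < 1e-12:
        raise np.linalg.LinAlgError("degenerate source triangle; affine map singular")
    T = D @ np.linalg.inv(S)
    T[2] = (0.0, 0.0, 1.0)  # clamp float noise in the homogeneous row
    return T


class PiecewiseAffineWarp(TransformerMixin, BaseEstimator):
    """Piecewise-affine warp from one landmark frame into another.

    Parameters
    ----------
    mesh : optional TriangleMesh; if omitted, ``fit`` triangulates the
        destination shape (the mean face) and reuses that topology on the
        source.

    After ``fit(src_points, dst_points)`` the estimator exposes ``mesh_``,
    per-triangle ``affines_`` (n_tri, 3, 3) and the source triangle
    geometry.  ``transform`` maps points through the triangle that contains
    them in source coordinates; points on a shared edge are assigned to the
    lowest triangle index, and points outside the source hull are returned
    unwarped with ``in_mesh = False``.
    """

    def __init__(self, mesh: TriangleMesh | None = None):
        self.mesh = mesh

    def fit(self, X, y) -> "PiecewiseAffineWarp":
        src = np.asarray(X, dtype=float)
        dst = np.asarray(y, dtype=float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise ValueError("source and destination must be matching (n, 2) arrays")
        self.mesh_ = self.mesh if self.mesh is not None else triangulate(dst)
        src_tris = self.mesh_.triangles_at(src)
        dst_tris = self.mesh_.triangles_at(dst)
        self.affines_ = np.stack(
            [triangle_affine(s, d) for s, d in zip(src_tris, dst_tris)]
        )
        self.src_points_ = src
        self.dst_points_ = dst
        # precompute barycentric solvers: inverse of [[x1-x3, x2-x3], [y1-y3, y2-y3]]
        v0 = src_tris[:, 0] - src_tris[:, 2]
        v1 = src_tris[:, 1] - src_tris[:, 2]
        det = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
        if np.any(np.abs(det) < 1e-12):
            raise ValueError("degenerate source triangle in mesh")
        self._binv = np.empty((len(det), 2, 2))
        self._binv[:, 0, 0] = v1[:, 1] / det
        self._binv[:, 0, 1] = -v1[:, 0] / det
        self._binv[:, 1, 0] = -v0[:, 1] / det
        self._binv[:, 1, 1] = v0[:, 0] / det
        self._anchor = src_tris[:, 2]
        return self

    def assign_triangles(self, points: np.ndarray) -> np.ndarray:
        """Index of the containing source triangle per point (-1 if none).

        Triangles are scanned in index order, so boundary points land in the
        lowest-index triangle deterministically.
        """
        pts = np.asarray(points, dtype=float)
        assign = np.full(len(pts), -1, dtype=int)
        remaining = np.ones(len(pts), dtype=bool)
        for i in range(len(self.mesh_)):
            if not remaining.any():
                break
            d = pts[remaining] - self._anchor[i]
            lam12 = d @ self._binv[i].T
            lam3 = 1.0 - lam12[:, 0] - lam12[:, 1]
            inside = (
                (lam12[:, 0] >= -_BARY_TOL)
                & (lam12[:, 1] >= -_BARY_TOL)
                & (lam3 >= -_BARY_TOL)
            )
            idx = np.flatnonzero(remaining)[inside]
            assign[idx] = i
            remaining[idx] = False
        return assign

    def transform(self, X) -> np.ndarray:
        warped, _ = self.transform_with_flags(X)
        return warped

    def transform_with_flags(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Warp points; returns ``(warped, in_mesh)``.

        Out-of-mesh points are passed through unwarped with flag False.
        """
        pts = np.asarray(X, dtype=float)
        assign = self.assign_triangles(pts)
        warped = pts.copy()
        in_mesh = assign >= 0
        for i in np.unique(assign[in_mesh]):
            sel = assign == i
            T = self.affines_[i]
            p = pts[sel]
            warped[sel, 0] = T[0, 0] * p[:, 0] + T[0, 1] * p[:, 1] + T[0, 2]
            warped[sel, 1] = T[1, 0] * p[:, 0] + T[1, 1] * p[:, 1] + T[1, 2]
        return warped, in_mesh


def warp_points(
    points,
    src_landmarks: LandmarkSet,
    mesh: TriangleMesh,
    dst_shape: MeanShape,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp points from a face's frame into the mean-face frame.

    Thin wrapper over :class:`PiecewiseAffineWarp`; returns
    ``(warped_points, in_mesh_flags)``.
    """
    warper = PiecewiseAffineWarp(mesh=mesh).fit(src_landmarks.points, dst_shape.points)
    return warper.transform_with_flags(points)


def warp_trial_gaze(
    trial,
    saccades,
    landmarks: LandmarkSet,
    mesh: TriangleMesh,
    mean_shape: MeanShape,
    exclude_amp_dva: float = 1.0,
) -> pd.DataFrame:
    """Warp a trial's fixational gaze into the mean-face frame.

    Applies the same large-saccade sample exclusion as the heatmap recipe,
    warps the remaining valid on-image samples, and preserves timestamps so
    dwell time is conserved for in-mesh samples.  The result carries columns
    ``t_ms, x_dva, y_dva, in_mesh`` plus a ``frac_out_of_mesh`` attribute
    in ``DataFrame.attrs``.
    """
    from gazemorph.heatmaps import saccade_exclusion_mask

    if landmarks is None:
        raise ValueError(f"trial {trial.trial_id}: no landmarks for image {trial.image_id}")
    view = trial.viewing_samples
    keep = view["on_image"].to_numpy(dtype=bool)
    keep &= np.isfinite(view["x_dva"].to_numpy()) & np.isfinite(view["y_dva"].to_numpy())
    keep &= ~saccade_exclusion_mask(view, saccades, exclude_amp_dva)
    pts = view[keep]
    warped, in_mesh = warp_points(
        pts[["x_dva", "y_dva"]].to_numpy(), landmarks, mesh, mean_shape
    )
    out = pd.DataFrame(
        {
            "t_ms": pts["t_ms"].to_numpy(),
            "x_dva": warped[:, 0],
            "y_dva": warped[:, 1],
            "in_mesh": in_mesh,
        }
    )
    out.attrs["frac_out_of_mesh"] = float((~in_mesh).mean()) if len(out) else float("nan")
    return out
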