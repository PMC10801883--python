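"""Mean shape, triangulation, and piecewise-affine gaze warping."""

import numpy as np
import pytest

from gazemorph.io import LandmarkSet
from gazemorph.morphing import (
    MeanShape,
    PiecewiseAffineWarp,
    compute_mean_shape,
    triangle_affine,
    triangulate,
    warp_points,
    warp_trial_gaze,
)
from gazemorph.io import mirror_landmarks

from conftest import make_trial


def _bary_oracle(p, src_tri, dst_tri):
    """Independent barycentric-coordinate warp of one point."""
    A = np.column_stack([src_tri[0] - src_tri[2], src_tri[1] - src_tri[2]])
    l12 = np.linalg.solve(A, p - src_tri[2])
    lam = np.array([l12[0], l12[1], 1 - l12.sum()])
    return lam @ dst_tri


class TestMeanShape:
    def test_identical_sets_give_that_set(self, face_layout):
        m = compute_mean_shape([face_layout, face_layout, face_layout])
        np.testing.assert_allclose(m.points, face_layout.points)

    def test_set_plus_mirror_is_symmetric(self, face_layout):
        m = compute_mean_shape([face_layout, mirror_landmarks(face_layout)])
        remirrored = mirror_landmarks(
            LandmarkSet(image_id="m", points=m.points)
        )
        np.testing.assert_allclose(remirrored.points, m.points, atol=1e-9)

    def test_mean_matches_per_coordinate_oracle(self, face_layout):
        rng = np.random.default_rng(0)
        sets = [
            LandmarkSet(image_id=f"r{i}", points=face_layout.points + rng.normal(0, 1, (26, 2)))
            for i in range(3)
        ]
        m = compute_mean_shape(sets)
        expect = (sets[0].points + sets[1].points + sets[2].points) / 3.0
        np.testing.assert_allclose(m.points, expect, atol=1e-12)


class TestTriangulate:
    def test_three_points_one_triangle(self):
        mesh = triangulate(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        assert len(mesh) == 1

    def test_unit_square_two_triangles(self):
        mesh = triangulate(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))
        assert len(mesh) == 2

    def test_collinear_raises(self):
        with pytest.raises(ValueError):
            triangulate(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))

    def test_empty_circumcircle_property(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-5, 5, (26, 2))
        mesh = triangulate(pts)
        for tri in mesh.vertex_indices:
            a, b, c = pts[tri]
            # circumcenter via brute-force linear solve
            M = 2 * np.array([b - a, c - a])
            rhs = np.array([b @ b - a @ a, c @ c - a @ a])
            center = np.linalg.solve(M, rhs)
            r2 = np.sum((a - center) ** 2)
            others = np.delete(np.arange(26), tri)
            d2 = np.sum((pts[others] - center) ** 2, axis=1)
            assert np.all(d2 >= r2 - 1e-9)


class TestTriangleAffine:
    def test_identity_translation_scale(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(triangle_affine(src, src), np.eye(3), atol=1e-12)
        shifted = src + (2.0, 3.0)
        T = triangle_affine(src, shifted)
        np.testing.assert_allclose(T[:2, 2], (2.0, 3.0), atol=1e-12)
        np.testing.assert_allclose(T[:2, :2], np.eye(2), atol=1e-12)
        T2 = triangle_affine(src, 2 * src)
        np.testing.assert_allclose(T2[:2, :2], 2 * np.eye(2), atol=1e-12)
        np.testing.assert_allclose(T2[:2, 2], 0.0, atol=1e-12)

    def test_degenerate_source_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            triangle_affine(np.array([[0, 0], [1, 1], [2, 2]], dtype=float), np.eye(3, 2))


class TestWarp:
    @pytest.fixture
    def warp_setup(self, landmark_pair):
        src, _ = landmark_pair
        rng = np.random.default_rng(7)
        dst = MeanShape(points=src.points + rng.normal(0, 0.6, (26, 2)))
        mesh = triangulate(dst)
        return src, dst, mesh

    def test_landmarks_map_exactly(self, warp_setup):
        src, dst, mesh = warp_setup
        warped, in_mesh = warp_points(src.points, src, mesh, dst)
        assert in_mesh.all()
        np.testing.assert_allclose(warped, dst.points, atol=1e-9)

    def test_centroids_map_to_centroids(self, warp_setup):
        src, dst, mesh = warp_setup
        src_tris = mesh.triangles_at(src.points)
        dst_tris = mesh.triangles_at(dst.points)
        warped, _ = warp_points(src_tris.mean(axis=1), src, mesh, dst)
        np.testing.assert_allclose(warped, dst_tris.mean(axis=1), atol=1e-9)

    def test_random_points_match_barycentric_oracle(self, warp_setup):
        src, dst, mesh = warp_setup
        warper = PiecewiseAffineWarp(mesh=mesh).fit(src.points, dst.points)
        rng = np.random.default_rng(8)
        # random interior points: convex combinations within random triangles
        tri_idx = rng.integers(0, len(mesh), 1000)
        w = rng.dirichlet((1, 1, 1), 1000)
        src_tris = mesh.triangles_at(src.points)
        pts = np.einsum("nk,nkd->nd", w, src_tris[tri_idx])
        warped, in_mesh = warper.transform_with_flags(pts)
        assert in_mesh.all()
        dst_tris = mesh.triangles_at(dst.points)
        for n in range(1000):
            i = warper.assign_triangles(pts[n : n + 1])[0]
            expect = _bary_oracle(pts[n], src_tris[i], dst_tris[i])
            assert np.max(np.abs(warped[n] - expect)) < 1e-9

    def test_edge_continuity(self, warp_setup):
        # midpoints of shared edges must map identically through both triangles
        src, dst, mesh = warp_setup
        warper = PiecewiseAffineWarp(mesh=mesh).fit(src.points, dst.points)
        from collections import defaultdict

        edge_tris = defaultdict(list)
        for ti, tri in enumerate(mesh.vertex_indices):
            for a, b in ((0, 1), (1, 2), (0, 2)):
                edge_tris[tuple(sorted((tri[a], tri[b])))].append(ti)
        shared = [(e, ts) for e, ts in edge_tris.items() if len(ts) == 2]
        assert shared
        for (i, j), (t1, t2) in shared:
            mid = (src.points[i] + src.points[j]) / 2.0
            out = []
            for t in (t1, t2):
                T = warper.affines_[t]
                out.append(T[:2, :2] @ mid + T[:2, 2])
            np.testing.assert_allclose(out[0], out[1], atol=1e-9)

    def test_out_of_hull_flagged_not_warped(self, warp_setup):
        src, dst, mesh = warp_setup
        far = np.array([[100.0, 100.0], [-50.0, 0.0]])
        warped, in_mesh = warp_points(far, src, mesh, dst)
        assert not in_mesh.any()
        np.testing.assert_allclose(warped, far)

    def test_inverse_composition_consistency(self, warp_setup):
        src, dst, mesh = warp_setup
        fwd = PiecewiseAffineWarp(mesh=mesh).fit(src.points, dst.points)
        back = PiecewiseAffineWarp(mesh=mesh).fit(dst.points, src.points)
        rng = np.random.default_rng(9)
        tri_idx = rng.integers(0, len(mesh), 200)
        w = rng.dirichlet((1, 1, 1), 200)
        pts = np.einsum("nk,nkd->nd", w, mesh.triangles_at(src.points)[tri_idx])
        there, _ = fwd.transform_with_flags(pts)
        round_trip, _ = back.transform_with_flags(there)
        np.testing.assert_allclose(round_trip, pts, atol=1e-8)


class TestWarpTrialGaze:
    def test_pinned_gaze_maps_to_mean_landmark(self, landmark_pair):
        src, _ = landmark_pair
        dst = MeanShape(points=src.points * 0.9)
        mesh = triangulate(dst)
        pin = src.point("nose_tip")
        n = 2000
        tr = make_trial(np.arange(n), np.full(n, pin[0]), np.full(n, pin[1]))
        w = warp_trial_gaze(tr, [], src, mesh, dst)
        assert len(w) == n
        assert w["in_mesh"].all()
        np.testing.assert_allclose(w[["x_dva", "y_dva"]].to_numpy(), np.tile(pin * 0.9, (n, 1)), atol=1e-9)

    def test_off_face_gaze_fully_out_of_mesh(self, landmark_pair):
        src, _ = landmark_pair
        dst = MeanShape(points=src.points)
        mesh = triangulate(dst)
        n = 500
        tr = make_trial(np.arange(n), np.full(n, 13.0), np.full(n, 10.0))
        w = warp_trial_gaze(tr, [], src, mesh, dst)
        assert w.attrs["frac_out_of_mesh"] == 1.0

    def test_per_triangle_dwell_conserved(self, landmark_pair):
        src, _ = landmark_pair
        rng = np.random.default_rng(11)
        dst = MeanShape(points=src.points + rng.normal(0, 0.5, (26, 2)))
        mesh = triangulate(dst)
        warper = PiecewiseAffineWarp(mesh=mesh).fit(src.points, dst.points)
        tri_idx = rng.integers(0, len(mesh), 1500)
        w = rng.dirichlet((2, 2, 2), 1500)
        pts = np.einsum("nk,nkd->nd", w, mesh.triangles_at(src.points)[tri_idx])
        tr = make_trial(np.arange(1500), pts[:, 0], pts[:, 1])
        out = warp_trial_gaze(tr, [], src, mesh, dst)
        assert out["in_mesh"].all()
        src_assign = warper.assign_triangles(pts)
        dst_warper = PiecewiseAffineWarp(mesh=mesh).fit(dst.points, dst.points)
        dst_assign = dst_warper.assign_triangles(out[["x_dva", "y_dva"]].to_numpy())
        np.testing.assert_array_equal(src_assign, dst_assign)
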