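"""Rigid preprocessing: mirroring, axis alignment, crops, landmark alignment."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from radsym.mesh import LabelVolume, LandmarkSet, SurfaceMesh
from radsym.phantom import PhantomParams, generate_pair, generate_phantom
from radsym.preprocess import (
    DegenerateGeometryError,
    EmptyResultError,
    PreprocessConfig,
    crop_by_plane,
    extract_isosurface,
    isolate_articular_surface,
    mirror_x,
    preprocess_pair,
    principal_axis_align,
    rigid_align_landmarks,
    rodrigues_rotation,
    shift_lowest_to_origin,
)


def _lm(mesh):
    v = mesh.vertices
    return LandmarkSet({"RS": v[np.argmax(v[:, 2])], "DSN": v[np.argmin(v[:, 0])]})


class TestMirror:
    def test_negates_x_only(self):
        m = SurfaceMesh([[1, 2, 3], [0, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        out, _ = mirror_x(m, _lm(m))
        assert np.array_equal(out.vertices[0], [-1, 2, 3])

    def test_involution(self, small_phantom):
        mesh, lm = small_phantom
        twice, lm2 = mirror_x(*mirror_x(mesh, lm))
        assert np.array_equal(twice.vertices, mesh.vertices)
        assert np.array_equal(twice.faces, mesh.faces)
        assert lm2 == lm

    def test_signed_volume_preserved(self, small_phantom):
        mesh, lm = small_phantom
        mirrored, _ = mirror_x(mesh, lm)
        assert mirrored.signed_volume() == pytest.approx(mesh.signed_volume(), rel=1e-12)


class TestPrincipalAxisAlign:
    def test_already_aligned_is_identity(self):
        # symmetric cloud with exactly diagonal covariance, dominant along z
        xy = np.array([[1, 0], [-1, 0], [0, 1], [0, -1], [0, 0]], dtype=float)
        z = np.linspace(-20, 20, 9)
        pts = np.array([[x, y, zz] for x, y in xy for zz in z])
        m = SurfaceMesh(pts, [[0, 1, 2]])
        lm = LandmarkSet({"RS": pts[np.argmax(pts[:, 2])], "DSN": pts[0]})
        _, _, xf = principal_axis_align(m, lm)
        assert np.allclose(xf.rotation, np.eye(3), atol=1e-9)

    def test_cylinder_axis_swap(self, rng):
        pts = rng.normal(size=(300, 3)) * [30, 1, 1]  # long axis along x
        m = SurfaceMesh(pts, [[0, 1, 2]])
        lm = LandmarkSet({"RS": pts[np.argmax(pts[:, 0])], "DSN": pts[0]})
        out, _, _ = principal_axis_align(m, lm)
        # the long extent moves to z (up to the small PCA tilt of a random cloud)
        assert np.ptp(out.vertices[:, 2]) == pytest.approx(np.ptp(pts[:, 0]), rel=0.01)

    def test_random_rotations_recover_axis(self, small_phantom, rng):
        mesh, lm = small_phantom
        for seed in range(5):
            R = Rotation.random(random_state=seed).as_matrix()
            rotated = SurfaceMesh(mesh.vertices @ R.T, mesh.faces)
            rlm = lm.transformed(lambda p: p @ R.T)
            out, _, _ = principal_axis_align(rotated, rlm)
            v = out.vertices - out.vertices.mean(axis=0)
            evals, evecs = np.linalg.eigh(np.cov(v.T))
            assert abs(evecs[:, -1] @ [0, 0, 1]) > 0.9999

    def test_rs_end_points_up(self, small_phantom):
        mesh, lm = small_phantom
        out, olm, _ = principal_axis_align(mesh, lm)
        assert olm["RS"][2] > out.centroid()[2]

    def test_isotropic_cloud_rejected(self):
        g = np.stack(np.meshgrid(*[np.arange(4)] * 3, indexing="ij"), -1).reshape(-1, 3)
        m = SurfaceMesh(g.astype(float), [[0, 1, 2]])
        with pytest.raises(DegenerateGeometryError):
            principal_axis_align(m, LandmarkSet({"RS": g[0], "DSN": g[1]}))

    def test_rodrigues_matches_scipy(self, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        assert np.allclose(
            rodrigues_rotation(axis, 0.7),
            Rotation.from_rotvec(0.7 * axis).as_matrix(),
            atol=1e-12,
        )


class TestShiftLowest:
    def test_translation_and_idempotence(self, small_phantom):
        mesh, lm = small_phantom
        shifted = SurfaceMesh(mesh.vertices + [3, -4, 10], mesh.faces)
        out, olm = shift_lowest_to_origin(shifted, lm)
        low = out.vertices[np.argmin(out.vertices[:, 2])]
        assert np.allclose(low, 0, atol=1e-12)
        again, _ = shift_lowest_to_origin(out, olm)
        assert np.array_equal(again.vertices, out.vertices)

    def test_landmark_offsets_preserved(self, small_phantom):
        mesh, lm = small_phantom
        out, olm = shift_lowest_to_origin(mesh, lm)
        assert np.allclose(
            olm["RS"] - out.vertices[0], lm["RS"] - mesh.vertices[0], atol=1e-12
        )


class TestCropByPlane:
    def test_crop_at_z50(self, small_phantom):
        mesh, _ = small_phantom  # spans z in [0, 60]
        out = crop_by_plane(mesh, (0, 0, 50.0), (0, 0, 1), keep="below")
        assert out.vertices[:, 2].max() == pytest.approx(50.0, abs=1e-9)
        assert out.vertices[:, 2].min() == pytest.approx(0.0, abs=1e-9)

    def test_noop_when_plane_outside(self, small_phantom):
        mesh, _ = small_phantom
        out = crop_by_plane(mesh, (0, 0, 1000.0), (0, 0, 1), keep="below")
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_everything_removed_raises(self, small_phantom):
        mesh, _ = small_phantom
        with pytest.raises(EmptyResultError):
            crop_by_plane(mesh, (0, 0, -10.0), (0, 0, 1), keep="below")

    def test_spherical_cap_area(self, sphere10):
        # cap above z = h on a radius-10 sphere has lateral area 2*pi*R*(R-h)
        h = 4.0
        cap = crop_by_plane(sphere10, (0, 0, h), (0, 0, 1), keep="above")
        assert cap.area == pytest.approx(2 * np.pi * 10 * (10 - h), rel=0.02)

    def test_vertex_set_matches_brute_force_filter(self, small_phantom):
        mesh, _ = small_phantom
        z0 = 30.0
        out = crop_by_plane(mesh, (0, 0, z0), (0, 0, 1), keep="below")
        kept = mesh.vertices[mesh.vertices[:, 2] <= z0 + 1e-9]
        # every strictly-inside original vertex survives; extras are clip points
        from scipy.spatial import cKDTree

        d = cKDTree(out.vertices).query(kept)[0]
        assert d.max() < 1e-9
        on_plane = np.abs(out.vertices[:, 2] - z0) < 1e-9
        inside = cKDTree(mesh.vertices).query(out.vertices[~on_plane])[0]
        assert inside.max() < 1e-9


class TestRigidAlignLandmarks:
    def test_identity(self, rng):
        pts = rng.normal(size=(5, 3))
        xf = rigid_align_landmarks(pts, pts)
        assert np.allclose(xf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(xf.translation, 0, atol=1e-9)

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(6, 3)) * 10
        R = Rotation.random(random_state=7).as_matrix()
        t = np.array([4.0, -2.0, 9.0])
        xf = rigid_align_landmarks(pts, pts @ R.T + t)
        assert np.allclose(xf.rotation, R, atol=1e-9)
        assert np.allclose(xf.translation, t, atol=1e-8)

    def test_reflected_target_yields_proper_rotation(self, rng):
        pts = rng.normal(size=(8, 3))
        mirrored = pts * [-1, 1, 1]
        xf = rigid_align_landmarks(pts, mirrored)
        assert np.linalg.det(xf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_raises(self):
        pts = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            rigid_align_landmarks(pts, pts + 1.0)

    def test_least_squares_optimality_spot_check(self, rng):
        src = rng.normal(size=(5, 3)) * 5
        tgt = src @ Rotation.random(random_state=9).as_matrix().T + [1, 2, 3]
        tgt = tgt + 0.3 * rng.normal(size=tgt.shape)  # noisy correspondence
        best = rigid_align_landmarks(src, tgt)
        best_res = ((best.apply(src) - tgt) ** 2).sum()
        for seed in range(1000):
            r = np.random.default_rng(seed)
            R = Rotation.random(random_state=seed).as_matrix()
            t = r.normal(size=3) * 5
            res = ((src @ R.T + t - tgt) ** 2).sum()
            assert best_res <= res + 1e-9


class TestArticularIsolation:
    def test_predicate_and_oracle(self, small_phantom):
        mesh, lm = small_phantom
        out = isolate_articular_surface(mesh, lm)
        z_cut = lm["DSN"][2]
        assert out.vertices[:, 2].min() >= z_cut - 1e-12
        # vertex count equals brute-force face filter
        keep = mesh.vertices[:, 2] >= z_cut
        face_keep = keep[mesh.faces].all(axis=1)
        expected = len(np.unique(mesh.faces[face_keep]))
        assert out.n_vertices == expected

    def test_dsn_at_minimum_returns_whole_mesh(self, small_phantom):
        mesh, lm = small_phantom
        low = LandmarkSet({"RS": lm["RS"], "DSN": mesh.vertices[np.argmin(mesh.vertices[:, 2])]})
        out = isolate_articular_surface(mesh, low)
        assert out.n_vertices == mesh.n_vertices

    def test_dsn_above_everything_raises(self, small_phantom):
        mesh, lm = small_phantom
        high = LandmarkSet({"RS": lm["RS"], "DSN": [0, 0, 1e4]})
        with pytest.raises(EmptyResultError):
            isolate_articular_surface(mesh, high)


class TestPreprocessPair:
    @pytest.fixture(scope="class")
    def processed(self):
        pair = generate_pair(PhantomParams(mesh_resolution=900), asymmetry_mm=0.0, seed=5)
        return preprocess_pair(
            pair.left, pair.left_landmarks, pair.right, pair.right_landmarks,
            PreprocessConfig(target_vertices=500),
        )

    def test_outputs_span_final_crop_length(self, processed):
        L, _, R, _ = processed
        assert L.vertices[:, 2].min() == pytest.approx(0.0, abs=1e-6)
        assert L.vertices[:, 2].max() == pytest.approx(43.0, abs=1e-6)
        assert R.vertices[:, 2].max() == pytest.approx(43.0, abs=0.5)

    def test_symmetric_pair_aligns(self, processed):
        L, Llm, R, Rlm = processed
        assert np.linalg.norm(Llm["RS"] - Rlm["RS"]) < 0.1

    def test_vertex_budget(self, processed):
        L, _, R, _ = processed
        assert abs(L.n_vertices - 500) <= 10
        assert abs(R.n_vertices - 500) <= 10

    def test_symmetric_pair_surfaces_close(self, processed):
        from scipy.spatial import cKDTree

        L, _, R, _ = processed
        d = cKDTree(L.vertices).query(R.vertices)[0]
        # decimation error bound: surfaces of an exactly symmetric pair stay
        # within the decimation tolerance of each other
        assert np.mean(d) < 0.5

    def test_rigid_steps_preserve_pairwise_distances(self, small_phantom):
        mesh, lm = small_phantom
        sub = SurfaceMesh(mesh.vertices[:80], [[0, 1, 2]])
        sublm = LandmarkSet({"RS": lm["RS"], "DSN": lm["DSN"]})
        d0 = pdist(sub.vertices)
        m1, l1 = mirror_x(sub, sublm)
        m2, l2, _ = principal_axis_align(m1, l1)
        m3, _ = shift_lowest_to_origin(m2, l2)
        assert np.allclose(pdist(m3.vertices), d0, rtol=1e-9)
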