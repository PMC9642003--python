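import collections

import numpy as np
import pytest
from scipy.spatial import cKDTree

from memsta.geometry import theta_of_matrices
from memsta.io.volume import VolumeGrid
from memsta.surface import (
    SphereModel,
    TubeModel,
    gaussian_smooth,
    label_objects,
    pick_mesh,
    pick_sphere,
    pick_tube,
    resample_axis,
    segmentation_to_mesh,
)
from memsta.synthetic import make_blob_volume, make_tube_lattice


class TestResampleAxis:
    def test_straight_axis_regular_spacing(self):
        pts, tans = resample_axis([[0, 0, 0], [100, 0, 0]], 8.0)
        assert len(pts) == 13
        np.testing.assert_allclose(pts[:, 0], np.arange(13) * 8.0, atol=1e-9)
        np.testing.assert_allclose(tans, np.tile([1.0, 0, 0], (13, 1)), atol=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            resample_axis([[1, 1, 1], [1, 1, 1]], 5.0)

    def test_arc_spacing_on_quarter_circle(self):
        t = np.linspace(0, np.pi / 2, 2000)
        arc = np.stack([50 * np.cos(t), 50 * np.sin(t), np.zeros_like(t)], axis=1)
        pts, _ = resample_axis(arc, 5.0)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.all(np.abs(gaps - 5.0) < 0.1)

    def test_short_axis_gives_single_start_point(self):
        pts, _ = resample_axis([[0, 0, 0], [3, 0, 0]], 8.0)
        assert len(pts) == 1
        np.testing.assert_allclose(pts[0], [0, 0, 0])


@pytest.fixture(scope="module")
def straight():
    tube = TubeModel(axis_points=[[0, 0, 0], [100, 0, 0]], radius=20.0)
    return tube, pick_tube(tube, 8.0)


class TestPickTube:
    def test_ring_count_and_radius(self, straight):
        tube, ps = straight
        assert len(ps) == 13 * 16
        radial = np.linalg.norm(ps.positions[:, 1:], axis=1)
        np.testing.assert_allclose(radial, 20.0, atol=1e-6)

    def test_normals_perpendicular_to_axis_and_outward(self, straight):
        _, ps = straight
        normals = ps.matrices[:, :, 2]
        assert np.max(np.abs(normals[:, 0])) < 1e-9  # ⟂ tangent (x)
        radial = ps.positions.copy()
        radial[:, 0] = 0.0
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert np.min(np.einsum("ij,ij->i", normals, radial)) > 0.999

    def test_theta_sweeps_full_latitude_range(self, straight):
        _, ps = straight
        theta = theta_of_matrices(ps.matrices)
        assert theta.min() < 1.0 and theta.max() > 89.0

    def test_in_plane_axis_follows_tangent(self, straight):
        _, ps = straight
        np.testing.assert_allclose(ps.matrices[:, :, 0], np.tile([1.0, 0, 0], (len(ps), 1)), atol=1e-9)

    def test_oversampling_warning(self):
        tube = TubeModel(axis_points=[[0, 0, 0], [50, 0, 0]], radius=10.0)
        with pytest.warns(UserWarning, match="oversampling"):
            pick_tube(tube, 8.0, expected_spacing=6.0)

    def test_curved_axis_keeps_radius(self):
        t = np.linspace(0, np.pi / 2, 500)
        arc = np.stack([60 * np.cos(t), 60 * np.sin(t), np.zeros_like(t)], axis=1)
        tube = TubeModel(axis_points=arc, radius=15.0)
        ps = pick_tube(tube, 6.0)
        d_axis = cKDTree(arc).query(ps.positions)[0]
        assert np.all(np.abs(d_axis - 15.0) < 0.2)


class TestPickSphere:
    def test_count_formula_and_radius(self):
        ps = pick_sphere(SphereModel(center=[50, 50, 50], radius=20.0), 8.0)
        assert len(ps) == 79  # round(4*pi*400/64)
        np.testing.assert_allclose(
            np.linalg.norm(ps.positions - [50, 50, 50], axis=1), 20.0, atol=1e-9
        )

    def test_normals_radial(self):
        ps = pick_sphere(SphereModel(center=[0, 0, 0], radius=20.0), 8.0)
        radial = ps.positions / 20.0
        np.testing.assert_allclose(ps.matrices[:, :, 2], radial, atol=1e-9)

    def test_near_uniform_spacing(self):
        ps = pick_sphere(SphereModel(center=[0, 0, 0], radius=30.0), 5.0)
        assert len(ps) >= 100
        d = cKDTree(ps.positions).query(ps.positions, k=2)[0][:, 1]
        assert np.all(d > 0.7 * 5.0) and np.all(d < 1.4 * 5.0)


class TestGaussianSmoothAndLabel:
    def test_sigma_zero_is_identity(self, rng):
        g = VolumeGrid(rng.random((8, 8, 8)))
        np.testing.assert_array_equal(gaussian_smooth(g, 0.0).data, g.data)

    def test_intensity_conserved_for_interior_signal(self):
        data = np.zeros((32, 32, 32))
        x = np.arange(32) - 16
        ball = x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2 <= 36
        data[ball] = 1.0
        sm = gaussian_smooth(VolumeGrid(data), 2.0)
        assert abs(sm.data.sum() - data.sum()) / data.sum() < 1e-3

    def test_two_disjoint_balls(self):
        data = np.zeros((40, 20, 20))
        for cx in (8, 30):
            x, y, z = np.ogrid[:40, :20, :20]
            data[(x - cx) ** 2 + (y - 10) ** 2 + (z - 10) ** 2 <= 25] = 1.0
        _, n = label_objects(VolumeGrid(data), 0.5, min_voxels=10)
        assert n == 2

    def test_corner_touching_blocks_are_one_object(self):
        data = np.zeros((10, 10, 10))
        data[2:5, 2:5, 2:5] = 1.0
        data[5:8, 5:8, 5:8] = 1.0  # shares only the corner at (5,5,5) diagonally
        _, n = label_objects(VolumeGrid(data), 0.5, min_voxels=1)
        assert n == 1

    def test_empty_volume_gives_zero_objects(self):
        _, n = label_objects(VolumeGrid(np.zeros((8, 8, 8))), 0.5)
        assert n == 0

    def test_small_fragments_dropped(self):
        data = np.zeros((20, 20, 20))
        data[2:10, 2:10, 2:10] = 1.0  # 512 voxels
        data[15, 15, 15] = 1.0  # speck
        _, n = label_objects(VolumeGrid(data), 0.5, min_voxels=100)
        assert n == 1


@pytest.fixture(scope="module")
def ball():
    blob = make_blob_volume(15.0, {}, 64, seed=0)
    mesh = segmentation_to_mesh(blob.volume, 1.0, 0.5)
    return blob, mesh


class TestMeshing:
    def test_vertices_on_analytic_sphere(self, ball):
        blob, mesh = ball
        rho = np.linalg.norm(mesh.vertices - blob.center, axis=1)
        assert np.all(np.abs(rho - 15.0) < 1.0)

    def test_watertight(self, ball):
        _, mesh = ball
        edges = collections.Counter()
        for f in mesh.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                edges[tuple(sorted((int(a), int(b))))] += 1
        assert set(edges.values()) == {2}

    def test_normals_near_radial(self, ball):
        blob, mesh = ball
        rel = mesh.vertices - blob.center
        rel /= np.linalg.norm(rel, axis=1, keepdims=True)
        cosang = np.einsum("ij,ij->i", mesh.vertex_normals, rel)
        assert np.all(np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 6.0)

    def test_iso_outside_range_rejected(self, ball):
        blob, _ = ball
        with pytest.raises(ValueError, match="no surface"):
            segmentation_to_mesh(blob.volume, 1.0, 2.0)


@pytest.fixture(scope="module")
def ball_picks(ball):
    blob, mesh = ball
    return blob, mesh, pick_mesh(mesh, 5.0, direction="outward", seed=11)


class TestPickMesh:
    def test_points_on_surface(self, ball_picks):
        blob, _, ps = ball_picks
        rho = np.linalg.norm(ps.positions - blob.center, axis=1)
        assert np.all(np.abs(rho - 15.0) < 1.0)

    def test_outward_directionality(self, ball_picks):
        blob, mesh, ps = ball_picks
        dots = np.einsum("ij,ij->i", ps.matrices[:, :, 2], ps.positions - mesh.centre_of_mass())
        assert np.all(dots > 0)

    def test_inward_flips_normals(self, ball_picks):
        _, mesh, _ = ball_picks
        ps = pick_mesh(mesh, 5.0, direction="inward", seed=11)
        dots = np.einsum("ij,ij->i", ps.matrices[:, :, 2], ps.positions - mesh.centre_of_mass())
        assert np.all(dots < 0)

    def test_thinning_contract(self, ball_picks):
        _, _, ps = ball_picks
        d = cKDTree(ps.positions).query(ps.positions, k=2)[0][:, 1]
        assert d.min() >= 2.5 - 1e-9

    def test_reproducible_for_fixed_seed(self, ball_picks):
        _, mesh, ps = ball_picks
        again = pick_mesh(mesh, 5.0, direction="outward", seed=11)
        np.testing.assert_array_equal(again.positions, ps.positions)


def test_oversampling_guarantee_on_synthetic_lattice():
    """Picking at half the lattice spacing puts a pick within spacing/2 of
    every planted particle, so each real particle lands in some subtomogram."""
    truth = make_tube_lattice(radius=20, length=120, rise=6, twist_deg=30, jitter_sigma=0.0, seed=3)
    spacing = truth.nn_spacing
    picks = pick_tube(truth.model, spacing / 2.0)
    d, _ = cKDTree(picks.positions).query(truth.particles.positions)
    assert np.all(d <= spacing / 2.0)
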