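import numpy as np
import pytest

from memsta.geometry import euler_to_matrix
from memsta.lattice import (
    NeighbourMap,
    NeighbourMask,
    binarize_map,
    compute_neighbour_map,
    filter_by_neighbours,
)
from memsta.synthetic import make_tube_lattice

from conftest import make_set


class TestNeighbourMap:
    def test_identity_pair_symmetric_counts(self):
        s = make_set([[50, 50, 50], [60, 50, 50]])
        nmap = compute_neighbour_map(s, box=33, max_dist=15)
        c = nmap.centre
        assert nmap.grid[c + 10, c, c] == 1
        assert nmap.grid[c - 10, c, c] == 1
        assert nmap.grid.sum() == 2
        assert nmap.n_contributing == 2

    def test_rotated_frame_moves_contribution(self):
        rz90 = euler_to_matrix((90, 0, 0), "dynamo_zxz")
        s = make_set(
            [[50, 50, 50], [60, 50, 50]],
            matrices=np.stack([rz90, np.eye(3)]),
        )
        nmap = compute_neighbour_map(s, box=33, max_dist=15)
        c = nmap.centre
        # R1^T (10,0,0) = (0,-10,0)
        assert nmap.grid[c, c - 10, c] == 1
        assert nmap.grid[c - 10, c, c] == 1

    def test_single_particle_empty_map(self):
        nmap = compute_neighbour_map(make_set([[0, 0, 0]]), box=17)
        assert nmap.grid.sum() == 0 and nmap.n_contributing == 0

    def test_pairs_across_objects_ignored(self):
        s = make_set([[0, 0, 0], [5, 0, 0]], object_id=[1, 2])
        assert compute_neighbour_map(s, box=17).grid.sum() == 0

    def test_even_box_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            compute_neighbour_map(make_set([[0, 0, 0]]), box=32)

    def test_centrosymmetric_for_identity_orientations(self, rng):
        s = make_set(rng.uniform(0, 40, (40, 3)))
        g = compute_neighbour_map(s, box=33, max_dist=15).grid
        np.testing.assert_array_equal(g, g[::-1, ::-1, ::-1])


class TestBinarize:
    def _map_with(self, entries, box=17):
        g = np.zeros((box, box, box), dtype=np.int64)
        c = (box - 1) // 2
        for (dx, dy, dz), count in entries:
            g[c + dx, c + dy, c + dz] = count
        return NeighbourMap(grid=g)

    def test_single_peak_survives(self):
        m = self._map_with([((5, 0, 0), 8)])
        mask = binarize_map(m, sigma=0.0, level=0.5)
        c = mask.centre
        assert mask.grid[c + 5, c, c]
        assert mask.grid.sum() == 1

    def test_weak_peak_suppressed(self):
        m = self._map_with([((5, 0, 0), 10), ((-5, 0, 0), 3)])
        mask = binarize_map(m, sigma=0.0, level=0.5)
        c = mask.centre
        assert mask.grid[c + 5, c, c] and not mask.grid[c - 5, c, c]

    def test_centre_exclusion(self):
        m = self._map_with([((0, 0, 0), 50), ((1, 0, 0), 50), ((6, 0, 0), 50)])
        mask = binarize_map(m, sigma=0.0, level=0.5, exclusion_radius=2.0)
        c = mask.centre
        assert not mask.grid[c, c, c] and not mask.grid[c + 1, c, c]
        assert mask.grid[c + 6, c, c]

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="no neighbour density"):
            binarize_map(self._map_with([]), 1.0, 0.2)

    def test_mask_components_at_planted_lattice_positions(self):
        truth = make_tube_lattice(
            radius=20, length=240, rise=6, twist_deg=30, jitter_sigma=0.5, seed=4
        )
        nmap = compute_neighbour_map(truth.particles, box=33, max_dist=15)
        mask = binarize_map(nmap, sigma=0.5, level=0.2)
        c = mask.centre
        from scipy import ndimage

        lab, n = ndimage.label(mask.grid)
        centroids = np.array(ndimage.center_of_mass(mask.grid, lab, range(1, n + 1))) - c
        for v in truth.expected_offsets:
            assert np.min(np.linalg.norm(centroids - v, axis=1)) <= 1.0


class TestFilter:
    def _lattice_mask(self, truth, max_dist=15):
        nmap = compute_neighbour_map(truth.particles, box=33, max_dist=max_dist)
        return binarize_map(nmap, sigma=0.5, level=0.2)

    def test_lone_particle_removed_lattice_retained(self):
        truth = make_tube_lattice(radius=20, length=120, rise=6, twist_deg=30, seed=0)
        ps = truth.particles.copy()
        lone = make_set([[500.0, 500, 500]])
        ps.tags = np.concatenate([ps.tags, [ps.tags.max() + 1]])
        ps.tomo_id = np.concatenate([ps.tomo_id, [1]])
        ps.object_id = np.concatenate([ps.object_id, [1]])
        ps.positions = np.vstack([ps.positions, lone.positions])
        ps.shifts = np.vstack([ps.shifts, lone.shifts])
        ps.matrices = np.vstack([ps.matrices, lone.matrices])
        ps.cc = np.concatenate([ps.cc, [0.5]])
        ps.class_label = np.concatenate([ps.class_label, [0]])
        mask = self._lattice_mask(truth)
        out = filter_by_neighbours(ps, mask, 15, 1)
        assert ps.tags.max() not in out.tags
        assert len(out) == len(truth.particles)

    def test_orientation_scramble_removes_particle(self):
        truth = make_tube_lattice(radius=20, length=120, rise=6, twist_deg=30, seed=0)
        mask = self._lattice_mask(truth)
        ps = truth.particles.copy()
        victim = len(ps) // 2  # interior particle
        # tip the frame about its in-plane y-axis: no lattice direction is
        # preserved (a spin about x would leave the on-axis neighbours fixed)
        tilt = euler_to_matrix((0, 60, 0), "relion_zyz")
        ps.matrices[victim] = ps.matrices[victim] @ tilt
        out = filter_by_neighbours(ps, mask, 15, 2)
        assert ps.tags[victim] not in out.tags

    def test_min_neighbours_zero_rejected(self):
        truth = make_tube_lattice(radius=20, length=60, rise=6, twist_deg=30, seed=0)
        mask = self._lattice_mask(truth)
        with pytest.raises(ValueError, match="min_neighbours"):
            filter_by_neighbours(truth.particles, mask, 15, 0)

    def test_geometry_mismatch_rejected(self):
        truth = make_tube_lattice(radius=20, length=60, rise=6, twist_deg=30, seed=0)
        mask = self._lattice_mask(truth)
        with pytest.raises(ValueError, match="half-width"):
            filter_by_neighbours(truth.particles, mask, max_dist=30.0)

    def test_idempotent_with_fixed_mask(self):
        truth = make_tube_lattice(
            radius=20, length=120, rise=6, twist_deg=30, jitter_sigma=0.5,
            fake_fraction=0.1, seed=6,
        )
        mask = self._lattice_mask(truth)
        once = filter_by_neighbours(truth.particles, mask, 15, 2)
        twice = filter_by_neighbours(once, mask, 15, 2)
        assert list(twice.tags) == list(once.tags)


def test_planted_fake_benchmark_small():
    """Unit-scale version of the end-to-end benchmark (full 20-seed run in
    the acceptance suite): fakes removed, interior lattice retained."""
    removed_fake = kept_interior = total_fake = total_interior = 0
    for seed in range(4):
        truth = make_tube_lattice(
            radius=20, length=240, rise=6, twist_deg=30, jitter_sigma=0.5,
            fake_fraction=0.1, seed=seed,
        )
        ps = truth.particles
        nmap = compute_neighbour_map(ps, box=33, max_dist=15)
        mask = binarize_map(nmap, sigma=0.5, level=0.2)
        kept = set(filter_by_neighbours(ps, mask, 15, 2).tags.tolist())
        fake = set(ps.tags[~truth.is_real].tolist())
        interior = set(ps.tags[truth.interior_mask()].tolist())
        total_fake += len(fake)
        total_interior += len(interior)
        removed_fake += len(fake - kept)
        kept_interior += len(interior & kept)
    assert removed_fake / total_fake >= 0.95
    assert kept_interior / total_interior >= 0.98
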