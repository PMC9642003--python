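"""Lattice-based neighbour cleaning.

Tightly packed coats arrange their subunits in a (pseudo-helical) lattice,
so every real particle has neighbours at set relative positions and
orientations.  Accumulating each particle's neighbours in *its own
reference frame* produces a 3D density with sharp peaks at the lattice
vectors; thresholding that density gives a mask of expected neighbour
positions, and particles with no neighbour inside the mask are lone or
misaligned picks that can be dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .particles import ParticleSet

__all__ = [
    "NeighbourMap",
    "NeighbourMask",
    "compute_neighbour_map",
    "binarize_map",
    "filter_by_neighbours",
]


@dataclass
class NeighbourMap:
    """Counts of relative neighbour positions in particle reference frames.

    The grid has odd edge length L, one particle-coordinate voxel per bin,
    and its origin at the centre voxel: grid[c + dx, c + dy, c + dz] with
    c = (L-1)//2 counts neighbours at relative position (dx, dy, dz).
    """

    grid: np.ndarray
    n_contributing: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("neighbour map must be a cubic 3D grid")
        if self.grid.shape[0] % 2 == 0:
            raise ValueError("neighbour map edge length must be odd")
        if np.any(self.grid < 0):
            raise ValueError("neighbour map counts must be >= 0")

    @property
    def centre(self) -> int:
        return (self.grid.shape[0] - 1) // 2


@dataclass
class NeighbourMask:
    """Binarized neighbour map: True at expected neighbour positions."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("neighbour mask must be a cubic 3D grid")
        if self.grid.shape[0] % 2 == 0:
            raise ValueError("neighbour mask edge length must be odd")
        c = (self.grid.shape[0] - 1) // 2
        if self.grid[c, c, c]:
            raise ValueError("neighbour mask centre voxel must be False (self)")

    @property
    def centre(self) -> int:
        return (self.grid.shape[0] - 1) // 2


def _relative_offsets(pset: ParticleSet, max_dist: float):
    """Yield (i, voxel offset of j in i's frame) for all in-range pairs."""
    for _, idx in pset.groups():
        if len(idx) < 2:
            continue
        pos = pset.positions[idx]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(max_dist, output_type="ndarray")
        if len(pairs) == 0:
            continue
        for a, b in pairs:
            i, j = idx[a], idx[b]
            d = pset.positions[j] - pset.positions[i]
            # both ordered directions: j in i's frame and i in j's frame
            yield i, pset.matrices[i].T @ d
            yield j, pset.matrices[j].T @ (-d)


def compute_neighbour_map(
    pset: ParticleSet, box: int = 32, max_dist: float | None = None
) -> NeighbourMap:
    """Accumulate neighbour positions in each particle's reference frame.

    For every ordered pair (i, j) in the same (tomo_id, object_id) group
    with |x_j - x_i| <= max_dist, +1 is added at the voxel nearest to
    R_i^T (x_j - x_i), offset from the centre voxel.  ``box`` must be odd
    (it is rounded up if even is requested through the CLI); the default
    max_dist is (box-1)/2, the largest radius the grid can hold.
    """
    if box % 2 == 0:
        raise ValueError("box must be odd")
    c = (box - 1) // 2
    if max_dist is None:
        max_dist = float(c)
    if max_dist > c + 0.5:
        raise ValueError(f"max_dist {max_dist} exceeds grid half-width {c}")
    grid = np.zeros((box, box, box), dtype=np.int64)
    contributing = np.zeros(len(pset), dtype=bool)
    for i, rel in _relative_offsets(pset, max_dist):
        v = np.round(rel).astype(int) + c
        if np.all((v >= 0) & (v < box)):
            grid[v[0], v[1], v[2]] += 1
            contributing[i] = True
    return NeighbourMap(grid=grid, n_contributing=int(contributing.sum()))


def binarize_map(
    nmap: NeighbourMap,
    sigma: float = 0.5,
    level: float = 0.2,
    exclusion_radius: float = 2.0,
) -> NeighbourMask:
    """Smooth and threshold a neighbour map into a mask of expected positions.

    mask = gaussian(map, sigma) > level * max(smoothed); voxels within
    ``exclusion_radius`` of the centre are forced False so a particle can
    never count itself (or a duplicate of itself) as lattice support.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if nmap.grid.sum() == 0:
        raise ValueError("no neighbour density: the map is empty")
    smoothed = (
        ndimage.gaussian_filter(nmap.grid.astype(float), sigma, mode="constant")
        if sigma > 0
        else nmap.grid.astype(float)
    )
    mask = smoothed > level * smoothed.max()
    c = nmap.centre
    ax = np.arange(nmap.grid.shape[0]) - c
    dist2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    mask[dist2 <= exclusion_radius**2] = False
    return NeighbourMask(grid=mask)


def filter_by_neighbours(
    pset: ParticleSet,
    mask: NeighbourMask,
    max_dist: float | None = None,
    min_neighbours: int = 1,
) -> ParticleSet:
    """Keep particles with enough neighbours at expected lattice positions.

    Particle i is retained iff at least ``min_neighbours`` neighbours j
    (same group, within max_dist) fall on True mask voxels when expressed
    in i's reference frame.  Counting is single-pass against the original
    set: removing a bad particle never cascades into removing its former
    neighbours.
    """
    if min_neighbours < 1:
        raise ValueError("min_neighbours must be >= 1 (0 would keep everything)")
    box = mask.grid.shape[0]
    c = mask.centre
    if max_dist is None:
        max_dist = float(c)
    if max_dist > c + 0.5:
        raise ValueError(
            f"max_dist {max_dist} exceeds the mask's half-width {c}: geometry mismatch"
        )
    support = np.zeros(len(pset), dtype=np.int64)
    for i, rel in _relative_offsets(pset, max_dist):
        v = np.round(rel).astype(int) + c
        if np.all((v >= 0) & (v < box)) and mask.grid[v[0], v[1], v[2]]:
            support[i] += 1
    out = pset.subset(support >= min_neighbours)
    out.log(
        f"filter_by_neighbours: min_neighbours={min_neighbours}, "
        f"kept {len(out)}/{len(pset)}"
    )
    return out
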