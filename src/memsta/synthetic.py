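"""Ground-truth synthetic data for the picking/cleaning pipeline.

Emulates the geometry and score statistics the cleaning stages rely on,
for a coat like COPII's inner coat: a pseudo-helical particle lattice on a
cylindrical membrane, star-convex "blob" membranes voxelized into
segmentation volumes, cross-correlation scores with a smooth latitude
dependence plus noise and a contaminating outlier population, and the
convergence behaviour of a coarse alignment on oversampled picks.  Image
formation (projection, CTF, missing-wedge reconstruction) is not simulated:
every in-scope algorithm operates on coordinates, orientations and scores.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .geometry import normal_to_orientation, random_rotation_matrix
from .io.volume import VolumeGrid
from .particles import ParticleSet
from .surface import SphereModel, TubeModel

__all__ = [
    "SyntheticTruth",
    "BlobTruth",
    "make_tube_lattice",
    "make_blob_volume",
    "simulate_cc",
    "simulate_alignment_convergence",
]


@dataclass
class SyntheticTruth:
    """A planted particle lattice with per-particle ground-truth labels."""

    particles: ParticleSet
    is_real: np.ndarray  # True for lattice particles, False for fakes
    ring_index: np.ndarray  # lattice indices; -1 for fakes
    azimuth_index: np.ndarray
    lattice_vectors: np.ndarray  # (2, 3): ideal neighbour offsets in a particle's frame
    model: object = None
    nn_spacing: float = 0.0  # nearest-neighbour distance of the ideal (jitter-free) lattice
    # (4, 3): in-frame offsets of the +/- in-ring and +/- next-ring neighbours;
    # membrane curvature means the reverse offsets are not simple negations
    expected_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.is_real = np.asarray(self.is_real, dtype=bool)
        if len(self.is_real) != len(self.particles):
            raise ValueError("labels must cover all particles")

    def interior_mask(self) -> np.ndarray:
        """True for real particles not on the first/last ring (which lack
        a full neighbour shell and are expected losses in lattice cleaning)."""
        kmax = self.ring_index[self.is_real].max(initial=0)
        return self.is_real & (self.ring_index > 0) & (self.ring_index < kmax)


def make_tube_lattice(
    radius: float = 20.0,
    length: float = 120.0,
    rise: float = 6.0,
    twist_deg: float = 30.0,
    jitter_sigma: float = 0.0,
    fake_fraction: float = 0.0,
    seed: int = 0,
    tomo_id: int = 1,
    object_id: int = 1,
    origin=(0.0, 0.0, 0.0),
    voxel_size: float = 1.0,
) -> SyntheticTruth:
    """Plant a pseudo-helical lattice on a straight cylinder along +X.

    Rings sit every ``rise`` voxels along the axis; within a ring particles
    are spaced ``twist_deg`` apart in azimuth, and each ring is rotated by
    ``twist_deg`` relative to the previous one, giving every particle
    neighbours at fixed relative positions: the in-ring neighbour at chord
    2*r*sin(twist/2), and the next-ring neighbour at
    sqrt(rise^2 + (2*r*sin(twist/2))^2).  Positions are jittered by an
    isotropic Gaussian; orientations are the ideal outward normal with the
    in-plane axis along the tube tangent.  ``fake_fraction`` plants
    round(f * n_real) contaminants uniformly on the cylinder surface with
    uniformly random orientations.
    """
    if rise <= 0:
        raise ValueError("rise must be positive")
    if not (0.0 <= fake_fraction < 1.0):
        raise ValueError("fake_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    origin = np.asarray(origin, dtype=float)
    n_rings = int(np.floor(length / rise + 1e-9)) + 1
    m = max(1, int(round(360.0 / twist_deg)))
    x_hat = np.array([1.0, 0.0, 0.0])

    positions, matrices, rings, azims = [], [], [], []
    for k in range(n_rings):
        for j in range(m):
            phi = np.deg2rad((j + k) * twist_deg)
            normal = np.array([0.0, np.cos(phi), np.sin(phi)])
            positions.append(origin + np.array([k * rise, 0, 0]) + radius * normal)
            matrices.append(normal_to_orientation(normal, x_hat).matrix)
            rings.append(k)
            azims.append(j)
    n_real = len(positions)
    positions = np.array(positions)
    if jitter_sigma > 0:
        positions = positions + rng.normal(0.0, jitter_sigma, size=positions.shape)

    n_fake = int(round(fake_fraction * n_real))
    for _ in range(n_fake):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x = rng.uniform(0.0, length)
        pos = origin + np.array([x, radius * np.cos(phi), radius * np.sin(phi)])
        positions = np.vstack([positions, pos])
        matrices.append(random_rotation_matrix(rng))
        rings.append(-1)
        azims.append(-1)

    n = n_real + n_fake
    pset = ParticleSet(
        tags=np.arange(1, n + 1),
        tomo_id=np.full(n, tomo_id),
        object_id=np.full(n, object_id),
        positions=positions,
        shifts=np.zeros((n, 3)),
        matrices=np.array(matrices),
        cc=np.zeros(n),
        class_label=np.concatenate([np.ones(n_real, int), np.zeros(n_fake, int)]),
        voxel_size=voxel_size,
    )
    pset.log(
        f"make_tube_lattice: {n_real} real + {n_fake} fake "
        f"(r={radius}, rise={rise}, twist={twist_deg}, seed={seed})"
    )

    # ideal neighbour offsets in the frame of the (k=0, j=0) particle
    r0 = normal_to_orientation(np.array([0.0, 1.0, 0.0]), x_hat).matrix
    p0 = np.array([0.0, radius, 0.0])
    s = np.deg2rad(twist_deg)
    p_ring = np.array([0.0, radius * np.cos(s), radius * np.sin(s)])  # in-ring neighbour
    p_next = np.array([rise, radius * np.cos(s), radius * np.sin(s)])  # next-ring neighbour
    lattice_vectors = np.stack([r0.T @ (p_ring - p0), r0.T @ (p_next - p0)])
    neighbour_sites = [
        np.array([0.0, radius * np.cos(s), radius * np.sin(s)]),  # +a: j+1
        np.array([0.0, radius * np.cos(-s), radius * np.sin(-s)]),  # -a: j-1
        np.array([rise, radius * np.cos(s), radius * np.sin(s)]),  # +b: ring k+1
        np.array([-rise, radius * np.cos(-s), radius * np.sin(-s)]),  # -b: ring k-1
    ]
    expected_offsets = np.stack([r0.T @ (p - p0) for p in neighbour_sites])

    ideal = np.array(
        [
            origin
            + np.array(
                [
                    k * rise,
                    radius * np.cos(np.deg2rad((j + k) * twist_deg)),
                    radius * np.sin(np.deg2rad((j + k) * twist_deg)),
                ]
            )
            for k in range(n_rings)
            for j in range(m)
        ]
    )
    nn_spacing = float(cKDTree(ideal).query(ideal, k=2)[0][:, 1].min())

    axis = np.array([origin, origin + np.array([length, 0.0, 0.0])])
    return SyntheticTruth(
        particles=pset,
        is_real=np.array(rings) >= 0,
        ring_index=np.array(rings),
        azimuth_index=np.array(azims),
        lattice_vectors=lattice_vectors,
        model=TubeModel(axis_points=axis, radius=radius),
        nn_spacing=nn_spacing,
        expected_offsets=expected_offsets,
    )


@dataclass
class BlobTruth:
    """A voxelized star-convex membrane plus its analytic surface."""

    volume: VolumeGrid
    radius_fn: Callable  # r(theta, phi): polar angle from +z, azimuth
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    base_radius: float = 0.0


def make_blob_volume(
    base_radius: float = 15.0,
    harmonic_amplitudes: dict | None = None,
    grid_size: int = 64,
    seed: int = 0,
    voxel_size: float = 1.0,
) -> BlobTruth:
    """Voxelize an irregular, star-convex membrane body.

    The surface is r(theta, phi) = base_radius * (1 + sum_l a_l * f_l),
    where f_l is a random (seeded) real combination of degree-l spherical
    harmonics scaled to peak amplitude 1, so each degree perturbs the
    radius by at most a_l * base_radius.  ``harmonic_amplitudes`` maps
    degree -> amplitude, e.g. {2: 0.15, 3: 0.1}; an empty/None mapping
    gives an exact ball.  The analytic r(theta, phi) is returned for
    oracle checks of meshing and mesh picking.
    """
    if harmonic_amplitudes is None:
        harmonic_amplitudes = {}
    rng = np.random.default_rng(seed)

    terms = []
    for degree, amp in sorted(harmonic_amplitudes.items()):
        weights = rng.standard_normal(2 * degree + 1)
        # scale this degree's random harmonic to peak amplitude 1
        th = np.linspace(0.0, np.pi, 91)
        ph = np.linspace(0.0, 2.0 * np.pi, 181, endpoint=False)
        tt, pp = np.meshgrid(th, ph, indexing="ij")

        def f_l(theta, phi, degree=degree, weights=weights):
            out = np.zeros_like(np.asarray(theta, dtype=float))
            for mi, w in zip(range(-degree, degree + 1), weights):
                out = out + w * np.real(sph_harm_y(degree, mi, theta, phi))
            return out

        peak = np.abs(f_l(tt, pp)).max()
        terms.append((amp, f_l, peak))

    def radius_fn(theta, phi):
        r = np.ones_like(np.asarray(theta, dtype=float))
        for amp, f_l, peak in terms:
            r = r + amp * f_l(theta, phi) / peak
        return base_radius * r

    # positivity check on a dense angular sample
    th = np.linspace(0.0, np.pi, 91)
    ph = np.linspace(0.0, 2.0 * np.pi, 181, endpoint=False)
    tt, pp = np.meshgrid(th, ph, indexing="ij")
    rr = radius_fn(tt, pp)
    if np.any(rr <= 0):
        raise ValueError("harmonic perturbation drives the surface radius non-positive")

    center = np.full(3, (grid_size - 1) / 2.0)
    ax = np.arange(grid_size)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    dx, dy, dz = gx - center[0], gy - center[1], gz - center[2]
    rho = np.sqrt(dx * dx + dy * dy + dz * dz)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, dz / np.maximum(rho, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(dy, dx) % (2.0 * np.pi)
    inside = rho <= radius_fn(theta, phi)
    volume = VolumeGrid(inside.astype(np.float32), voxel_size=voxel_size)
    return BlobTruth(volume=volume, radius_fn=radius_fn, center=center, base_radius=base_radius)


def simulate_cc(
    truth: SyntheticTruth,
    curve_coeffs=(0.55, 0.15 / 90.0),
    noise_sigma: float = 0.02,
    fake_delta: float = 0.10,
    seed: int = 0,
) -> ParticleSet:
    """Fill in cross-correlation scores with a latitude-dependent mean.

    Real particles score poly(theta) + N(0, noise_sigma); fakes the same
    minus ``fake_delta``.  The default curve rises by 0.15 from theta = 0
    (top views, weak membrane signal) to 90 (side views), reproducing the
    missing-wedge bias that defeats a single raw-CC threshold.
    ``curve_coeffs`` are increasing-power polynomial coefficients in theta
    (degrees).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    pset = truth.particles.copy()
    from .geometry import theta_of_matrices

    theta = theta_of_matrices(pset.matrices)
    cc = np.polynomial.polynomial.polyval(theta, np.asarray(curve_coeffs, dtype=float))
    cc = cc + rng.normal(0.0, noise_sigma, size=len(pset)) if noise_sigma > 0 else cc
    cc = np.where(truth.is_real, cc, cc - fake_delta)
    pset.cc = cc
    pset.log(
        f"simulate_cc: curve={list(curve_coeffs)}, sigma={noise_sigma}, "
        f"fake_delta={fake_delta}, seed={seed}"
    )
    return pset


def simulate_alignment_convergence(
    picks: ParticleSet,
    truth: SyntheticTruth,
    snap_sigma: float = 0.5,
    seed: int = 0,
    max_spin_deg: float = 5.0,
) -> ParticleSet:
    """Emulate the coarse-alignment output on oversampled picks.

    Each pick receives a shift that moves it onto its nearest true lattice
    particle (plus Gaussian convergence noise of width ``snap_sigma``), and
    that particle's orientation perturbed by a small random in-plane spin.
    Feeding the result to apply_shifts + remove_duplicates reproduces the
    duplicate-rejection scenario of real workflows.
    """
    if not np.any(truth.is_real):
        raise ValueError("truth lattice is empty")
    rng = np.random.default_rng(seed)
    real_pos = truth.particles.positions[truth.is_real]
    real_mat = truth.particles.matrices[truth.is_real]
    tree = cKDTree(real_pos)
    _, nearest = tree.query(picks.positions)

    out = picks.copy()
    targets = real_pos[nearest]
    if snap_sigma > 0:
        targets = targets + rng.normal(0.0, snap_sigma, size=targets.shape)
    out.shifts = targets - out.positions
    spins = np.deg2rad(rng.uniform(-max_spin_deg, max_spin_deg, size=len(out)))
    mats = np.empty_like(out.matrices)
    for i, (ni, a) in enumerate(zip(nearest, spins)):
        c, s = np.cos(a), np.sin(a)
        rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        mats[i] = real_mat[ni] @ rz
    out.matrices = mats
    out.log(f"simulate_alignment_convergence: snap_sigma={snap_sigma}, seed={seed}")
    return out
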