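# Methods

This note records the models, conventions, numerical choices and known
limitations behind `memsta`. It documents what the code computes; every
empirical statement here is reproduced by the test suite or by
`scripts/acceptance.py`.

## Orientations and Euler conventions

Orientations are stored as 3×3 rotation matrices mapping particle-frame
vectors into tomogram-frame vectors (column-vector action); Euler triplets
exist only at I/O boundaries. Two conventions are interpreted:

- `dynamo_zxz`: triplet (tdrot, tilt, narot), R = Rz(narot)·Rx(tilt)·Rz(tdrot)
- `relion_zyz`: triplet (rot, tilt, psi), R = Rz(rot)·Ry(tilt)·Rz(psi)

with Rz(a) rotating +x toward +y. Keeping the matrix as the internal store
makes every algorithm immune to convention drift: conversion between table
dialects always composes to a matrix and decomposes on output, never does
angle arithmetic.

Decomposition extracts tilt as `atan2(hypot(R₃₁, R₃₂), R₃₃)`, which stays
accurate near tilt = 0/180° where `arccos(R₃₃)` loses half the significand.
At gimbal lock (|sin tilt| < 1e-12) the third triplet element is set to 0 and
the whole in-plane spin is folded into the first, giving a deterministic
decomposition; the lock threshold is deliberately tiny because the atan2
extraction remains accurate arbitrarily close to lock, so a loose threshold
would only inject snap error. Round-trip error is < 1e-13 (Frobenius) on
1000 random rotations per convention, including near-lock matrices.

The latitude angle is θ = arccos |R₃₃| ∈ [0°, 90°]: the missing wedge
penalises membrane views symmetrically above and below the equator, so
normals at θ and 180°−θ are treated alike (top and bottom views score the
same). θ is always recomputed from the orientation matrix, never read from
a table column.

`normal_to_orientation` builds a frame by Gram–Schmidt: z = normal, x = the
in-plane reference projected and renormalised, y = z × x. When the reference
is absent or nearly parallel to the normal the fallback order is global +Z
then +X — deterministic, seed-free.

## File formats

All readers/writers are implemented in-package against the published
layouts: Dynamo tables (whitespace ASCII, ≥26 columns; tag in column 1,
shifts 4–6, ZXZ Euler triplet 7–9, CC 10, tomogram/object 20–21,
coordinates 24–26), AV3 motive lists (EM container: 512-byte header with
data-type code 5 = float32 and three int32 dims; 20×N payload, one
particle's 20 values contiguous), RELION particle STAR files (one pinned
dialect: `data_optics` with `rlnImagePixelSize`, `data_particles` with
0-based voxel coordinates, ZYZ angles in degrees, origins in Å), Chimera
`.cmm` marker sets (XML; markers ordered by `id`; physical Å divided by the
tomogram voxel size on request) and MRC2014 mode-2 volumes (data exposed as
`data[x, y, z]`, x fastest on disk).

Convention boundaries handled at I/O only: Dynamo tables and motive lists
are 1-based (internal coordinates are 0-based voxel indices); RELION origins
are *subtracted* from coordinates whereas the internal shift is *added*, so
the sign flips at the STAR boundary. Positions (columns 24–26) and shifts
(4–6) are kept separate; `apply_shifts` is the only operation that sums
them. Unmapped columns of a table read from disk are preserved verbatim when
the same set is rewritten.

## Surface picking

Oversampling is the central strategy: candidates are placed denser than the
expected particle spacing so each true particle falls inside at least one
box (verified as a property test on the synthetic lattice: picking at half
the lattice spacing leaves no true particle farther than half a spacing from
a pick). In-plane orientation is aligned with the surface tangent where one
exists; downstream alignment refines it.

- **Tubes.** The traced axis polyline is resampled at constant arc length
  equal to the sampling (points at arc-length multiples of the step;
  tangents are central differences). Each axis sample carries a ring of
  k = max(3, round(2πr/sampling)) points at the tube radius in the plane
  perpendicular to the tangent. Ring reference directions are
  parallel-transported along the axis (project the previous reference out of
  the new tangent) to avoid twist artifacts on curved axes.
- **Spheres.** A Fibonacci lattice of n = max(4, round(4πr²/sampling²))
  points: deterministic and near-uniform (nearest-neighbour spacing within
  [0.7, 1.4]× the sampling).
- **Segmented membranes.** The segmentation volume is Gaussian-smoothed,
  26-connected components above a threshold become membrane objects (default
  minimum size 500 voxels at ~10 Å/voxel — smaller fragments are
  segmentation noise), and each object is meshed by marching cubes. Vertex
  normals are derivative-of-Gaussian gradients of the volume (sigma floor
  1.5 voxels), negated so they point out of the dense interior; on a
  voxelized r = 15 ball they stay within ~3.4° of radial, whereas finite
  differences of the smoothed volume leave ~10° of voxelization noise.
  Picking draws 10·area/sampling² candidates by area-weighted face sampling
  (seeded RNG) and greedily thins them to a minimum spacing of sampling/2 —
  near-blue-noise and intentionally denser than the nominal sampling, which
  is harmless because oversampling is the point. Normals are interpolated
  barycentrically and flipped to match the requested directionality relative
  to the object's centre of mass (default outward: the motivating coat sits
  on the convex face).

## Duplicate removal

Greedy by descending CC (ties broken by lower tag for reproducibility)
within each (tomogram, object) group, accepting a particle iff it lies at
least the minimum separation from every accepted one — the same semantics as
Dynamo's "separation in tomogram", applied post hoc to a converged table.
Grouping per object is the default because particles on different membranes
may legitimately sit close in tomogram space. The implementation (KD-tree
accelerated) is property-tested against a brute-force O(n²) oracle, and on
simulated convergence of 4×-oversampled picks it recovers the planted count
within 2% (separation = 0.6× the lattice nearest-neighbour spacing,
following the rule that the separation must be below the expected
inter-particle distance).

## Missing-wedge CC normalisation

Per (tomogram, object) group with at least `min_per_object` particles
(default 50), a least-squares polynomial of degree 3 (default; the empirical
CC–θ trend is smooth and low-order) is fitted to CC against θ; smaller
groups fall back to the pooled global fit and are flagged. Scores are
adjusted additively, `cc_adj = cc − p(θ) + mean(cc)`: the additive residual
is robust where the fitted curve approaches zero and preserves within-θ
spreads and rank order (a multiplicative variant is available). Because OLS
residuals are orthogonal to the regressors, `cc_adj` is decorrelated from θ
by construction. An optional trimmed refit (drop residuals beyond 3 scaled
MADs, refit once) guards the fit against the very outliers it is meant to
expose; it is off by default and used when contamination is expected.

The benchmark scenario — scores rising by 0.15 from θ = 0 to 90°, Gaussian
noise σ = 0.02, 10% contaminants 0.10 below the curve — is the regime where
a raw threshold fails: the best single raw-CC threshold cannot exceed ~0.5
on min(precision, recall) for outlier removal, while a single threshold on
adjusted scores exceeds 0.95 on both.

## Lattice neighbour cleaning

For every ordered pair (i, j) in the same group within `max_dist`, the
offset Rᵢᵀ(xⱼ − xᵢ) is accumulated at its nearest voxel (integral counts,
unambiguous mask tests; 1-voxel binning) in a cubic map with odd edge length
(default 33, centre voxel = zero offset). The map is Gaussian-filtered
(σ = 0.5) and thresholded at 0.2× its smoothed maximum; voxels within 2
voxels of the centre are forced off so a particle can never support itself.
Filtering is single-pass against the pre-filter set — a cascade would erode
lattice edges unboundedly — and idempotent for a fixed mask.

The retention rule requires 2 neighbours at expected positions (pipeline
default). This was calibrated on the synthetic planted-fake benchmark: with
a single required neighbour, a fake embedded in a dense lattice has ~8–15
neighbours within range and one accidental mask hit is common, capping fake
removal near 90%; requiring two drives it to ~99% while interior retention
stays ≥99.5% (each interior particle has six expected neighbours). The
single-neighbour rule ("at least one neighbour in an expected position")
remains available (`min_neighbours 1`) and is the natural choice for sparse,
lone-particle contamination rather than planted in-lattice fakes. The mask
is pooled over all objects by default since lattices of the same coat share
geometry.

## Synthetic data

The generators emulate exactly the statistical structure the cleaning stages
assume, and nothing else:

- **Tube lattice** (`make_tube_lattice`): rings every `rise` (default 6
  voxels ≈ 60 Å at 10 Å/voxel) along a straight cylinder of radius 20
  voxels, particles every `twist` = 30° in azimuth, consecutive rings
  rotated by the same twist — each particle has in-ring neighbours at chord
  2r·sin(twist/2) and next-ring neighbours at √(rise² + chord²). Because a
  twist that divides 360° aligns rings into axial columns, the lattice
  nearest-neighbour spacing is the rise; the generator records it
  (`nn_spacing`) and the four ideal in-frame neighbour offsets
  (`expected_offsets`; curvature makes reverse offsets differ from
  negations). Positional jitter is isotropic Gaussian (σ = 0.5 voxels in
  benchmarks); contaminants are planted uniformly on the cylinder with Haar-
  random orientations at 10% of the real count.
- **Blob volumes** (`make_blob_volume`): star-convex bodies
  r(θ,φ) = r₀·(1 + Σₗ aₗ·fₗ(θ,φ)) with fₗ a seeded random real combination
  of degree-l spherical harmonics scaled to unit peak, voxelized on a cubic
  grid; the analytic radius function is returned so meshing and picking can
  be checked against ground truth.
- **CC scores** (`simulate_cc`): real particles score p(θ) + N(0, σ), fakes
  the same minus a fixed deficit (defaults: linear rise of 0.15 across
  latitude, σ = 0.02, deficit 0.10 — a 5σ separation *after* normalisation,
  none before).
- **Alignment convergence** (`simulate_alignment_convergence`): each pick
  receives a shift onto its nearest true particle plus Gaussian convergence
  noise, and that particle's orientation up to a small random in-plane spin.

All generators are pure functions of parameters + seed. What they do *not*
model: tomographic image formation (projection, CTF, noise volumes,
missing-wedge reconstruction), membrane deformation, or correlated
alignment failures. Passing tests therefore demonstrate the correctness of
the geometry and score logic under the stated statistical assumptions, not
picking performance on real tomograms — on real data the CC–θ trend, the
contamination geometry and the lattice disorder are all messier, which is
why every threshold is exposed as a parameter.

## Pipeline and problem sizes

`run_pipeline` executes apply-shifts → duplicate removal → CC fit/adjust/
threshold → neighbour map/mask/filter, logging in/out counts per stage into
a deterministic JSON report (counts are non-increasing by construction; the
coarse alignment itself is an explicit external hand-off). Benchmarks and
the acceptance script use tubes of 120–360 voxels length (≈250–800
particles, 20 seeds where a rate is measured, ~3400 oversampled picks for
the pipeline run) — large enough that the measured rates have a few-per-mil
resolution while the whole acceptance run stays around half a minute.

## Known limitations

- Only the two named Euler conventions; no quaternion API.
- The STAR dialect is pinned and minimal; exotic optics tables are ignored
  on read.
- `resample_axis` never emits the axis endpoint unless it falls on a step
  multiple; for picking this is immaterial under oversampling.
- Neighbour maps use 1-voxel binning; sub-voxel lattice vectors are
  resolvable only via the mask centroids, not the raw counts.
- Lattice cleaning assumes one lattice geometry per dataset when pooling the
  mask across objects; mixed coats need per-object masks.
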