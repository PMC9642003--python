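# memsta

Surface-based particle picking and dataset cleaning for membrane-associated
subtomogram averaging (STA).

Tightly packed membrane coats — the COPII inner coat is the motivating case —
decorate tubes, vesicles and irregularly shaped membranes with particles whose
exact positions are unknown but whose *surface* is easy to trace or segment.
`memsta` implements the surface-picking and cleaning stages of such a
workflow:

1. **Oversampled surface picking.** Candidate subtomogram coordinates are laid
   out on the membrane surface at a sampling finer than the expected
   inter-particle distance, so every real particle is contained in at least
   one subtomogram. Each candidate's orientation is initialised with its
   z-axis along the local membrane normal, fixing two of the three Euler
   angles before alignment. Supported surfaces: tubes (traced axis `.cmm` +
   radius), spheres, and segmentation volumes (smoothed, labelled into
   objects, meshed by marching cubes).
2. **Duplicate removal.** After an external coarse alignment (Dynamo/RELION),
   picks containing the same particle converge to the same coordinates;
   a greedy filter keeps the best-scoring pick of each cluster subject to a
   minimum separation *d*: sort by cross-correlation (CC) descending and
   accept a particle iff it is ≥ *d* from every accepted one.
3. **Missing-wedge CC normalisation.** The ±60° tilt range leaves a missing
   wedge in Fourier space, so the membrane's contribution to CC depends on the
   latitude angle θ = arccos |ẑ<sub>p</sub> · ẑ| between the particle normal
   and the beam axis: side views (θ≈90°) out-score top views (θ≈0°), and no
   single raw-CC threshold works. Per membrane object, a polynomial *p*(θ) is
   fitted to CC-vs-θ and scores are adjusted as
   `cc_adj = cc − p(θ) + mean(cc)`, after which one threshold separates real
   particles from junk at every latitude.
4. **Lattice neighbour cleaning.** Coat subunits form a pseudo-helical
   lattice, so each real particle has neighbours at set relative positions.
   Accumulating neighbour offsets `Rᵢᵀ(xⱼ − xᵢ)` in each particle's own
   reference frame gives a 3D density with peaks at the lattice vectors;
   thresholding it yields a mask of expected neighbour positions, and
   particles without enough neighbours inside the mask are dropped.

A synthetic-data module generates ground-truth lattices, irregular
("blob") segmentation volumes, latitude-dependent CC scores with planted
outliers, and simulated alignment convergence, so the full pipeline is
testable without any external data.

## Worked example

```sh
# plant a pseudo-helical lattice (radius 20 vx, rise 6 vx, twist 30°,
# 10% fake contaminants) and give it missing-wedge-biased CC scores
memsta simulate tube-lattice --length 240 --jitter 0.5 --fake-fraction 0.1 \
    --seed 1 --out lattice.tbl --labels labels.tsv
memsta simulate cc --in lattice.tbl --labels labels.tsv --seed 2 --out scored.tbl

# fit the CC-vs-theta polynomial, adjust, threshold
memsta cc-fit --in scored.tbl --degree 3 --out fits.json
memsta cc-adjust --in scored.tbl --fits fits.json --out adjusted.tbl
memsta cc-threshold --in adjusted.tbl --low 0.58 --out kept.tbl

# neighbour analysis
memsta neighbour-map --in kept.tbl --box 33 --max-dist 15 --out nmap.mrc
memsta neighbour-mask --in nmap.mrc --sigma 0.5 --level 0.2 --out nmask.mrc
memsta neighbour-filter --in kept.tbl --mask nmask.mrc --min-neighbours 2 --out clean.tbl
```

which prints, stage by stage:

```
wrote 541 particles to lattice.tbl
wrote 541 particles to scored.tbl
wrote 2 fits to fits.json
wrote 541 particles to adjusted.tbl
wrote 487 particles to kept.tbl
487 particles contributed; wrote nmap.mrc
mask has 161 true voxels; wrote nmask.mrc
wrote 486 particles to clean.tbl
```

The planted truth here is 492 lattice particles plus 49 fakes. On the
adjusted scores the two populations separate cleanly (real ≈ 0.63 ± 0.02,
fakes ≈ 0.53 ± 0.02), so the 0.58 threshold removes all 49 fakes at the cost
of 5 real particles (541→487); on the *raw* scores the same populations
overlap because high-latitude fakes out-score low-latitude real particles.
The neighbour filter then drops one end-of-tube particle that lacks enough
lattice neighbours (487→486); with contamination already gone it has nothing
else to do, while on an unthresholded table it removes the fakes directly. The same steps run in Python via
`memsta.ccnorm`, `memsta.lattice`, etc., and
`memsta run --config pipeline.yaml` executes the whole cascade with a JSON
report of per-stage counts.

Picking works the same way from the shell (`memsta pick-tube --cmm axis.cmm
--radius 20 --sampling 8 --voxel-size 10`, `memsta pick-sphere`,
`memsta pick-surface --seg seg.mrc`), writing Dynamo `.tbl`, AV3 motive-list
`.em` or RELION `.star` tables.

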