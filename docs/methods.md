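# Methods

This note records the models, conventions and design choices behind
`trxscore`, in the order the pipeline uses them.

## Two-state model preparation

A candidate conformer is merged into the reference structure at
whole-residue granularity: for every residue in the triggered selection the
reference atoms become conformer A and the candidate atoms conformer B.
Bookkeeping follows the standard low-occupancy-intermediate convention:

* **Occupancy.** Conformer B starts at `q_init` (default 0.25, the
  customary initialization for a weakly populated intermediate) and A is
  maintained as the exact complement `1 − q_init`; the complement invariant
  `occ(A) + occ(B) = 1` is validated to 1e-6 on every model.
* **B-factors.** Each B atom copies the B-factor of the same-named A atom
  exactly (equivalent atomic displacements in both states are assumed; the
  occupancy–B-factor trade-off is otherwise unidentifiable at this data
  quality). A candidate atom with no same-named reference atom is an error
  listing the offending atoms — silently dropping it would leave the
  B-factor source undefined.
* **Hydrogens** in the candidate fragment are dropped by default (hydrogen
  placement is an external step); `keep_hydrogens=True` retains them.
* **Residue matching** is by (chain, number, insertion code); a different
  residue name at the same position is an error, since conformers must be
  the same chemical residue. No sequence alignment is attempted.

Superposition onto the reference uses the matched Cα atoms (all residues by
default) and the least-squares rigid (Kabsch) solution via
`scipy.spatial.transform.Rotation.align_vectors`; pairs with a missing Cα
are skipped with a warning, fewer than three matched pairs or a collinear
configuration is an error. Because the moving residues participate in the
alignment, a frame whose selected residues are genuinely displaced is pulled
very slightly toward the reference; downstream this biases the refined
occupancy of near-truth frames a few points above the simulated truth
(≈ 0.29 vs 0.25 under the default conditions). This mirrors the standard
align-on-all-Cα practice and is left as is.

## Model density

Model density uses one isotropic Gaussian per atom: amplitude = occupancy ×
electron count Z, variance σ² = B/(8π²) + 0.9 Å². The fixed 0.9 Å² core
variance stands in for the intrinsic atomic width so that a B = 0 atom still
has finite extent; the single-Gaussian form targets metric correctness
(normalization: the numeric integral of one atom's density is occ·Z within
1%), not scattering accuracy — no multi-Gaussian form factors, bulk solvent
or symmetry. Grids are orthorhombic (90°) only; Gaussians are stamped to a
4.5σ cutoff (> 99.9% of the mass). Internal array order is `[ix, iy, iz]`
with nodes at `origin + index·spacing`; CCP4/MRC files (mode 2, float32) are
read and written through gemmi with the origin in the MRC-2014 ORIGIN header
words, falling back to N*START on read.

## Real-space metrics

A residue mask is the set of voxel nodes within `radius` (default 2.0 Å, the
conventional display clipping radius) of any selected atom; for two-state
residues the mask follows the B conformer by default (configurable), since B
is the conformer under scrutiny. Over mask voxels:

* **RSCC** — Pearson correlation of observed vs model density; zero variance
  in either grid makes it a missing value rather than a number.
* **RSZO** — mean observed density / map noise σ.
* **RSZD±** — peak-Z simplification: the strongest positive and strongest
  negative difference-map Z inside the mask, both reported as non-negative
  magnitudes. The canonical EDSTATS statistic is more elaborate; this form
  has the same range and the same "below 3 is good" reading, is exactly
  reproducible against a brute-force scan, and externally computed EDSTATS
  tables can be ingested in its place.

Map noise σ defaults to the RMS about the mean over all voxels; a
1.4826×MAD estimator is available for heavy-tailed maps. The pipeline
evaluates RSZD on each model's own residual map (observed − calculated),
normalized by that map's σ.

**Difference-density weights.** Voxels of the isomorphous difference map
with |Z| ≥ 3 (the conventional contouring threshold) are assigned to the
residue of their nearest atom among the selected residues, provided that
atom is within a 3.5 Å capture radius; more distant strong voxels are
discarded rather than reassigned. ρ_pos,j / ρ_neg,j are the sums of assigned
positive / |negative| densities. All selected residues stay in the weight
set — zero-weight ones included — so the 1/m prefactor of the weighted RSZD
runs over the full selection. The nearest-atom rule is a deliberate,
documented stand-in for blob-clustering approaches.

## Geometry validation

Native geometry uses a packaged minimal ideal-value table (Engh–Huber-style
backbone + Cβ bonds and angles, vdW radii per element):

* **Clashscore** — clashes per 1000 atoms, heavy atoms by default (hydrogen
  placement is external; an `include_hydrogens` flag exists). A clash is a
  pair more than three bonds apart on the covalent graph (distance-inferred
  intra-residue bonds plus peptide C–N links) with vdW overlap ≥ 0.4 Å.
  Atoms in different non-blank conformers never clash and never bond —
  alternative conformations are mutually exclusive.
* **Bond/angle RMS** — RMS of (observed − ideal) over all table-matched
  bonds and angles, evaluated per conformer; unknown residues and atoms
  without a template entry are skipped, never guessed. Side chains beyond
  Cβ are not restrained by the shipped table.
* **Conformer RMSD** — RMSD of B vs A over same-named atom pairs, no
  re-superposition (the displacement itself is the signal).

MolProbity score, Ramachandran, rotamer and Cβ outliers require curated
torsion libraries and are *not* computed natively; they enter the composite
score through ingested tables and contribute zero (with a logged warning)
when absent for the whole batch.

## Composite scoring

Min–max normalization is over exactly the batch being ranked; an external
comparison model joins the pool only if explicitly added as a frame. Policy
decisions where the scheme is underdetermined:

* a constant column normalizes to all zeros (it cannot discriminate);
* a column missing for every model is dropped from the sum with a warning
  (shrinking the geometry term's nominal 0–8 range);
* a column missing for only some models pins those models at the worst
  normalized value 1.0 and flags them — incomplete validation is never
  rewarded;
* ties on the composite break by lower R-free, then model id;
* scores are written to 6 decimals, comparisons use exact floats.

The composite is the plain sum of the three terms, bounded by [0, 13] when
all columns are present.

## Ensemble analysis

Atomic RMSF is `sqrt(mean_n |r_i,n − r̄_i|²)` over pre-aligned frames — no
internal re-superposition, so an un-removed rigid motion inflates it by
design (the pipeline aligns first). The per-residue profile aggregates
atomic values as an RMS, `sqrt((1/M) Σ ρ_i²)`; a plain-mean reading of
"average per residue" is exposed as `agg="mean"` but the RMS form is the
default. Residues with RMSF below 1.0 Å are flagged stable, the conventional
bound for a well-refined pool. Frames with missing atoms are an error with
the offending atoms listed, not imputed.

## Synthetic data generator

The simulator emulates the data regime the workflow is built for — a
low-occupancy two-state mixture:

* **Reference structure**: ideal-geometry poly-alanine (N, CA, C, O, CB)
  built by internal-coordinate (NeRF) construction in a helix (φ = −57°,
  ψ = −47°) or strand (φ = −139°, ψ = 135°) motif, trans peptides,
  L-chirality at Cα; by construction it scores exactly zero bond/angle RMS
  and zero clashes. B-factors default to 20 Å².
* **Truth conformer**: the selected residues (default: the three central
  ones) rigidly displaced by 1.2 Å in a seed-derived direction — a coherent,
  internally ideal motion, large enough to separate the two states' density
  at 0.8 Å grid spacing.
* **Maps**: map_ref = ρ_A + ε, map_trig = (1−q)ρ_A + qρ_B + ε′ with q = 0.25
  and i.i.d. Gaussian voxel noise at 5% of the reference map RMS by default.
  Independent draws for the two maps; with zero noise the mixture identity
  diff = q(ρ_B − ρ_A) holds to 1e-10.
* **Decoys**: 200 frames, 10 of them "near" (truth + 0.05 Å per-atom
  jitter), the rest "far" (reference + 0.8 Å per-atom perturbation — bad
  geometry *and* bad density, as uninformed candidates would be). The
  manifest records every frame's class and RMSD to the planted truth.
* **Mock refiner**: group occupancy only, solved in closed form
  (least squares in q, clamped to [0, 1]). Coordinate refinement is exactly
  the externalized step; an arbitrary external command can be plugged in via
  a `{model}`/`{out}` template.

What the generator does **not** emulate: spatially correlated map noise,
realistic scattering (form factors, solvent, crystal packing), reciprocal
space and R-factors from actual reflections, side chains beyond Cβ, and
coordinate relaxation during refinement. Passing tests therefore demonstrate
the correctness and discriminating power of the bookkeeping, metrics and
scoring machinery under controlled conditions — not end-to-end accuracy on
experimental data, where refinement behavior and map quality dominate.

In the pipeline's mock branch, R-work/R-free are a real-space residual
analog (Σ|obs − calc| / Σ|obs|, with R-free on a seeded 5% held-out voxel
subset, the same subset for every model of a batch); refinement logs with
true reciprocal-space R-factors can be ingested instead.

## Problem sizes and determinism

Default study conditions: 20 residues, q = 0.25, 200 decoys (10 near-truth),
5% map noise, 0.8 Å grid spacing — a scale at which the full pipeline runs
in a few seconds per replicate and the planted-truth tests use 20 seeded
replicates. Larger pools (the thousands-of-frames regime) are a
configuration change (`n_decoys`, `skip_frames` for discarding
equilibration-biased leading frames), not a code change. Every random choice
flows from a recorded integer seed; identical spec + seed reproduces
manifests, maps and scores bit-for-bit, and the final ranking is independent
of the worker count because results are assembled keyed by frame id.

## Known limitations

* PDB is the only structure dialect (no mmCIF); orthorhombic 90° grids only.
* The peak-Z RSZD and the nearest-atom weight assignment are documented
  simplifications of EDSTATS / blob-clustering practice.
* Native geometry covers backbone + Cβ; full MolProbity-class validation is
  ingestion-only.
* The mock refiner never moves coordinates, so it cannot model the
  coordinate relaxation a real reciprocal-space refiner performs.
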