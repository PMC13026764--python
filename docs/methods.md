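# Methods

This note records the models, conventions and numerical choices behind
`enscompare`, and what the synthetic-data generators do and do not
emulate.

## Ensembles, alignment and selections

An ensemble is a fixed topology plus `(n_frames, n_atoms, 3)` Cartesian
coordinates in ångström. Multi-model PDB is the native exchange format;
XTC/DCD trajectories are read through MDAnalysis with its nm→Å
conversion. PDB parsing keeps the highest-occupancy alternate location
per atom and skips insertion-coded residues with a warning, so parsing
is deterministic. Residue positions in all matrix outputs are 0-based
positions in the topology; original PDB residue numbers survive as
labels only. Repeat trajectories of one system are concatenated in
input order into a single ensemble before analysis.

Superposition is the closed-form SVD (Kabsch) solution with the
reflection branch excluded, so the rotation is always proper. Point
sets with fewer than 3 points, or rank < 2 after centering (collinear
configurations, which leave a free spin about the axis), are rejected.
Frames are aligned each with its own transform, computed on a fit
selection (Cα by default, since every downstream metric is Cα-based)
and applied to all atoms. Alignment is idempotent to < 1e-9 Å.

Named selections: `calpha` (exactly one CA per residue, an error
otherwise), `backbone_cb` (N, CA, C, O, CB where present; glycine
contributes four atoms), `heavy` (every non-hydrogen atom). The
backbone + Cβ set matches the output of coarse-grained generative
models, which is why the contact map uses it.

## Flexibility, correlations, contacts

RMSF, DCCM and the distance-based contact map are defined in the README.
Numerical conventions that matter:

- DCCM diagonals are set to exactly 1 and values clipped to [−1, 1] to
  absorb rounding at the Cauchy–Schwarz boundary. A residue with zero
  total displacement makes the correlation undefined and is reported by
  name.
- Whole-matrix MAE averages over all n² elements (the plain mean of the
  element-wise absolute difference); the JSON reports also carry the
  diagonal-free variant, with field names making the convention
  explicit. Stratified MAE averages over unique unordered pairs
  (i < j), so pair-count-weighted per-stratum MAEs recombine exactly to
  the overall off-diagonal MAE.
- Sequence-separation strata: a pair (i, j) is *close* if
  |i−j|/n_res < 0.2, *far* if > 0.8, otherwise *middle*; boundary
  values fall to middle.
- Terminal stratification defaults to max(5, 10 % of the chain) per
  terminus.
- Interaction classes on close contacts (reference mean-min distance
  < 5 Å by default, a typical contact criterion at backbone/Cβ
  resolution): *polar_polar* = one acidic {ASP, GLU} + one basic
  {LYS, ARG}; *pi_pi* = both aromatic {PHE, TYR, TRP, HIS}; *non_polar*
  = both in {ALA, VAL, LEU, ILE, MET, PRO, GLY}; anything else,
  including unknown residue names, is *other*. HIS is counted aromatic
  and excluded from the basic set to avoid double counting. All sets
  are arguments.
- Secondary-structure strata are consumed from an external per-residue
  annotation (H/E/C); the package assigns none itself.

## Distribution shifts between variants

PCA is fitted once per protein on the pooled, commonly-aligned Cα
coordinates of the wild type and all mutants, so every variant is
projected onto the same axes. The implementation is scikit-learn PCA
(full SVD) with the component sign fixed so the largest-magnitude entry
is positive, making projections reproducible. 2D histograms share bin
edges spanning the pooled range (default 50 × 50 bins; KL depends on
the binning, so the bin count is echoed in the report). KL divergence
uses the natural logarithm (nats) with WT as the reference
distribution. Because the divergence is undefined when a mutant bin is
empty where the wild type has mass, both tables receive an additive
pseudocount (default 1e-6 per bin) and are renormalized; this keeps KL
finite and is negligible for well-populated bins. Identical histograms
give exactly 0.

## Two-state bias

Each frame is superposed independently onto the apo and the holo Cα
reference and its RMSD to each recorded. Residue matching between the
two references (trimming to the equivalent segment) is the caller's
responsibility. State membership at the cutoff (default 3 Å) uses
strict inequality: a frame at exactly the cutoff belongs to neither
state. Rather than a quadrant label, the summary reports the
holo-bias fraction — the fraction of frames with RMSD_holo < RMSD_apo —
which restates "biased toward holo" independently of axis order.

## Pocket-based structure selection

Pocket detections are consumed as PDB-format point clouds, one file per
frame: grid points of one pocket share a residue number, and the pocket
energy (more negative = more favourable) sits in the B-factor column,
matching the shape of grid-based pocket-detection output. The exposure
score of a frame is the best, over pockets, fraction of reference-ligand
atoms within 1 Å (configurable) of any grid point. The adaptive filter
retains frames with score ≥ cutoff, starting at 0.5 and stepping down
by 0.1 while the retained count stays ≤ the minimum (default 100);
the cutoff floors at 0.0, where every frame is retained, so the
procedure terminates even for hopeless series. Retained frames'
pocket-atom coordinates (protein heavy atoms within the radius of the
ligand; the 1 Å default is deliberately tight and exposed as a flag)
are reduced to 2 principal components — fitted on retained frames only —
and clustered with seeded k-means (k = 5, 10 restarts, best inertia).
Each cluster's representative is its minimum-energy frame; energy ties
break to the lowest frame index. Identical coordinates across frames
make k clusters meaningless and are rejected.

## Screening metrics

Docking scores are lower-is-better internally (a flag negates
higher-is-better inputs at ingestion). Per-ligand aggregation across
receptor structures defaults to the best (minimum) finite score — the
standard ensemble-docking convention; mean and median are available.
The ROC sweeps thresholds over unique scores with ties grouped
(scikit-learn's sweep, no vertex dropping); AUC is the trapezoidal
area, which equals the midrank Mann–Whitney estimator. ER at a
false-positive level interpolates TPR linearly between ROC vertices
(the discrete curve rarely touches FPR = 0.01 exactly), taking the
upper TPR at vertical segments. Top-N counts actives among the N best
ligands with ties at the boundary broken by ligand id.

## Synthetic generators

The generators emulate the *statistical* structure the metrics measure,
not protein physics: no force field, no side-chain packing, no
solvent. Passing tests therefore demonstrate that the estimators
recover designed fluctuation scales, correlations, state weights,
exposures and separabilities at the stated sample sizes — not that any
particular generative model reproduces MD.

- **Backbone**: an ideal-helix Cα trace (1.5 Å rise, 100° turn, 2.3 Å
  radius — arbitrary fixed constants producing a protein-like ~3.8 Å
  Cα spacing) with N, C, O, Cβ at fixed offsets; glycine omits Cβ.
- **Harmonic ensembles**: per-residue Gaussian displacements (scale σ_i
  per coordinate, so E[RMSF_i] → σ_i√3) applied rigidly to all atoms of
  a residue. Correlated blocks share a latent standard-normal factor:
  Δ = σ(√(1−|ρ|)·ε_i + √|ρ|·ε_shared), giving exact pairwise
  correlation ρ within the block and positive-definiteness by
  construction; negative ρ flips the shared loading's sign for the
  second range. Overlapping blocks are rejected.
- **Shifted ("mutant") ensembles**: the reference is displaced along a
  seeded random unit mode with total displacement norm
  magnitude·mean(σ). The harmonic noise projected onto any unit mode
  has standard deviation σ, so magnitude is the shift in units of the
  ensemble's own spread along the mode — magnitudes 0.5/1/2 produce
  overlapping-to-separated distributions rather than saturated,
  disjoint ones.
- **Two-state mixtures**: Bernoulli choice of apo or holo coordinates
  plus isotropic jitter; true labels are returned for occupancy
  checks.
- **Pocket scenes**: a line ligand (3 Å spacing); the primary pocket's
  grid points coincide with exactly k ligand atoms so measured
  exposure equals k/n exactly; decoy pockets are placed far away.
  Exposures not representable as k/n are rejected.
- **Screening tables**: active scores ~ N(−δ, 1), decoys ~ N(0, 1),
  so the expected AUC is Φ(δ/√2).

All generators are bit-reproducible under a fixed seed.

## Problem sizes and tolerances in the test suite

Statistical recovery tests use sizes where the estimator's sampling
error is comfortably below the asserted tolerance: 5000 frames for
RMSF (±3 % of σ√3) and DCCM (±0.05), 2000 frames for occupancy (±3 %)
and KL monotonicity, 20 000 ligands for the binormal AUC (±0.01), 200
permutations for the null AUC (±0.02). Exact identities (MAE algebra,
adaptive-filter traces, designed exposures, brute-force matrix oracles
on ≤ 5-residue toys) are asserted at 1e-12 or exactly. Recovery
statistics are computed directly on generated ensembles, which are
already expressed in the common reference frame; per-frame re-fitting
of pure-noise frames would absorb ~6/(3n) of the displacement variance
into the rigid fit and bias RMSF low, so superposition is exercised
separately on inputs with genuine rigid motions.

## Known limitations

- PDB output is fixed-format with 0-based atom serials per model; no
  mmCIF, no hydrogens, no periodic-boundary handling (inputs are
  assumed whole).
- The harmonic generator's rigid per-residue displacement preserves
  intra-residue geometry but not bonded geometry between neighbouring
  residues at large σ.
- KL on sparse histograms (frames ≪ occupied bins) carries an upward
  finite-sample bias common to both sides of a comparison; comparisons
  at equal sample sizes remain ordered, but absolute values should not
  be read as population divergences.
- Whether a study subsamples frames before comparison is up to the
  caller; all frames provided are used.
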