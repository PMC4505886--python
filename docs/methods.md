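# Methods

This note records the model behind `vdomgeom`, the choices made where the
design was genuinely open, and what the synthetic validation does and does
not demonstrate.

## Rigid-frame model of Vα/Vβ association

The package treats each TCR variable domain as a rigid body represented by
its conserved framework: the β-sheet core of the immunoglobulin fold,
stripped of CDR loops and turns. The working assumptions are

* the framework core is structurally conserved across TCRs, so matched
  framework Cα positions superpose to well under 1 Å;
* interdomain *rotation* carries the biological signal, while translations
  of the β domain are small in comparison;
* each biological unit (BU) of a crystal is an independent observation of
  the interdomain geometry.

Residue correspondence is positional: anchors are identified by author
residue numbers shared between template and target. For real data this
presumes IMGT-equivalenced numbering in the manifest; the synthetic
generator numbers all domains identically. No structure-based alignment
(distance-matrix or sequence alignment) is performed — the conserved
framework is the premise, not a result.

### Loop/turn removal

A Cα-only geometric detector: residue *i* is "extended" when
|Cα(i−1) − Cα(i+1)| > 6.0 Å (ideal strand ≈ 6.4–6.8 Å, helix ≈ 5.4 Å, turns
lower). Runs shorter than 3 are discarded. This is deliberately coarse — the
subsequent iterative pruning removes residual non-rigid positions, so the
detector only needs to seed the iteration with mostly-strand positions.

### Iterative anchor derivation

Starting from the loop-stripped reference positions resolved in every
domain, each iteration (i) Kabsch-superposes all domains onto the reference
on the current anchors, (ii) drops in one batch every anchor whose
ensemble-mean deviation exceeds `deviation_cutoff` (default 1.0 Å).
Convergence = no anchor dropped. Defaults: `max_iter` 20; the variance of
per-domain RMSDs at convergence is reported and should fall below
`rmsd_var_tol` (0.05 Å²). These thresholds are conventions for "converged
subset, low RMSD variance"; the procedure is idempotent on its own output
(tested). Fewer than three surviving anchors, collinear anchors, or hitting
the iteration cap raise a diagnostic-carrying error.

## Euler angles and the EAD

The β pose of an aligned complex is the rigid transform mapping the
reference β anchors onto the structure's β anchors. Its rotation is reported
as an xyz-order Euler triple: **R = R_z(Θ)·R_y(Ψ)·R_x(Φ)** (intrinsic
x→y→z; verified against an independent rotation library in the tests,
because "xyz order" alone is ambiguous). At gimbal lock (|Ψ| = 90°, where
only Φ±Θ is determined) the convention Φ := 0 applies; recomposition still
reproduces the input matrix exactly. Angles are degrees externally, radians
internally.

The Euler-angle distance is the Euclidean norm of the componentwise
differences wrapped to (−180°, 180°]. Wrapping makes each component the
geodesic circle distance, so the EAD satisfies the metric axioms on the
whole torus (property-tested); for the small angles observed in practice it
coincides with the plain Euclidean distance. The EAD operates on degrees —
results are conventionally reported in degrees, and any uniform unit change
only rescales the metric.

BU averaging is the componentwise arithmetic mean taken on angles unwrapped
relative to the first BU, so sets straddling the ±180° seam average
correctly.

## Ward clustering and multiscale bootstrap

Ward's minimum-variance linkage runs on the condensed EAD matrix via the
standard Lance–Williams recursion (scipy's nearest-neighbor-chain
implementation; deterministic for identical input — we did not re-implement
the tie-break order, determinism being the property that matters).
BU-averaged records are the default clustering unit.

Node support follows the multiscale-bootstrap recipe: bootstrap
probabilities bp_r are counted at ten relative resample sizes r ∈ [0.5, 1.4]
(the replicate budget `n_replicas`, default 10 000, split evenly; the
study-scale budget of 10⁶ is a flag away), then
Φ⁻¹(1 − bp) is fit against v·σ + c/σ with σ² = 1/r, giving
au = 1 − Φ(v − c). Saturated curves (all bp = 1 or 0) short-circuit to
au = 1/0.

**What is resampled** is an interpretation point: with only three angle
components, feature resampling (the convention of the cited clustering-
significance tools) is statistically thin. The default therefore resamples
*observations* (structures); a node counts as supported in a replicate when
its member set, restricted to the labels present, recurs as a clade
(restrictions smaller than 2 or equal to the whole replicate are excluded
from the denominator). `resample="components"` provides the
feature-resampling variant. Neither mode is asserted as the original
procedure.

**Cluster extraction:** maximal non-root nodes with au ≥ threshold (default
0.95) become clusters; uncovered leaves become singletons. The root is
excluded because the full leaf set trivially recurs in every replicate.
A consequence worth knowing: genuinely nested structure (two clusters much
closer to each other than to a third) is reported at the coarsest supported
level.

## Center of rotation

A cubic grid (extent 32 Å, spacing 0.1 Å → 321³ = 33,076,161 points, indexed
identically for every structure) is centered on the reference β cuboid; each
structure's β pose transports the grid. Per index the n² ordered pairwise
distances between point images are reduced to their variance with 1/(n²−1)
normalization. As printed, the defining double sum lacks a square on the
deviation term and would vanish identically; it is implemented as a proper
variance (squared deviations), self-pairs (k = l, distance 0) included
exactly as the sums are written, with a flag to exclude them. The argmin
(ties to the lowest index) is the CoR; an all-zero field (no rotational
diversity) is a degenerate-input error rather than a silent index 0.

Exhaustive evaluation of 321³ points against all structure pairs is
cluster-scale work, so the default is coarse-to-fine: a 1.0 Å pass over the
full cube, then a 0.1 Å pass in a 3 Å box around the coarse minimum. Because
1.0 and 3.0 are multiples of 0.1 and boxes are centered on lattice points,
the refined lattice is a sub-lattice of the exhaustive one; both strategies
return the same argmin on every instance small enough to enumerate (tested).

A geometric caveat the test suite encodes: the zero-variance locus of a
*single* relative rotation is its whole axis, so an ensemble with effectively
one relative rotation (e.g. two tight clusters) localizes the pivot only up
to a line. Three or more distinct rotation axes through the pivot make the
minimum a point.

Hydrogen-bond detection at the CoR uses heavy-atom donor–acceptor distances
(default cutoff 3.5 Å, no angle term — deposited structures carry no
hydrogens); residues missing expected side-chain atoms are flagged, not
silently skipped. Conservation at the adjacent position (IMGT 44) is
tabulated from a user-supplied aligned FASTA plus a column↔IMGT map;
fractions are relative to the total sequence count and gapped rows are
reported as incomplete rather than dropped, since the exclusion criterion
for incomplete germline sequences is not standardized.

## Synthetic generator

`synthetic_fixtures` builds Cα-level pseudo-Ig domains (seven ideal extended
strands on two sheets, compact connecting loops, 0.15 Å jitter), pairs them
at a 22 Å offset, and places the β domain by a known rotation about a known
pivot (11 Å, the interface midpoint). Planted ensembles draw each
structure's triple as cluster center + independent per-component Gaussian
jitter — matching the EAD's componentwise form so expected distances are
analytic — plus optional isotropic coordinate noise. Defaults mirror the
statistical shape of the curated structure set: 60 structures, six clusters
spread over ~30° of angle space, 1° intra-cluster spread, 0.1 Å coordinate
noise.

What this validates: the geometry chain (superposition → pose → Euler →
EAD → clustering → CoR) is exact on rigid inputs (planted angles recovered
to <10⁻⁶ °, pivot to within one grid spacing) and degrades gracefully under
coordinate noise. What it does not validate: real TCRs are not rigid — loop
remodeling, framework mutations, unresolved residues and genuine numbering
inhomogeneity are absent from the fixtures, so agreement there bounds
algorithmic error only, not the structural-biology error of applying a
rigid-framework model to flexible proteins.

## Problem sizes and budgets

The default test suite and the acceptance script run entirely on synthetic
inputs: ensembles of 10–60 structures, bootstrap budgets of 300–10 000
replicates, and coarse-to-fine CoR searches (a full-ensemble exhaustive pass
at 0.1 Å is intentionally out of default scope). These sizes were chosen as
desk-scale defaults that exercise every code path; all scale knobs
(`n_replicas`, grid `spacing`/`extent`, `strategy="exhaustive"`) accept
study-scale values.

## Known limitations

* Manifest-driven chain/domain identification only; no automatic α/β
  detection. The shipped 85-entry manifest lists identity, species, bound
  state and TCR type, but per-BU chain pairs and V-domain ranges must be
  completed per deposition before real-data runs.
* The converged anchor subset depends on the ensemble fed to the builder;
  subsets derived from different ensembles are consistent in behavior
  (convergence, low RMSD variance) but not guaranteed identical.
* Translation components of the β pose are computed but not analyzed.
* The bootstrap's resampling unit is an interpretation (see above); au
  values from the two modes should not be compared across modes.
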