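# vdomgeom

Quantitative analysis of the association geometry between the variable
domains (Vα/Vβ) of αβ T-cell receptors.

## The problem

A TCR binds its peptide–MHC ligand through the paired variable domains of
its α and β chains. The two immunoglobulin folds do not associate at a fixed
angle: across crystal structures the Vβ domain is rotated relative to Vα by
up to ~30°, and this interdomain geometry matters for epitope recognition,
signaling models, and TCR structure prediction. Comparing the geometry across
structures is awkward because TCRs differ in loop structure and chain length,
so `vdomgeom` reduces every variable domain to a unified rigid frame:

1. **Framework anchors.** Loops and turns are stripped; a conserved subset of
   β-strand framework positions is derived iteratively over the ensemble
   (anchors whose post-superposition deviation exceeds a cutoff are dropped
   until the subset converges).
2. **Superposition.** Every complex is superposed on its Vα anchors onto a
   single high-resolution reference structure by least-squares (Kabsch)
   fitting of matched Cα atoms. Principal-axis cuboids attached to the
   framework give each domain the same local frame.
3. **Euler-angle geometry.** The pose of each Vβ domain relative to the
   reference Vβ is a rigid transform; its rotation is expressed as an
   xyz-order Euler triple (Φ, Ψ, Θ), with R = R_z(Θ)·R_y(Ψ)·R_x(Φ). The
   similarity of two geometries *i*, *j* is the Euler-angle distance

   d_E(i, j) = √((Φ_i−Φ_j)² + (Ψ_i−Ψ_j)² + (Θ_i−Θ_j)²)   [degrees]

   with componentwise differences wrapped to (−180°, 180°].
4. **Clustering with significance.** Structures with several biological
   units are merged by componentwise angle averaging; the pairwise d_E matrix
   is clustered with Ward's minimum-variance method, and per-node support is
   estimated by multiscale bootstrap (bp at several resample sizes, combined
   into an approximately-unbiased *au* p-value). Maximal nodes with
   au ≥ 95 % are the significant geometry clusters.
5. **Center of rotation (CoR).** A cubic grid (extent 32 Å, spacing 0.1 Å,
   321³ = 33,076,161 points) fixed to the reference β cuboid is carried along
   by every structure's β pose. For each grid index *i* the variance of the
   n² ordered pairwise distances δ(g_{i,k}, g_{i,l}) across structures is
   computed; the argmin is the common pivot about which all observed Vβ
   orientations can be generated. The CoR sits next to the conserved
   interchain glutamine pair (IMGT position 44), whose hydrogen bonds the
   package detects and whose sequence conservation it tabulates from a
   V-segment multiple sequence alignment.

The package is aimed at structural immunologists and TCR-modelling groups:
it ships a manifest of the 85-entry curated TCR structure set, a synthetic
generator with exact ground truth (planted angles, pivot, cluster labels)
for validation, library APIs in scikit-learn estimator style
(`FrameworkTemplateBuilder`, `BootstrapWardClusterer`,
`RotationCenterFinder`), and a `vdomgeom` command line
(`simulate / align / cluster / cor / conserve`).

## Worked example

Three planted angular clusters (centers 30° apart, 0.5° spread, common pivot
at x = 11 Å) run through the full pipeline:

```python
import numpy as np
from vdomgeom import BootstrapWardClusterer, RotationCenterFinder
from vdomgeom.pipeline import build_templates, extract_geometries
from vdomgeom.synthetic_fixtures import SyntheticSpec, planted_ensemble

spec = SyntheticSpec(n_structures=18, n_clusters=3,
                     cluster_center_angles=((0, 0, 0), (30, 0, 0), (0, 30, 0)),
                     intra_cluster_spread=0.5, coordinate_noise=0.0, seed=7)
complexes, truth = planted_ensemble(spec)
templates = build_templates(complexes)
records, poses = extract_geometries(complexes, templates)
for r in records[:3]:
    print(f"  {r.pdb_id}: phi={r.euler.phi:7.3f}  psi={r.euler.psi:7.3f}  theta={r.euler.theta:7.3f}")
clusterer = BootstrapWardClusterer(n_replicas=2000, random_state=1).fit(
    np.array([r.euler.as_array() for r in records]))
print("significant clusters:", clusterer.n_clusters_)
finder = RotationCenterFinder(grid_center=templates.beta_cuboid.center).fit(
    list(poses.values()))
print("CoR (x, y, z) [A]:", np.round(finder.center_, 3).tolist())
```

prints

```
  syn000: phi=  0.000  psi=  0.000  theta=  0.000
  syn001: phi= 29.554  psi= -0.425  theta= -0.450
  syn002: phi=  0.110  psi= 30.521  theta= -0.087
significant clusters: 3
CoR (x, y, z) [A]: [10.964, 0.022, -0.037]
```

The first structure is the reference, so its triple is zero; the others
recover their planted rotations (cluster centers ±jitter). Clustering finds
exactly the three planted groups at au ≥ 95 %, and the grid search localizes
the planted pivot to within one grid spacing (0.1 Å).

The same steps run from the shell:

```sh
vdomgeom simulate --spec spec.json --out fixtures/
vdomgeom align   --manifest manifest.tsv --structures fixtures/ --out aligned/
vdomgeom cluster --geometries aligned/geometry.csv --replicas 10000 --seed 42 --out clustered/
vdomgeom cor     --poses aligned/poses.json --center 22 0 0 --out cor/
```

For real structures, complete the shipped
`src/vdomgeom/data/table1_manifest.tsv` with per-BU chain pairs and V-domain
residue ranges, place the PDB/mmCIF files in a directory, and run the same
`align / cluster / cor` sequence with `--reference 2bnu`.

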