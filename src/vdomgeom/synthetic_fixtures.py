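"""Synthetic two-domain complexes with known ground truth.

Every pipeline stage is testable without downloading structures: the
generator builds Cα-level pseudo-immunoglobulin "domains" (two β-sheets of
extended strands joined by compact decoy loops), pairs them into α/β
complexes, and places the β domain by a *known* rotation about a *known*
pivot.  Planted ensembles add per-cluster angular offsets (independent
Gaussian jitter per Euler component, so expected EADs are analytically
computable) and optional isotropic coordinate noise.  All generators are pure
functions of their seed.

Default ensemble conditions mirror the statistical structure of the curated
TCR set: six angular clusters spread over ~30° of Euler-angle space,
~1° intra-cluster spread, and 0.1 Å coordinate noise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .cuboid_geometry import EulerTriple, rotation_from_euler
from .framework_template import RigidTransform
from .structure_io import Atom, Residue, TCRComplex, VariableDomain, write_domains_pdb

DEFAULT_CLUSTER_CENTERS = (
    (0.0, 0.0, 0.0),
    (12.0, 0.0, 0.0),
    (0.0, 12.0, 0.0),
    (0.0, 0.0, 12.0),
    (-10.0, 8.0, 0.0),
    (8.0, -10.0, 6.0),
)
BETA_OFFSET = np.array([22.0, 0.0, 0.0])  # β domain center relative to α
DEFAULT_PIVOT = np.array([11.0, 0.0, 0.0])  # interface point between the domains


@dataclasses.dataclass
class SyntheticSpec:
    """Conditions of a planted ensemble; fixed seed → byte-identical output."""

    n_structures: int = 60
    n_clusters: int = 6
    cluster_center_angles: tuple = DEFAULT_CLUSTER_CENTERS
    intra_cluster_spread: float = 1.0  # degrees, per Euler component
    pivot: tuple = tuple(DEFAULT_PIVOT)
    coordinate_noise: float = 0.1  # Å, isotropic per atom
    seed: int = 0

    def __post_init__(self):
        if self.intra_cluster_spread < 0 or self.coordinate_noise < 0:
            raise ValueError("spread and noise must be >= 0")
        if self.n_clusters > len(self.cluster_center_angles):
            raise ValueError("not enough cluster centers for n_clusters")


def toy_domain(seed: int, chain_type: str = "alpha", chain_id: str = "A") -> VariableDomain:
    """~100-residue Cα pseudo-Ig trace with framework strands and decoy loops.

    Seven extended strands (Cα rise 3.4 Å, so the i−1→i+1 distance of ~6.8 Å
    reads as strand to the geometric detector) on two sheets, joined by
    compact loop segments.  The strand positions form the designated
    framework subset, exposed as ``domain.framework_numbers``.
    """
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    framework: list[bool] = []
    strand_len, loop_len = 9, 5
    n_strands = 7
    for s in range(n_strands):
        sheet = 0 if s < 4 else 1
        y = (s if sheet == 0 else s - 4) * 4.8
        z = sheet * 10.0
        direction = 1 if s % 2 == 0 else -1
        x0 = 0.0 if direction == 1 else (strand_len - 1) * 3.4
        start = np.array([x0, y, z])
        for i in range(strand_len):
            coords.append(start + np.array([direction * 3.4 * i, 0.0, 0.0]))
            framework.append(True)
        if s < n_strands - 1:
            # compact connecting loop: short steps bulging off the sheet
            a = coords[-1]
            nxt_sheet = 0 if s + 1 < 4 else 1
            ny = ((s + 1) if nxt_sheet == 0 else (s + 1) - 4) * 4.8
            nz = nxt_sheet * 10.0
            ndir = 1 if (s + 1) % 2 == 0 else -1
            nx0 = 0.0 if ndir == 1 else (strand_len - 1) * 3.4
            b = np.array([nx0, ny, nz])
            for i in range(1, loop_len + 1):
                t = i / (loop_len + 1)
                bulge = np.array([0.0, 2.5 * np.sin(np.pi * t), 2.0 * np.sin(np.pi * t)])
                coords.append(a + t * (b - a) + bulge)
                framework.append(False)
    xyz = np.array(coords)
    xyz -= xyz.mean(axis=0)  # domain centered on its centroid
    xyz += rng.normal(0.0, 0.15, size=xyz.shape)
    residues = [
        Residue(name="ALA", number=i + 1, atoms=[Atom("CA", "C", xyz[i])])
        for i in range(len(xyz))
    ]
    domain = VariableDomain(chain_type, residues, chain_id)
    domain.framework_numbers = [
        i + 1 for i, is_fw in enumerate(framework) if is_fw
    ]
    return domain


def _shift_domain(domain: VariableDomain, offset: np.ndarray) -> VariableDomain:
    return domain.transformed(np.eye(3), offset)


def _add_gln_pair(alpha: VariableDomain, beta: VariableDomain,
                  midpoint: np.ndarray, d1: float = 3.06, d2: float = 3.14) -> None:
    """Append Q-like interface residues carrying NE2/OE1 donor–acceptor pairs.

    Two crossed contacts: α:NE2···β:OE1 at ``d1`` Å and β:NE2···α:OE1 at
    ``d2`` Å, emulating the conserved twofold interchain hydrogen bond.
    """
    up = np.array([0.0, 0.0, 1.0])
    a_ne2 = midpoint + np.array([-d1 / 2, 0.0, 0.0])
    b_oe1 = midpoint + np.array([+d1 / 2, 0.0, 0.0])
    b_ne2 = midpoint + 4.0 * up + np.array([+d2 / 2, 0.0, 0.0])
    a_oe1 = midpoint + 4.0 * up + np.array([-d2 / 2, 0.0, 0.0])
    n_a = alpha.residues[-1].number + 1
    n_b = beta.residues[-1].number + 1
    alpha.residues.append(Residue("GLN", n_a, atoms=[
        Atom("CA", "C", a_ne2 + np.array([-3.0, 0.0, 0.0])),
        Atom("NE2", "N", a_ne2), Atom("OE1", "O", a_oe1),
    ]))
    beta.residues.append(Residue("GLN", n_b, atoms=[
        Atom("CA", "C", b_oe1 + np.array([3.0, 0.0, 0.0])),
        Atom("OE1", "O", b_oe1), Atom("NE2", "N", b_ne2),
    ]))


def synth_complex(
    alpha: VariableDomain,
    beta: VariableDomain,
    euler: EulerTriple,
    pivot=DEFAULT_PIVOT,
    pdb_id: str = "syn0",
    bu_index: int = 1,
    bound_state: str = "mhc1",
    tcr_type: str = "",
    coordinate_noise: float = 0.0,
    rng: np.random.Generator | None = None,
    with_gln_pair: bool = False,
) -> TCRComplex:
    """Pair two toy domains, rotating β about ``pivot`` by the xyz triple.

    The applied transform ``x → R x + (p − R p)`` is stored as ground truth
    (``complex.ground_truth``) together with the planted Euler triple.
    """
    pivot = np.asarray(pivot, dtype=float)
    R = rotation_from_euler(euler)
    t = pivot - R @ pivot
    beta_placed = _shift_domain(beta, BETA_OFFSET).transformed(R, t)
    alpha_copy = alpha.transformed(np.eye(3), np.zeros(3))
    if with_gln_pair:
        _add_gln_pair(alpha_copy, beta_placed, midpoint=pivot.copy())
    if coordinate_noise > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        for dom in (alpha_copy, beta_placed):
            for res in dom.residues:
                for atom in res.atoms:
                    atom.position = atom.position + rng.normal(
                        0.0, coordinate_noise, size=3
                    )
    cx = TCRComplex(
        pdb_id=pdb_id,
        bu_index=bu_index,
        alpha=alpha_copy,
        beta=beta_placed,
        bound_state=bound_state,
        tcr_type=tcr_type,
    )
    cx.alpha.framework_numbers = list(getattr(alpha, "framework_numbers", []))
    cx.beta.framework_numbers = list(getattr(beta, "framework_numbers", []))
    cx.ground_truth = {
        "euler": [euler.phi, euler.psi, euler.theta],
        "pivot": pivot.tolist(),
        "pose": RigidTransform(R, t),
    }
    return cx


def planted_ensemble(spec: SyntheticSpec) -> tuple[list[TCRComplex], np.ndarray]:
    """Ensemble of complexes with planted cluster structure about one pivot.

    Structure *i* belongs to cluster ``i mod n_clusters``; its Euler triple is
    the cluster center plus independent Gaussian jitter per component.
    Returns the complexes and the true cluster labels.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = toy_domain(spec.seed, "alpha", "A")
    beta = toy_domain(spec.seed + 1, "beta", "B")
    complexes, labels = [], []
    centers = np.asarray(spec.cluster_center_angles, dtype=float)
    for i in range(spec.n_structures):
        c = i % spec.n_clusters
        angles = centers[c] + rng.normal(0.0, spec.intra_cluster_spread, size=3)
        cx = synth_complex(
            alpha,
            beta,
            EulerTriple(*angles),
            pivot=spec.pivot,
            pdb_id=f"syn{i:03d}",
            tcr_type=f"type{c}",
            coordinate_noise=spec.coordinate_noise,
            rng=rng,
        )
        cx.ground_truth["cluster"] = c
        complexes.append(cx)
        labels.append(c)
    return complexes, np.array(labels)


def write_fixture_set(spec: SyntheticSpec, out_dir: str | Path) -> list[Path]:
    """Write the ensemble as PDB files plus a truth JSON; re-ingestible."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    complexes, labels = planted_ensemble(spec)
    paths = []
    truth = {"seed": spec.seed, "pivot": list(spec.pivot), "structures": {}}
    for cx in complexes:
        p = out / f"{cx.pdb_id}.pdb"
        write_domains_pdb(p, cx.alpha, cx.beta, remark=f"synthetic fixture {cx.pdb_id}")
        paths.append(p)
        gt = cx.ground_truth
        truth["structures"][cx.pdb_id] = {
            "euler": gt["euler"],
            "cluster": int(gt["cluster"]),
            "alpha_chain": cx.alpha.source_chain_id,
            "beta_chain": cx.beta.source_chain_id,
        }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return paths
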