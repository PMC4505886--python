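"""Conserved-framework anchor derivation and rigid superposition.

The immunoglobulin fold of a TCR variable domain has a structurally conserved
β-sheet core (the framework) surrounding hypervariable loops.  Interdomain
geometry is only meaningful after all domains are put into one frame, so this
module (i) strips loops and turns, (ii) iteratively derives the subset of
framework positions on which an ensemble of domains superposes rigidly, and
(iii) performs least-squares (Kabsch) superposition of matched Cα atoms onto
the reference structure.

Residue correspondence is positional: anchors are identified by author residue
numbers shared between template and target (IMGT-equivalenced numbering for
real data, identical numbering for synthetic fixtures).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, DegenerateGeometryError, SuperpositionError
from .structure_io import TCRComplex, VariableDomain

REFERENCE_ID = "2bnu"


@dataclasses.dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6 or np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclasses.dataclass
class FrameworkTemplate:
    """Converged superposition anchors of one chain type, in the reference frame."""

    chain_type: str
    anchor_positions: list[int]
    anchor_coordinates: np.ndarray
    reference_id: str = REFERENCE_ID

    def __post_init__(self):
        self.anchor_coordinates = np.asarray(self.anchor_coordinates, dtype=float)
        if len(self.anchor_positions) != len(self.anchor_coordinates):
            raise ValueError("positions and coordinates disagree in length")
        if len(self.anchor_positions) < 3:
            raise DegenerateGeometryError("a template needs >= 3 anchors")
        _require_non_collinear(self.anchor_coordinates)

    def __len__(self) -> int:
        return len(self.anchor_positions)

    def to_file(self, path: str | Path) -> None:
        lines = [f"# framework template  chain_type={self.chain_type}  "
                 f"reference={self.reference_id}"]
        for p, (x, y, z) in zip(self.anchor_positions, self.anchor_coordinates):
            lines.append(f"{p}\t{x:.6f}\t{y:.6f}\t{z:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "FrameworkTemplate":
        chain_type, reference = "alpha", REFERENCE_ID
        positions, coords = [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                for tok in line.split():
                    if tok.startswith("chain_type="):
                        chain_type = tok.split("=", 1)[1]
                    elif tok.startswith("reference="):
                        reference = tok.split("=", 1)[1]
                continue
            p, x, y, z = line.split("\t")
            positions.append(int(p))
            coords.append([float(x), float(y), float(z)])
        return cls(chain_type, positions, np.array(coords), reference)


@dataclasses.dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    matched: list[tuple[int, int]]


def _require_non_collinear(coords: np.ndarray, tol: float = 1e-8) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(s) < 2 or s[1] <= tol:
        raise DegenerateGeometryError("anchor coordinates are collinear")


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping ``moving`` onto ``target``.

    Returns the transform and the residual RMSD over the point pairs.
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape or moving.shape[0] < 3:
        raise SuperpositionError("need >= 3 matched point pairs of equal shape")
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, moving - mc)
    R = rot.as_matrix()
    transform = RigidTransform(R, tc - R @ mc)
    rmsd = float(rssd) / np.sqrt(moving.shape[0])
    return transform, rmsd


# ---------------------------------------------------------------------------
# loop/turn removal


def remove_loops_and_turns(
    domain: VariableDomain, d13_cutoff: float = 6.0, min_run: int = 3
) -> np.ndarray:
    """Boolean mask keeping extended (β-strand) positions of a domain.

    A Cα-only geometric detector: residue *i* is extended when the
    Cα(i−1)–Cα(i+1) distance exceeds ``d13_cutoff`` (≈6.4 Å in ideal strands,
    ≈5.4 Å in helices, smaller in turns).  Runs shorter than ``min_run`` are
    discarded, which removes isolated extended residues inside loops.
    """
    if len(domain) < 20:
        raise DegenerateGeometryError("domain too short for strand detection (< 20)")
    ca = domain.ca_coords()
    n = len(ca)
    ext = np.zeros(n, dtype=bool)
    d13 = np.linalg.norm(ca[2:] - ca[:-2], axis=1)
    ext[1:-1] = d13 > d13_cutoff
    ext[0], ext[-1] = ext[1], ext[-2]
    # drop runs shorter than min_run
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if ext[i]:
            j = i
            while j < n and ext[j]:
                j += 1
            if j - i >= min_run:
                mask[i:j] = True
            i = j
        else:
            i += 1
    if not mask.any():
        raise DegenerateGeometryError("no secondary structure assignable (empty mask)")
    return mask


# ---------------------------------------------------------------------------
# iterative framework-subset derivation


def derive_framework_subset(
    domains: list[VariableDomain],
    chain_type: str,
    reference_index: int = 0,
    deviation_cutoff: float = 1.0,
    rmsd_var_tol: float = 0.05,
    max_iter: int = 20,
    initial_mask: np.ndarray | None = None,
) -> FrameworkTemplate:
    """Iteratively derive the converged framework anchor subset of an ensemble.

    Starting from the loop-stripped positions of the reference domain that are
    resolved in *every* domain, each iteration superposes all domains onto the
    reference on the current anchors and drops (in one batch, largest first)
    every anchor whose mean post-superposition deviation exceeds
    ``deviation_cutoff`` Å.  Convergence means the subset stopped changing;
    the variance of the per-domain RMSDs is reported on the returned template
    builder/estimator and should end up below ``rmsd_var_tol``.
    """
    if len(domains) < 2:
        raise SuperpositionError("need >= 2 domains to derive a framework subset")
    ref = domains[reference_index]
    if initial_mask is None:
        initial_mask = remove_loops_and_turns(ref)
    ref_numbers = ref.residue_numbers()
    candidates = [n for n, keep in zip(ref_numbers, initial_mask) if keep]
    # restrict to positions resolved (with Cα) in every domain
    common = set(candidates)
    for d in domains:
        common &= set(d.ca_by_number())
    anchors = [n for n in candidates if n in common]
    diagnostics = []
    ref_ca = ref.ca_by_number()
    for iteration in range(1, max_iter + 1):
        if len(anchors) < 3:
            raise ConvergenceError(
                "fewer than 3 anchors remain", last_subset=anchors, diagnostics=diagnostics
            )
        ref_xyz = np.array([ref_ca[n] for n in anchors])
        try:
            _require_non_collinear(ref_xyz)
        except DegenerateGeometryError as exc:
            raise ConvergenceError(str(exc), last_subset=anchors,
                                   diagnostics=diagnostics) from exc
        devs = np.zeros(len(anchors))
        rmsds = []
        for d in domains:
            dmap = d.ca_by_number()
            xyz = np.array([dmap[n] for n in anchors])
            tr, rmsd = kabsch(xyz, ref_xyz)
            devs += np.linalg.norm(tr.apply(xyz) - ref_xyz, axis=1)
            rmsds.append(rmsd)
        devs /= len(domains)
        rmsd_var = float(np.var(rmsds))
        diagnostics.append(
            {"iteration": iteration, "n_anchors": len(anchors),
             "max_deviation": float(devs.max()), "rmsd_variance": rmsd_var}
        )
        bad = devs > deviation_cutoff
        if not bad.any():
            template = FrameworkTemplate(
                chain_type, anchors, np.array([ref_ca[n] for n in anchors])
            )
            template.rmsd_variance = rmsd_var
            template.n_iterations = iteration
            template.diagnostics = diagnostics
            return template
        order = np.argsort(-devs)
        drop = {anchors[i] for i in order if bad[i]}
        anchors = [n for n in anchors if n not in drop]
    raise ConvergenceError(
        f"framework subset did not converge within {max_iter} iterations",
        last_subset=anchors,
        diagnostics=diagnostics,
    )


def superpose_on_template(
    domain: VariableDomain, template: FrameworkTemplate
) -> SuperpositionResult:
    """Kabsch superposition of a domain's anchor Cαs onto the template."""
    dmap = domain.ca_by_number()
    matched = [(n, n) for n in template.anchor_positions if n in dmap]
    if len(matched) < 3:
        raise SuperpositionError(
            f"only {len(matched)} anchors matched; >= 3 needed"
        )
    target = np.array(
        [template.anchor_coordinates[template.anchor_positions.index(n)]
         for n, _ in matched]
    )
    moving = np.array([dmap[n] for n, _ in matched])
    transform, rmsd = kabsch(moving, target)
    return SuperpositionResult(transform, rmsd, matched)


def align_complex_on_alpha(
    complex_: TCRComplex, alpha_template: FrameworkTemplate
) -> tuple[TCRComplex, SuperpositionResult]:
    """Superpose a complex on its Vα domain; the *same* transform moves all atoms.

    The aligned copy is a member of the superposed set (Sα): its α framework
    sits on the reference, while its β domain carries the structure's own
    interdomain geometry.
    """
    result = superpose_on_template(complex_.alpha, alpha_template)
    tr = result.transform
    return complex_.transformed(tr.rotation, tr.translation), result


class FrameworkTemplateBuilder(BaseEstimator):
    """Estimator wrapper around the iterative framework-subset derivation.

    Parameters
    ----------
    deviation_cutoff : float, Å
        Anchors whose ensemble-mean deviation from the reference exceeds this
        are dropped each iteration.
    rmsd_var_tol : float, Å²
        Target variance of per-domain RMSDs at convergence (diagnostic).
    max_iter : int
        Iteration cap; exceeding it raises :class:`ConvergenceError`.
    reference_index : int
        Which input domain anchors the reference frame.

    Attributes
    ----------
    template_ : FrameworkTemplate
    anchor_positions_ : list of int
    n_iter_ : int
    rmsd_variance_ : float
    """

    def __init__(self, deviation_cutoff=1.0, rmsd_var_tol=0.05, max_iter=20,
                 reference_index=0):
        self.deviation_cutoff = deviation_cutoff
        self.rmsd_var_tol = rmsd_var_tol
        self.max_iter = max_iter
        self.reference_index = reference_index

    def fit(self, X, y=None):
        """Derive the converged anchor subset from a list of VariableDomain."""
        domains = list(X)
        chain_type = domains[0].chain_type
        self.template_ = derive_framework_subset(
            domains,
            chain_type,
            reference_index=self.reference_index,
            deviation_cutoff=self.deviation_cutoff,
            rmsd_var_tol=self.rmsd_var_tol,
            max_iter=self.max_iter,
        )
        self.anchor_positions_ = list(self.template_.anchor_positions)
        self.n_iter_ = self.template_.n_iterations
        self.rmsd_variance_ = self.template_.rmsd_variance
        return self

    def transform(self, X):
        """Superpose each domain onto the fitted template; returns aligned copies."""
        out = []
        for d in X:
            res = superpose_on_template(d, self.template_)
            out.append(d.transformed(res.transform.rotation, res.transform.translation))
        return out
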