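"""Grid-based search for the common center of rotation (CoR).

A cubic grid is fixed to the reference β cuboid and carried along by every
structure's β pose, with identical point indexing everywhere.  For each grid
index the Euclidean distances between the point's images in every ordered
pair of structures are collected, and their variance is the field value; the
grid point of minimal variance is the CoR — the spot that moves most
coherently under all observed interdomain rotations, i.e. the common pivot.

The study-scale grid (32 Å extent, 0.1 Å spacing, 321³ = 33,076,161 points)
is prohibitive to evaluate exhaustively for large ensembles, so the default
strategy is coarse-to-fine: a 1.0 Å pass over the full cube, then a 0.1 Å
pass in a 3 Å box around the coarse minimum.  The coarse lattice is a
sub-lattice of the exhaustive one, so on every instance small enough to check
the two strategies return the same argmin (tested).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateGeometryError
from .framework_template import RigidTransform
from .structure_io import TCRComplex

_DEGENERATE_TOL = 1e-16


@dataclasses.dataclass
class Grid:
    """Cubic grid: corner ``origin``, ``spacing`` Å, ``points_per_axis`` per axis.

    Axes are the reference-frame axes.  Point index is row-major,
    ``i = (ix · m + iy) · m + iz`` with m = points_per_axis.
    """

    origin: np.ndarray
    spacing: float
    points_per_axis: int

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.points_per_axis < 2:
            raise ValueError("need >= 2 points per axis")

    @property
    def n_points(self) -> int:
        return self.points_per_axis ** 3

    def points(self) -> np.ndarray:
        m = self.points_per_axis
        ax = np.arange(m) * self.spacing
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        return pts + self.origin

    def point(self, index: int) -> np.ndarray:
        m = self.points_per_axis
        ix, rem = divmod(index, m * m)
        iy, iz = divmod(rem, m)
        return self.origin + self.spacing * np.array([ix, iy, iz], dtype=float)


@dataclasses.dataclass
class VarianceField:
    """Per-grid-index variance of the ordered pairwise point distances (Å²)."""

    values: np.ndarray
    n_structures: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-9):
            raise ValueError("variance must be non-negative")


@dataclasses.dataclass
class CoRResult:
    i_min: int
    coordinate: np.ndarray
    variance_at_min: float
    subset_used: str = "all"
    spacing: float = 0.1

    def to_dict(self) -> dict:
        return {
            "i_min": int(self.i_min),
            "coordinate": [float(x) for x in self.coordinate],
            "variance_at_min": float(self.variance_at_min),
            "subset_used": self.subset_used,
            "spacing": self.spacing,
        }


@dataclasses.dataclass
class HBondContact:
    donor_residue: str
    donor_atom: str
    acceptor_residue: str
    acceptor_atom: str
    distance: float
    donor_chain: str = "alpha"
    acceptor_chain: str = "beta"


# ---------------------------------------------------------------------------
# grid construction & transformation


def fit_grid(cuboid_or_center, spacing: float, extent: float) -> Grid:
    """Cubic grid of side ``extent`` centered on a cuboid (or point).

    ``spacing`` must divide ``extent``; the point count per axis is
    extent/spacing + 1 (so 32 Å at 0.1 Å gives 321³ points).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ratio = extent / spacing
    n_cells = int(round(ratio))
    if abs(ratio - n_cells) > 1e-9 or n_cells < 1:
        raise ValueError(f"spacing {spacing} does not divide extent {extent}")
    center = getattr(cuboid_or_center, "center", cuboid_or_center)
    center = np.asarray(center, dtype=float)
    return Grid(center - extent / 2.0, spacing, n_cells + 1)


def transform_grid_points(grid: Grid, pose: RigidTransform) -> np.ndarray:
    """Images g_{i,k} of every reference grid point under one structure's pose."""
    return pose.apply(grid.points())


# ---------------------------------------------------------------------------
# variance field (the printed double sums, with squared deviations)


def variance_field(
    positions: np.ndarray, include_self_pairs: bool = True
) -> VarianceField:
    """Variance of ordered pairwise distances per grid index.

    ``positions`` is (n, G, 3): per structure, the transformed grid points.
    For each index i the n² ordered pair distances δ(g_{i,k}, g_{i,l}) are
    reduced to their variance with 1/(count−1) normalization.  Self pairs
    (k = l, distance 0) are included by default, exactly as the double sums
    are written; a flag excludes them.
    """
    P = np.asarray(positions, dtype=float)
    if P.ndim != 3 or P.shape[2] != 3:
        raise ValueError("positions must be (n_structures, n_points, 3)")
    n = P.shape[0]
    if n < 2:
        raise ValueError("need >= 2 structures")
    G = P.shape[1]
    sum_d = np.zeros(G)
    sum_d2 = np.zeros(G)
    for k in range(n):
        d = np.linalg.norm(P[k][None, :, :] - P, axis=2)  # (n, G)
        sum_d += d.sum(axis=0)
        sum_d2 += (d * d).sum(axis=0)
    count = n * n if include_self_pairs else n * n - n
    mean = sum_d / count
    var = (sum_d2 - count * mean * mean) / (count - 1)
    return VarianceField(np.maximum(var, 0.0), n)


def locate_cor(
    field: VarianceField, grid: Grid, subset_used: str = "all"
) -> CoRResult:
    """Argmin of the variance field, mapped to reference-frame coordinates.

    Ties break to the lowest index.  An (effectively) all-zero field means the
    poses carry no rotational diversity and no CoR is defined.
    """
    if len(field.values) != grid.n_points:
        raise ValueError("field does not cover the grid")
    if float(field.values.max()) <= _DEGENERATE_TOL:
        raise DegenerateGeometryError(
            "variance field is identically zero: no rotational diversity"
        )
    i_min = int(np.argmin(field.values))
    return CoRResult(
        i_min=i_min,
        coordinate=grid.point(i_min),
        variance_at_min=float(field.values[i_min]),
        subset_used=subset_used,
        spacing=grid.spacing,
    )


def find_rotation_center(
    poses: list[RigidTransform],
    grid_center,
    spacing: float = 0.1,
    extent: float = 32.0,
    strategy: str = "coarse2fine",
    coarse_spacing: float = 1.0,
    refine_box: float = 3.0,
    include_self_pairs: bool = True,
    subset: str = "all",
) -> CoRResult:
    """End-to-end CoR search over an ensemble of β poses.

    ``strategy="exhaustive"`` evaluates the full grid at ``spacing``;
    ``"coarse2fine"`` (default) runs a ``coarse_spacing`` pass first and then
    refines at ``spacing`` inside a ``refine_box`` Å box around the coarse
    minimum (box points stay on the exhaustive lattice when refine_box and
    coarse_spacing are multiples of spacing).
    """
    if strategy not in ("coarse2fine", "exhaustive"):
        raise ValueError("strategy must be 'coarse2fine' or 'exhaustive'")
    if strategy == "exhaustive":
        grid = fit_grid(grid_center, spacing, extent)
        positions = np.stack([transform_grid_points(grid, p) for p in poses])
        return locate_cor(variance_field(positions, include_self_pairs), grid, subset)
    coarse = fit_grid(grid_center, coarse_spacing, extent)
    positions = np.stack([transform_grid_points(coarse, p) for p in poses])
    coarse_min = locate_cor(variance_field(positions, include_self_pairs), coarse, subset)
    fine = fit_grid(coarse_min.coordinate, spacing, refine_box)
    positions = np.stack([transform_grid_points(fine, p) for p in poses])
    result = locate_cor(variance_field(positions, include_self_pairs), fine, subset)
    result.spacing = spacing
    return result


# ---------------------------------------------------------------------------
# CoR residue environment & interchain hydrogen bonds

# side-chain donor / acceptor heavy atoms (structures carry no hydrogens)
_SC_DONORS = {
    "ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"],
    "TRP": ["NE1"], "ASN": ["ND2"], "GLN": ["NE2"], "SER": ["OG"],
    "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
}
_SC_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"], "MET": ["SD"],
}
_BACKBONE_DONOR = "N"
_BACKBONE_ACCEPTORS = ("O", "OXT")


def cor_environment(
    complex_: TCRComplex, cor: np.ndarray, radius: float
) -> pd.DataFrame:
    """Residues of an aligned complex with any atom within ``radius`` of the CoR.

    One row per residue (chain, residue name, author number, closest-atom
    distance), sorted by distance.  An empty frame is a valid result.
    """
    cor = np.asarray(cor, dtype=float)
    rows = []
    for chain_name, domain in (("alpha", complex_.alpha), ("beta", complex_.beta)):
        for res in domain.residues:
            if not res.atoms:
                continue
            d = min(
                float(np.linalg.norm(a.position - cor)) for a in res.atoms
            )
            if radius > 0 and d <= radius:
                rows.append(
                    {"chain": chain_name, "residue": res.name,
                     "number": res.number, "distance": d}
                )
    df = pd.DataFrame(rows, columns=["chain", "residue", "number", "distance"])
    return df.sort_values("distance", ignore_index=True) if len(df) else df


def flag_missing_sidechains(residues) -> list[str]:
    """Residue labels whose expected donor/acceptor side-chain atoms are absent."""
    flagged = []
    for res in residues:
        expected = set(_SC_DONORS.get(res.name, [])) | set(_SC_ACCEPTORS.get(res.name, []))
        have = {a.name for a in res.atoms}
        if expected - have:
            flagged.append(res.label)
    return flagged


def detect_interchain_hbonds(
    residues_alpha, residues_beta, cutoff: float = 3.5
) -> list[HBondContact]:
    """All α↔β donor–acceptor heavy-atom pairs with distance ≤ cutoff.

    A pure distance criterion on heavy atoms (no angle term: the deposited
    structures carry no hydrogens).  Both directions are scanned, so the
    conserved twofold Q–Q interaction yields two contacts.
    """
    def donors(res):
        out = [(a, _BACKBONE_DONOR) for a in res.atoms if a.name == _BACKBONE_DONOR]
        out += [(a, a.name) for a in res.atoms if a.name in _SC_DONORS.get(res.name, [])]
        return out

    def acceptors(res):
        out = [(a, a.name) for a in res.atoms if a.name in _BACKBONE_ACCEPTORS]
        out += [(a, a.name) for a in res.atoms
                if a.name in _SC_ACCEPTORS.get(res.name, [])]
        return out

    contacts = []
    for da_chain, (dres_list, ares_list) in (
        ("alpha", (residues_alpha, residues_beta)),
        ("beta", (residues_beta, residues_alpha)),
    ):
        other = "beta" if da_chain == "alpha" else "alpha"
        for dres in dres_list:
            for datom, dname in donors(dres):
                for ares in ares_list:
                    for aatom, aname in acceptors(ares):
                        dist = float(np.linalg.norm(datom.position - aatom.position))
                        if dist <= cutoff:
                            contacts.append(
                                HBondContact(
                                    donor_residue=f"{dres.name}{dres.label}",
                                    donor_atom=dname,
                                    acceptor_residue=f"{ares.name}{ares.label}",
                                    acceptor_atom=aname,
                                    distance=dist,
                                    donor_chain=da_chain,
                                    acceptor_chain=other,
                                )
                            )
    return sorted(contacts, key=lambda c: c.distance)


# ---------------------------------------------------------------------------
# exports


def write_variance_field_csv(path: str | Path, grid: Grid, field: VarianceField) -> None:
    pts = grid.points()
    pd.DataFrame(
        {"index": np.arange(grid.n_points), "x": pts[:, 0], "y": pts[:, 1],
         "z": pts[:, 2], "var": field.values}
    ).to_csv(path, index=False)


def write_cor_report(path: str | Path, result: CoRResult, **extra) -> None:
    payload = result.to_dict()
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_hbond_table(path: str | Path, contacts: list[HBondContact]) -> None:
    pd.DataFrame([dataclasses.asdict(c) for c in contacts]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# estimator


class RotationCenterFinder(BaseEstimator):
    """Estimator locating the common pivot of an ensemble of rigid β poses.

    ``fit`` takes a list of :class:`RigidTransform` poses (reference-frame →
    structure) and searches the grid anchored at ``grid_center`` for the point
    whose images across structures vary least.

    Attributes
    ----------
    center_ : (3,) CoR coordinate in the reference frame, Å
    i_min_ : int, grid index of the minimum
    variance_ : float, field value at the minimum, Å²
    result_ : CoRResult
    """

    def __init__(self, grid_center=(0.0, 0.0, 0.0), spacing=0.1, extent=32.0,
                 strategy="coarse2fine", coarse_spacing=1.0, refine_box=3.0,
                 include_self_pairs=True, subset="all"):
        self.grid_center = grid_center
        self.spacing = spacing
        self.extent = extent
        self.strategy = strategy
        self.coarse_spacing = coarse_spacing
        self.refine_box = refine_box
        self.include_self_pairs = include_self_pairs
        self.subset = subset

    def fit(self, X, y=None):
        poses = list(X)
        self.result_ = find_rotation_center(
            poses,
            grid_center=np.asarray(self.grid_center, dtype=float),
            spacing=self.spacing,
            extent=self.extent,
            strategy=self.strategy,
            coarse_spacing=self.coarse_spacing,
            refine_box=self.refine_box,
            include_self_pairs=self.include_self_pairs,
            subset=self.subset,
        )
        self.center_ = self.result_.coordinate
        self.i_min_ = self.result_.i_min
        self.variance_ = self.result_.variance_at_min
        return self
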