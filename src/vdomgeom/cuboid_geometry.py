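"""Cuboid frames, xyz Euler angles, and the Euler-angle distance (EAD).

After all complexes are superposed on their Vα frameworks, each Vβ domain sits
somewhere in the reference frame.  A unified cuboid — principal-axis box of
the reference framework anchors — gives every β domain the *same* local frame,
so its placement is a single rigid transform relative to the reference β
domain.  The rotation part is expressed as an xyz-order Euler triple
(Φ, Ψ, Θ), and the similarity of two geometries is the Euclidean norm of the
componentwise (wrapped) angle differences, in degrees.

Convention (documented because "xyz order" alone is ambiguous): the rotation
matrix factors as ``R = Rz(Θ) · Ry(Ψ) · Rx(Φ)`` — intrinsic rotations about
x, then y, then z; equivalently extrinsic z·y·x.  Test vectors live in the
test suite.  Gimbal lock (|Ψ| = 90°) uses the convention Φ := 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError
from .framework_template import (
    FrameworkTemplate,
    RigidTransform,
    SuperpositionResult,
    align_complex_on_alpha,
    superpose_on_template,
)
from .structure_io import TCRComplex, VariableDomain


def wrap_degrees(angle):
    """Wrap angles (degrees) into the interval (−180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


@dataclasses.dataclass
class EulerTriple:
    """(Φ, Ψ, Θ) in degrees, xyz rotation order; each wrapped to (−180, 180]."""

    phi: float
    psi: float
    theta: float

    def __post_init__(self):
        self.phi = float(wrap_degrees(self.phi))
        self.psi = float(wrap_degrees(self.psi))
        self.theta = float(wrap_degrees(self.theta))

    def as_array(self) -> np.ndarray:
        return np.array([self.phi, self.psi, self.theta])


@dataclasses.dataclass
class Cuboid:
    """A rigid box: center, half extents (Å) and orthonormal axes (rows)."""

    center: np.ndarray
    half_extents: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.half_extents = np.asarray(self.half_extents, float)
        self.axes = np.asarray(self.axes, float)
        if not np.all(self.half_extents > 0):
            raise ValueError("half_extents must be positive")
        err = np.abs(self.axes @ self.axes.T - np.eye(3)).max()
        if err > 1e-8 or np.linalg.det(self.axes) < 0:
            raise ValueError("axes must form a proper rotation")


@dataclasses.dataclass
class GeometryRecord:
    """β-domain pose of one biological unit (or a BU-averaged structure)."""

    pdb_id: str
    bu_index: int | str
    euler: EulerTriple
    bound_state: str = "unbound"
    tcr_type: str = ""

    @property
    def label(self) -> str:
        return f"{self.pdb_id}:{self.bu_index}"


# ---------------------------------------------------------------------------
# rotations <-> Euler triples


def rotation_from_euler(triple: EulerTriple) -> np.ndarray:
    """Compose ``Rz(Θ) · Ry(Ψ) · Rx(Φ)`` from a triple in degrees."""
    phi, psi, theta = np.deg2rad(triple.as_array())
    cx, sx = np.cos(phi), np.sin(phi)
    cy, sy = np.cos(psi), np.sin(psi)
    cz, sz = np.cos(theta), np.sin(theta)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def euler_xyz_from_rotation(rotation: np.ndarray) -> EulerTriple:
    """Extract the xyz-order Euler triple (degrees) of a proper rotation.

    Inverse of :func:`rotation_from_euler` away from gimbal lock; at
    |Ψ| = 90° the Φ := 0 convention applies.
    """
    R = np.asarray(rotation, float)
    if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-6 \
            or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper rotation matrix")
    sy = -R[2, 0]
    if abs(sy) >= 1.0 - 1e-12:
        # gimbal lock: only phi+theta (or phi-theta) is determined
        psi = np.copysign(np.pi / 2, sy)
        phi = 0.0
        theta = np.arctan2(-R[0, 1], R[1, 1])
    else:
        psi = np.arcsin(sy)
        phi = np.arctan2(R[2, 1], R[2, 2])
        theta = np.arctan2(R[1, 0], R[0, 0])
    return EulerTriple(*np.rad2deg([phi, psi, theta]))


def euler_angle_distance(a: EulerTriple, b: EulerTriple) -> float:
    """Euclidean distance of two Euler triples, componentwise wrapped, degrees."""
    diff = wrap_degrees(a.as_array() - b.as_array())
    return float(np.sqrt(np.sum(diff * diff)))


# ---------------------------------------------------------------------------
# cuboids


def build_reference_cuboid(
    domain: VariableDomain, template: FrameworkTemplate
) -> Cuboid:
    """Principal-axis cuboid of the reference domain's framework anchors.

    Axes are the principal axes of the anchor Cα cloud, ordered by decreasing
    spread.  Eigenvector sign ambiguity is removed by orienting each of the
    first two axes so its dot product with the reference-frame axis of the
    same rank is positive; the third axis is their cross product (right-
    handed).  Extents are sized to cover all of the domain's atoms.
    """
    anchors = np.asarray(template.anchor_coordinates, float)
    center = anchors.mean(axis=0)
    centered = anchors - center
    vals, vecs = np.linalg.eigh(centered.T @ centered)
    order = np.argsort(vals)[::-1]
    if vals[order[1]] <= 1e-10:
        raise DegenerateGeometryError("anchors are collinear; cuboid axes undefined")
    axes = vecs[:, order].T  # rows = principal axes, largest spread first
    for i in range(2):
        if axes[i, i] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    all_atoms = np.array(
        [a.position for r in domain.residues for a in r.atoms]
    )
    proj = (all_atoms - center) @ axes.T
    half = np.abs(proj).max(axis=0)
    half = np.maximum(half, 1e-6)
    return Cuboid(center, half, axes)


def beta_pose(
    aligned: TCRComplex, beta_template: FrameworkTemplate
) -> tuple[RigidTransform, SuperpositionResult]:
    """Rigid pose of an aligned structure's β domain relative to the reference β.

    The Kabsch superposition maps the structure's β anchors onto the template;
    its inverse places the reference β framework onto this structure, which is
    the pose whose rotation the Euler angles describe.
    """
    result = superpose_on_template(aligned.beta, beta_template)
    return result.transform.inverse(), result


def place_beta_cuboid(
    aligned: TCRComplex,
    beta_template: FrameworkTemplate,
    ref_cuboid: Cuboid,
) -> Cuboid:
    """Transform the reference β cuboid by the aligned structure's β pose."""
    pose, _ = beta_pose(aligned, beta_template)
    cuboid = Cuboid(
        pose.apply(ref_cuboid.center),
        ref_cuboid.half_extents.copy(),
        ref_cuboid.axes @ pose.rotation.T,
    )
    cuboid.pose = pose
    return cuboid


# ---------------------------------------------------------------------------
# pipeline helper + table I/O


def complex_geometry(
    complex_: TCRComplex,
    alpha_template: FrameworkTemplate,
    beta_template: FrameworkTemplate,
) -> tuple[GeometryRecord, RigidTransform]:
    """Align a complex on Vα and express its Vβ pose as an Euler triple.

    Returns the geometry record together with the β pose transform (needed for
    the center-of-rotation grid analysis).
    """
    aligned, _ = align_complex_on_alpha(complex_, alpha_template)
    pose, _ = beta_pose(aligned, beta_template)
    record = GeometryRecord(
        pdb_id=complex_.pdb_id,
        bu_index=complex_.bu_index,
        euler=euler_xyz_from_rotation(pose.rotation),
        bound_state=complex_.bound_state,
        tcr_type=complex_.tcr_type,
    )
    return record, pose


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "pdb_id": r.pdb_id,
            "bu": r.bu_index,
            "phi": r.euler.phi,
            "psi": r.euler.psi,
            "theta": r.euler.theta,
            "bound_state": r.bound_state,
            "tcr_type": r.tcr_type,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_geometry_table(records, path: str | Path) -> None:
    """CSV writer: one row per BU/structure with Φ, Ψ, Θ in degrees."""
    records_to_frame(records).to_csv(path, index=False)


def read_geometry_table(path: str | Path) -> list[GeometryRecord]:
    df = pd.read_csv(path)
    return [
        GeometryRecord(
            pdb_id=str(row.pdb_id),
            bu_index=row.bu if isinstance(row.bu, str) else int(row.bu),
            euler=EulerTriple(row.phi, row.psi, row.theta),
            bound_state=row.bound_state,
            tcr_type="" if pd.isna(row.tcr_type) else str(row.tcr_type),
        )
        for row in df.itertuples()
    ]
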