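"""End-to-end orchestration: templates → alignment → geometries → poses.

Thin glue over the per-stage modules, shared by the command-line interface
and programmatic use.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .cuboid_geometry import (
    Cuboid,
    GeometryRecord,
    build_reference_cuboid,
    complex_geometry,
)
from .framework_template import (
    FrameworkTemplate,
    FrameworkTemplateBuilder,
    RigidTransform,
)
from .structure_io import TCRComplex


@dataclasses.dataclass
class TemplateSet:
    alpha: FrameworkTemplate
    beta: FrameworkTemplate
    beta_cuboid: Cuboid
    reference_pdb_id: str


def build_templates(
    complexes: list[TCRComplex],
    reference_pdb_id: str | None = None,
    deviation_cutoff: float = 1.0,
    rmsd_var_tol: float = 0.05,
    max_iter: int = 20,
) -> TemplateSet:
    """Derive converged α/β framework templates anchored on the reference.

    The reference complex (default: the first) defines the frame: its raw
    coordinates are the reference coordinate system and the β cuboid is built
    on its β anchors.
    """
    if reference_pdb_id is None:
        ref_idx = 0
    else:
        ref_idx = next(
            i for i, c in enumerate(complexes) if c.pdb_id == reference_pdb_id
        )
    builder = FrameworkTemplateBuilder(
        deviation_cutoff=deviation_cutoff,
        rmsd_var_tol=rmsd_var_tol,
        max_iter=max_iter,
        reference_index=ref_idx,
    )
    alpha_t = builder.fit([c.alpha for c in complexes]).template_
    beta_t = FrameworkTemplateBuilder(
        deviation_cutoff=deviation_cutoff,
        rmsd_var_tol=rmsd_var_tol,
        max_iter=max_iter,
        reference_index=ref_idx,
    ).fit([c.beta for c in complexes]).template_
    cuboid = build_reference_cuboid(complexes[ref_idx].beta, beta_t)
    return TemplateSet(alpha_t, beta_t, cuboid, complexes[ref_idx].pdb_id)


def extract_geometries(
    complexes: list[TCRComplex], templates: TemplateSet
) -> tuple[list[GeometryRecord], dict[str, RigidTransform]]:
    """Per-BU Euler-angle records and β poses for a set of complexes."""
    records, poses = [], {}
    for cx in complexes:
        rec, pose = complex_geometry(cx, templates.alpha, templates.beta)
        records.append(rec)
        poses[rec.label] = pose
    return records, poses


def write_poses_json(poses: dict[str, RigidTransform], path: str | Path) -> None:
    payload = {
        label: {"rotation": p.rotation.tolist(), "translation": p.translation.tolist()}
        for label, p in poses.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_poses_json(path: str | Path) -> dict[str, RigidTransform]:
    payload = json.loads(Path(path).read_text())
    return {
        label: RigidTransform(np.array(d["rotation"]), np.array(d["translation"]))
        for label, d in payload.items()
    }
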