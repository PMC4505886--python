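"""Reading TCR structures and extracting Vα/Vβ variable domains.

Structures are read with :mod:`gemmi` (PDB and mmCIF).  Which chains form a
biological unit (BU), and which author-numbered residue range is the variable
domain, is *manifest-driven*: a tab-separated manifest mirrors the dataset
table of the study (PDB id, per-BU chain pair, V-domain ranges, bound state,
species, TCR type).  Automatic α/β detection is deliberately out of scope —
a manifest makes every run reproducible.

Internally a residue keeps its author number plus insertion code, but all
indexing into an extracted domain is by 0-based ordinal position.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import ExtractionError, ManifestError, StructureParseError

BOUND_STATES = ("unbound", "mhc1", "mhc2", "superantigen")
_BOUND_CODE = {"u": "unbound", "1": "mhc1", "2": "mhc2", "s": "superantigen"}


@dataclasses.dataclass
class Atom:
    """One heavy atom: name, element, position (Å), altloc and occupancy."""

    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise StructureParseError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureParseError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )


@dataclasses.dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = dataclasses.field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}".strip()

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class VariableDomain:
    """The variable (antigen-binding) domain of one TCR chain.

    Residues are ordered by author numbering; the constant domain has been
    truncated away.  ``gap_count`` counts residues of the requested range that
    were unresolved in the crystal.
    """

    chain_type: str  # "alpha" | "beta"
    residues: list[Residue]
    source_chain_id: str
    gap_count: int = 0

    def __post_init__(self):
        if self.chain_type not in ("alpha", "beta"):
            raise ValueError(f"chain_type must be alpha/beta, got {self.chain_type!r}")
        keys = [(r.number, r.icode) for r in self.residues]
        if keys != sorted(keys):
            raise ValueError("residues must be strictly ordered by author numbering")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue numbers in domain")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) Cα coordinate array (residues lacking Cα are skipped)."""
        return np.array([r.ca.position for r in self.residues if r.ca is not None])

    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def ca_by_number(self) -> dict[int, np.ndarray]:
        return {r.number: r.ca.position for r in self.residues if r.ca is not None}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "VariableDomain":
        """Copy of the domain with ``x -> R x + t`` applied to every atom."""
        out = []
        for r in self.residues:
            atoms = [
                Atom(a.name, a.element, rotation @ a.position + translation,
                     a.altloc, a.occupancy)
                for a in r.atoms
            ]
            out.append(Residue(r.name, r.number, r.icode, atoms))
        return VariableDomain(self.chain_type, out, self.source_chain_id, self.gap_count)


@dataclasses.dataclass
class TCRComplex:
    """One biological unit: paired α/β variable domains plus metadata."""

    pdb_id: str
    bu_index: int
    alpha: VariableDomain
    beta: VariableDomain
    bound_state: str = "unbound"
    species: str = "human"
    tcr_type: str = ""
    subtype: str = ""
    context: list[Chain] = dataclasses.field(default_factory=list)
    ground_truth: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.bound_state not in BOUND_STATES:
            raise ValueError(f"bound_state must be one of {BOUND_STATES}")
        if self.bu_index < 1:
            raise ValueError("bu_index must be >= 1")

    def transformed(self, rotation, translation) -> "TCRComplex":
        """Apply the same rigid transform to every atom of the complex."""
        ctx = []
        for ch in self.context:
            residues = []
            for r in ch.residues:
                atoms = [Atom(a.name, a.element, rotation @ a.position + translation,
                              a.altloc, a.occupancy) for a in r.atoms]
                residues.append(Residue(r.name, r.number, r.icode, atoms))
            ctx.append(Chain(ch.chain_id, residues))
        return dataclasses.replace(
            self,
            alpha=self.alpha.transformed(rotation, translation),
            beta=self.beta.transformed(rotation, translation),
            context=ctx,
        )


@dataclasses.dataclass
class BUChains:
    """Chain ids of the α and β chains of one biological unit."""

    alpha_chain: str
    beta_chain: str


@dataclasses.dataclass
class ManifestEntry:
    pdb_id: str
    bus: list[BUChains]
    alpha_range: tuple[int, int] | None = None
    beta_range: tuple[int, int] | None = None
    bound_state: str = "unbound"
    species: str = "human"
    tcr_type: str = ""
    subtype: str = ""


@dataclasses.dataclass
class DatasetManifest:
    entries: list[ManifestEntry]

    def __post_init__(self):
        ids = [e.pdb_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate pdb_id in manifest")

    @property
    def total_bus(self) -> int:
        return sum(len(e.bus) for e in self.entries)

    def entry(self, pdb_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.pdb_id == pdb_id:
                return e
        raise ManifestError(f"{pdb_id} not in manifest")


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    """One conformer per atom name: highest occupancy, ties broken alphabetically."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
        out.append(dataclasses.replace(group[0], altloc=""))
    return out


def read_structure(path: str | Path) -> list[Chain]:
    """Parse a PDB or mmCIF file into chains of altloc-resolved residues.

    Only the first model is used.  Raises :class:`StructureParseError` on
    unreadable or empty input.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")
    chains = []
    for gchain in st[0]:
        residues = []
        for gres in gchain:
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    altloc=ga.altloc if ga.altloc != "\0" else "",
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                )
                for ga in gres
            ]
            residues.append(
                Residue(
                    name=gres.name,
                    number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    atoms=_resolve_altlocs(atoms),
                )
            )
        chains.append(Chain(gchain.name, residues))
    if not chains or all(len(c) == 0 for c in chains):
        raise StructureParseError(f"{path}: no ATOM records")
    return chains


def extract_variable_domain(
    chain: Chain,
    residue_range: tuple[int, int] | None,
    chain_type: str,
) -> VariableDomain:
    """Truncate a chain to its variable-domain residue range.

    ``residue_range`` is inclusive author numbering; ``None`` keeps the whole
    chain.  Residues of the range that are unresolved are counted in
    ``gap_count``.  Raises :class:`ExtractionError` if no residue in the range
    has a Cα atom.
    """
    if residue_range is None:
        kept = list(chain.residues)
        expected = len(kept)
    else:
        lo, hi = residue_range
        kept = [r for r in chain.residues if lo <= r.number <= hi]
        expected = hi - lo + 1
    kept = sorted(kept, key=lambda r: (r.number, r.icode))
    if not any(r.ca is not None for r in kept):
        raise ExtractionError(
            f"chain {chain.chain_id}: no Cα atoms in range {residue_range}"
        )
    gaps = max(expected - len(kept), 0)
    return VariableDomain(chain_type, kept, chain.chain_id, gap_count=gaps)


def enumerate_biological_units(
    chains: Iterable[Chain], entry: ManifestEntry
) -> list[TCRComplex]:
    """One :class:`TCRComplex` per biological unit listed in the manifest entry.

    Chains not named as α or β (MHC, peptide) are retained as context on every
    complex but excluded from the variable domains.
    """
    by_id = {c.chain_id: c for c in chains}
    complexes = []
    tcr_chain_ids = {b.alpha_chain for b in entry.bus} | {b.beta_chain for b in entry.bus}
    context = [c for c in by_id.values() if c.chain_id not in tcr_chain_ids]
    for i, bu in enumerate(entry.bus, start=1):
        for cid in (bu.alpha_chain, bu.beta_chain):
            if cid not in by_id:
                raise ManifestError(
                    f"{entry.pdb_id}: chain {cid!r} named in manifest absent from file"
                )
        alpha = extract_variable_domain(by_id[bu.alpha_chain], entry.alpha_range, "alpha")
        beta = extract_variable_domain(by_id[bu.beta_chain], entry.beta_range, "beta")
        complexes.append(
            TCRComplex(
                pdb_id=entry.pdb_id,
                bu_index=i,
                alpha=alpha,
                beta=beta,
                bound_state=entry.bound_state,
                species=entry.species,
                tcr_type=entry.tcr_type,
                subtype=entry.subtype,
                context=context,
            )
        )
    return complexes


# ---------------------------------------------------------------------------
# manifest file


def _parse_range(text: str) -> tuple[int, int] | None:
    text = text.strip()
    if not text or text == "-":
        return None
    lo, _, hi = text.partition("-")
    try:
        return int(lo), int(hi)
    except ValueError as exc:
        raise ManifestError(f"bad residue range {text!r}") from exc


def load_manifest(path: str | Path, allow_incomplete: bool = False) -> DatasetManifest:
    """Load a TSV manifest.

    Columns: ``pdb_id  bu_chains  alpha_range  beta_range  bound_state
    species  tcr_type  subtype``.  ``bu_chains`` is a comma-separated list of
    ``alpha:beta`` chain-id pairs, one per biological unit.  ``bound_state``
    accepts the table codes u/1/2/s or the long names.  With
    ``allow_incomplete`` rows may leave chains/ranges blank (the shipped
    reference manifest does; such entries cannot be processed until filled in).
    """
    path = Path(path)
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip().lower() == "pdb_id":
                continue  # header
            if len(fields) < 8:
                fields = fields + [""] * (8 - len(fields))
            pdb_id, bu_chains, a_rng, b_rng, bound, species, tcr_type, subtype = (
                f.strip() for f in fields[:8]
            )
            bus = []
            if bu_chains:
                for pair in bu_chains.split(","):
                    a, _, b = pair.partition(":")
                    if not a or not b:
                        raise ManifestError(f"{path}:{lineno}: bad BU chain pair {pair!r}")
                    bus.append(BUChains(a.strip(), b.strip()))
            elif not allow_incomplete:
                raise ManifestError(f"{path}:{lineno}: entry {pdb_id} names no chains")
            bound = _BOUND_CODE.get(bound.lower(), bound.lower()) or "unbound"
            if bound not in BOUND_STATES:
                raise ManifestError(f"{path}:{lineno}: unknown bound state {bound!r}")
            species = {"h": "human", "m": "mouse"}.get(species.lower(), species.lower()) or "human"
            entries.append(
                ManifestEntry(
                    pdb_id=pdb_id,
                    bus=bus,
                    alpha_range=_parse_range(a_rng),
                    beta_range=_parse_range(b_rng),
                    bound_state=bound,
                    species=species,
                    tcr_type=tcr_type,
                    subtype=subtype,
                )
            )
    return DatasetManifest(entries)


# ---------------------------------------------------------------------------
# writing


def write_domains_pdb(path: str | Path, *parts, remark: str = "") -> None:
    """Write domains/chains to a minimal PDB file (for inspection & round-trips).

    Each positional argument is a :class:`VariableDomain` or :class:`Chain`.
    Coordinates are written at PDB precision (3 decimals).
    """
    lines = []
    if remark:
        lines.append(f"REMARK 999 {remark}")
    serial = 1
    for part in parts:
        if isinstance(part, VariableDomain):
            chain_id, residues = part.source_chain_id, part.residues
        else:
            chain_id, residues = part.chain_id, part.residues
        for res in residues:
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.position
                lines.append(
                    f"ATOM  {serial:>5d} {name}{'':1s}{res.name:>3s} "
                    f"{chain_id[:1]:1s}{res.number:>4d}{res.icode[:1] or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
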