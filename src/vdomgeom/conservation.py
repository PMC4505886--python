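"""Amino-acid conservation at the CoR-adjacent position (IMGT position 44).

The CoR sits next to a residue pair — IMGT unique-numbering position 44 in
both chains, glutamine in most germline V segments — whose interchain
hydrogen bond stabilizes the pivot.  This module tabulates residue
frequencies at an alignment column of a V-segment multiple sequence
alignment.  MSA construction is external (an aligner run on the germline
database); the artifact consumes an aligned FASTA plus a column↔IMGT-position
map supplied as a two-column config file.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError

GAP = "-"


@dataclasses.dataclass
class Alignment:
    """id → aligned residue string; all rows equal length."""

    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, index: int) -> str:
        if not 0 <= index < self.length:
            raise IndexError(f"column {index} outside alignment of length {self.length}")
        return "".join(s[index] for s in self.sequences.values())


@dataclasses.dataclass
class PositionFrequencyTable:
    """Residue counts and fractions at one alignment column.

    Fractions are relative to the total sequence count (as conservation
    tables conventionally report them); gap rows are listed separately as
    incomplete rather than silently dropped.
    """

    position_label: str
    counts: dict[str, int]
    n_sequences: int
    n_gaps: int
    gap_ids: list[str]

    @property
    def fractions(self) -> dict[str, float]:
        return {aa: c / self.n_sequences for aa, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": self.position_label, "aa": aa, "count": c,
             "fraction": c / self.n_sequences}
            for aa, c in sorted(self.counts.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


def read_aligned_fasta(path: str | Path) -> Alignment:
    """Load an aligned FASTA; ids must be unique and rows equal length."""
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    if len(set(ids)) != len(ids):
        raise AlignmentFormatError(f"{path}: duplicate sequence ids")
    return Alignment({rec.id: str(rec.seq).upper() for rec in msa})


def write_aligned_fasta(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in alignment.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def frequency_at_position(
    alignment: Alignment, column: int, position_label: str | None = None
) -> PositionFrequencyTable:
    """Tabulate residue types at a 0-based alignment column."""
    col = alignment.column(column)
    counts = Counter(c for c in col if c != GAP)
    gap_ids = [name for name, seq in alignment.sequences.items() if seq[column] == GAP]
    return PositionFrequencyTable(
        position_label=position_label or f"col{column}",
        counts=dict(counts),
        n_sequences=alignment.n_sequences,
        n_gaps=len(gap_ids),
        gap_ids=gap_ids,
    )


def load_column_map(path: str | Path) -> dict[int, int]:
    """Two-column TSV ``imgt_position<TAB>alignment_column`` (0-based column)."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("imgt"):
            continue
        pos, col = line.split("\t")
        mapping[int(pos)] = int(col)
    return mapping


def frequency_at_imgt_position(
    alignment: Alignment, column_map: dict[int, int], imgt_position: int = 44
) -> PositionFrequencyTable:
    if imgt_position not in column_map:
        raise KeyError(f"IMGT position {imgt_position} not in column map")
    return frequency_at_position(
        alignment, column_map[imgt_position], position_label=f"IMGT{imgt_position}"
    )
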