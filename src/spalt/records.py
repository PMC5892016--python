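"""Protein sequence records and FASTA I/O.

A :class:`SequenceRecord` is the unit every scanner operates on: one
candidate protein with a free-text taxon label.  Residues are upper-case
one-letter amino-acid codes; ``X`` is allowed as an unknown residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The 20 standard amino acids plus X (unknown).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")


class AlphabetError(ValueError):
    """A residue outside the amino-acid alphabet, reported with its position."""

    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position
        self.char = char
        super().__init__(
            f"record {record_id!r}: invalid residue {char!r} at position {position}"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """One candidate protein sequence with taxon metadata."""

    id: str
    taxon: str
    residues: str

    def validate(self) -> "SequenceRecord":
        """Check the residue alphabet; raise :class:`AlphabetError` on violation."""
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise AlphabetError(self.id, i, ch)
        return self

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    The description line is parsed as ``id taxon...``: the first token is the
    record id, the remainder (if any) the taxon label; a record with no
    description keeps its id as the taxon.
    """
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        taxon = parts[1].strip() if len(parts) > 1 else rec.id
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(SequenceRecord(rec.id, taxon, str(rec.seq).upper()).validate())
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 80 columns, description = taxon."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.taxon)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(bio)
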