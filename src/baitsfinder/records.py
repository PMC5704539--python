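"""Sequence records and FASTA I/O.

A :class:`SequenceRecord` is the unit every stage of the pipeline passes
around: one transcriptome unigene, one reference protein or CDS, one
database entry. Residues are stored uppercase; IUPAC ambiguity codes are
permitted but never count as identities downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

# strict + ambiguity alphabets
_NT_CHARS = set("ACGTU") | set("RYSWKMBDHVN-")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY") | set("BXZJUO*-")

_NT_UNAMBIGUOUS = set("ACGT")
_AA_UNAMBIGUOUS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with a taxon label and an alphabet kind."""

    id: str
    residues: str
    kind: str = NUCLEOTIDE
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"SequenceRecord {self.id!r} has empty residues")
        object.__setattr__(self, "residues", self.residues.upper())
        alphabet = _NT_CHARS if self.kind == NUCLEOTIDE else _AA_CHARS
        bad = set(self.residues) - alphabet
        if bad:
            raise ValueError(
                f"SequenceRecord {self.id!r}: characters {sorted(bad)} not valid "
                f"for kind {self.kind!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def is_unambiguous(char: str, kind: str) -> bool:
    """True if *char* is a concrete (non-ambiguity, non-gap) residue."""
    pool = _NT_UNAMBIGUOUS if kind == NUCLEOTIDE else _AA_UNAMBIGUOUS
    return char in pool


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string (length truncated to a codon multiple)."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def six_frame_translations(seq: str) -> list[tuple[int, str]]:
    """All six reading frames of *seq*.

    Returns (frame, protein) pairs with frame in {1,2,3,-1,-2,-3}; negative
    frames read the reverse complement.
    """
    frames = []
    rc = reverse_complement(seq)
    for off in range(3):
        frames.append((off + 1, translate(seq[off:])))
        frames.append((-(off + 1), translate(rc[off:])))
    return [(f, p) for f, p in frames if p]


def read_fasta(
    source: Union[str, Path, TextIO],
    kind: str = NUCLEOTIDE,
    taxon: str = "",
) -> list[SequenceRecord]:
    """Read a FASTA file; the first whitespace-delimited header token is the id."""
    records = []
    for rec in SeqIO.parse(source, "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq), kind=kind, taxon=taxon))
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], dest: Union[str, Path, TextIO], width: int = 70
) -> None:
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            SeqIO.write(seqrecords, fh, "fasta")
    else:
        SeqIO.write(seqrecords, dest, "fasta")


def as_mapping(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    out: dict[str, SequenceRecord] = {}
    for r in records:
        if r.id in out:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        out[r.id] = r
    return out
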