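"""Group COS assignments into per-locus bundles and align them.

Every reference gene with at least one surviving assignment becomes a
:class:`LocusBundle`. An optional quality gate keeps only loci containing
the anchor taxon (the focal species with the best assembly by N50).
Alignment places the reference CDS as the first row so downstream exon
projection can walk its gap structure; members that hit the reference in
reverse orientation are reverse-complemented first (transcriptome
assemblies are unstranded).

Two alignment backends exist: an external MAFFT call (E-INS-i settings,
suited to sequences with long internal gaps) and an internal
reference-anchored star aligner that pairwise-aligns each member to the
reference and merges the rows on reference coordinates. The star aligner
keeps the pipeline self-contained and guarantees by construction that
degapping any row reproduces its input sequence.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .cos_filter import CosAssignment
from .homology import ScoringParams
from .records import NUCLEOTIDE, SequenceRecord, read_fasta, reverse_complement, write_fasta

GAP = "-"
MAFFT = "mafft"
INTERNAL = "internal"


@dataclass(frozen=True)
class AlignedRow:
    """One row of a locus alignment (gap character '-')."""

    seq_id: str
    taxon: str
    residues: str
    is_reference: bool = False

    def degapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class LocusBundle:
    """One reference gene plus all focal sequences assigned to it."""

    ref_gene_id: str
    members: tuple[CosAssignment, ...]
    alignment: Optional[tuple[AlignedRow, ...]] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("LocusBundle needs at least one member")
        off = {m.ref_gene_id for m in self.members} - {self.ref_gene_id}
        if off:
            raise ValueError(
                f"members assigned to {sorted(off)} mixed into bundle {self.ref_gene_id}"
            )
        if self.alignment is not None:
            widths = {len(r.residues) for r in self.alignment}
            if len(widths) != 1:
                raise ValueError("alignment rows have unequal widths")

    @property
    def taxa(self) -> set[str]:
        return {m.taxon for m in self.members}


def bundle_by_reference(assignments: Sequence[CosAssignment]) -> list[LocusBundle]:
    """One bundle per reference gene; members partition the assignments."""
    groups: dict[str, list[CosAssignment]] = {}
    for a in assignments:
        groups.setdefault(a.ref_gene_id, []).append(a)
    return [
        LocusBundle(ref_gene_id=g, members=tuple(groups[g])) for g in sorted(groups)
    ]


def require_anchor_taxon(
    bundles: Sequence[LocusBundle],
    anchor: Optional[str],
    known_taxa: Optional[set[str]] = None,
) -> list[LocusBundle]:
    """Keep only loci containing the anchor taxon; ``anchor=None``
    disables the gate and returns the input unchanged."""
    if anchor is None:
        return list(bundles)
    if known_taxa is not None and anchor not in known_taxa:
        raise ValueError(f"unknown anchor taxon {anchor!r}; known: {sorted(known_taxa)}")
    return [b for b in bundles if anchor in b.taxa]


def oriented_member_sequence(member: CosAssignment) -> str:
    """Member residues, reverse-complemented when the retained hit is on
    the reverse strand/frame (s_start > s_end)."""
    seq = member.unigene.residues
    return reverse_complement(seq) if member.hit.is_reverse else seq


def align_locus(
    bundle: LocusBundle,
    reference_cds: SequenceRecord,
    backend: str = INTERNAL,
    scoring: ScoringParams = ScoringParams(),
) -> LocusBundle:
    """Align the reference CDS plus all member unigenes.

    Rows: reference first, then members in input order. Degapping any row
    recovers its (oriented) input sequence exactly.
    """
    if reference_cds.id != bundle.ref_gene_id:
        raise ValueError(
            f"reference CDS {reference_cds.id!r} does not match bundle "
            f"{bundle.ref_gene_id!r}"
        )
    member_seqs = [
        (m.unigene.id, m.taxon, oriented_member_sequence(m)) for m in bundle.members
    ]
    if backend == INTERNAL:
        rows = _star_align(reference_cds, member_seqs, scoring)
    elif backend == MAFFT:
        rows = _mafft_align(reference_cds, member_seqs)
    else:
        raise ValueError(f"unknown alignment backend {backend!r}")
    return replace(bundle, alignment=tuple(rows))


# ---------------------------------------------------------------------------
# internal reference-anchored star aligner


def _pairwise_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    alphabet = "ACGTURYSWKMBDHVN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            m[a, b] = scoring.nt_match if (a == b and a in "ACGT") else scoring.nt_mismatch
    aligner.substitution_matrix = m
    aligner.open_gap_score = -(scoring.nt_gap_open + scoring.nt_gap_extend)
    aligner.extend_gap_score = -scoring.nt_gap_extend
    return aligner


def _map_member_to_reference(ref: str, mem: str, aligner: Align.PairwiseAligner):
    """Project *mem* onto reference coordinates.

    Returns (ins, at) where ins[r] is the member substring inserted
    between reference residues r-1 and r (r in 0..len(ref)) and at[r] is
    the member character aligned to reference residue r, or None.
    """
    R = len(ref)
    ins = [""] * (R + 1)
    at: list[Optional[str]] = [None] * R
    alignment = aligner.align(ref, mem)[0]
    blocks_r, blocks_m = alignment.aligned
    prev_r = int(blocks_r[0][0])
    prev_m = 0  # member prefix outside the local alignment is an insertion
    for (rs, re_), (ms, me) in zip(blocks_r, blocks_m):
        if ms > prev_m:
            ins[prev_r] += mem[prev_m:ms]
        for k in range(re_ - rs):
            at[rs + k] = mem[ms + k]
        prev_r, prev_m = int(re_), int(me)
    if prev_m < len(mem):
        ins[prev_r] += mem[prev_m:]
    return ins, at


def _star_align(
    reference: SequenceRecord,
    member_seqs: Sequence[tuple[str, str, str]],
    scoring: ScoringParams,
) -> list[AlignedRow]:
    ref = reference.residues
    R = len(ref)
    aligner = _pairwise_aligner(scoring)
    projections = [
        _map_member_to_reference(ref, seq, aligner) for _, _, seq in member_seqs
    ]
    widths = [
        max((len(ins[r]) for ins, _ in projections), default=0) for r in range(R + 1)
    ]
    ref_cols: list[str] = []
    member_cols: list[list[str]] = [[] for _ in member_seqs]
    for r in range(R + 1):
        w = widths[r]
        if w:
            ref_cols.append(GAP * w)
            for cols, (ins, _) in zip(member_cols, projections):
                cols.append(ins[r].ljust(w, GAP))
        if r < R:
            ref_cols.append(ref[r])
            for cols, (_, at) in zip(member_cols, projections):
                cols.append(at[r] or GAP)
    rows = [
        AlignedRow(reference.id, reference.taxon, "".join(ref_cols), is_reference=True)
    ]
    for (seq_id, taxon, _), cols in zip(member_seqs, member_cols):
        rows.append(AlignedRow(seq_id, taxon, "".join(cols)))
    return rows


# ---------------------------------------------------------------------------
# external MAFFT backend


def _mafft_align(
    reference: SequenceRecord, member_seqs: Sequence[tuple[str, str, str]]
) -> list[AlignedRow]:
    if shutil.which("mafft") is None:
        raise RuntimeError(
            "mafft binary not found on PATH; use the internal backend "
            "(backend='internal') or install MAFFT"
        )
    taxon_by_id = {seq_id: taxon for seq_id, taxon, _ in member_seqs}
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "locus.fa"
        records = [reference] + [
            SequenceRecord(seq_id, seq, NUCLEOTIDE, taxon)
            for seq_id, taxon, seq in member_seqs
        ]
        write_fasta(records, infile)
        proc = subprocess.run(
            ["mafft", "--genafpair", "--maxiterate", "1000", "--quiet", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = Path(tmp) / "aligned.fa"
        out.write_text(proc.stdout)
        aligned = read_fasta(out, kind=NUCLEOTIDE)
    by_id = {r.id: r.residues for r in aligned}
    rows = [AlignedRow(reference.id, reference.taxon, by_id[reference.id], True)]
    for seq_id, taxon, _ in member_seqs:
        rows.append(AlignedRow(seq_id, taxon, by_id[seq_id]))
    return rows


def write_locus_dirs(
    bundles: Sequence[LocusBundle],
    reference_cds: dict[str, SequenceRecord],
    out_dir: Union[str, Path],
) -> None:
    """Per-locus directories named after the reference gene, each with the
    unaligned member FASTA and, when present, the alignment."""
    out = Path(out_dir)
    for b in bundles:
        locus_dir = out / b.ref_gene_id
        locus_dir.mkdir(parents=True, exist_ok=True)
        records = [reference_cds[b.ref_gene_id]] + [
            SequenceRecord(m.unigene.id, oriented_member_sequence(m), NUCLEOTIDE, m.taxon)
            for m in b.members
        ]
        write_fasta(records, locus_dir / "sequences.fa")
        if b.alignment is not None:
            write_fasta(
                [
                    SequenceRecord(r.seq_id, r.residues, NUCLEOTIDE, r.taxon)
                    for r in b.alignment
                ],
                locus_dir / "alignment.fa",
            )
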