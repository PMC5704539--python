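"""Desk-scale local homology search and BLAST-tabular interchange.

The pipeline's searches (focal unigenes vs. the SCG reference, host and
plastid screens, reference self-comparison) are all small enough to run
with an internal engine instead of an external BLAST binary: queries are
seeded against an exact k-mer index of the subjects (k=3 for protein
comparisons with a two-seeds-on-one-diagonal rule, k=11 for nucleotide
comparisons), and every seeded pair is then aligned in full with an
affine-gap Smith-Waterman (gapped mode) or a best ungapped segment pair
(ungapped mode). Externally produced hits in 12-column ``outfmt 6``
tabular form can be substituted anywhere via :func:`parse_tabular_hits`.

Two programs are provided, mirroring the searches the workflow needs:

* ``blastx_like`` — nucleotide queries translated in all six reading
  frames against protein subjects; alignment lengths and coordinates on
  the subject side are in amino-acid units.
* ``blastn_like`` — nucleotide vs. nucleotide, both query strands.

E-values follow the Karlin-Altschul form ``E = m * n * 2**(-bitscore)``
with ``n`` the summed subject length, using fixed lambda/K constants; the
engine is a stand-in for BLAST, not a reproduction of its statistics.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .records import (
    NUCLEOTIDE,
    PROTEIN,
    SequenceRecord,
    is_unambiguous,
    reverse_complement,
    six_frame_translations,
)

GAPPED = "gapped"
UNGAPPED = "ungapped"
BLASTX_LIKE = "blastx_like"
BLASTN_LIKE = "blastn_like"


@dataclass(frozen=True)
class SearchMode:
    """Search configuration: gapped/ungapped, translated or nucleotide."""

    mode: str = GAPPED
    program: str = BLASTX_LIKE

    def __post_init__(self) -> None:
        if self.mode not in (GAPPED, UNGAPPED):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.program not in (BLASTX_LIKE, BLASTN_LIKE):
            raise ValueError(f"unknown program {self.program!r}")


@dataclass(frozen=True)
class ScoringParams:
    """BLAST-like scoring defaults.

    Protein: BLOSUM62 with gap open 11 / extend 1. Nucleotide: match +2,
    mismatch -3, gap open 5 / extend 2. A single fixed (lambda, K) pair
    converts raw scores to bit scores.
    """

    protein_matrix: str = "BLOSUM62"
    protein_gap_open: int = 11
    protein_gap_extend: int = 1
    nt_match: int = 2
    nt_mismatch: int = -3
    nt_gap_open: int = 5
    nt_gap_extend: int = 2
    karlin_lambda: float = 0.318
    karlin_k: float = 0.13
    max_evalue: float = 1e-10  # reporting cutoff of the search itself
    protein_word_size: int = 3
    nt_word_size: int = 11

    def bitscore(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, bitscore: float, query_len: int, db_len: int) -> float:
        # 2**(-bit) underflows harmlessly to 0.0 for very strong hits
        try:
            return query_len * db_len * 2.0 ** (-bitscore)
        except OverflowError:
            return math.inf if bitscore < 0 else 0.0


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise local alignment in BLAST tabular shape.

    Coordinates are 1-based inclusive. Reverse-strand / reverse-frame hits
    carry ``s_start > s_end``; query coordinates always refer to the
    forward query sequence with ``q_start < q_end``. For translated
    (blastx-like) searches ``aln_length``, mismatches and subject
    coordinates are in amino-acid units while query coordinates are in
    nucleotides.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject span as an ordered (low, high) 1-based inclusive pair."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))

    @property
    def is_reverse(self) -> bool:
        return self.s_start > self.s_end


class TabularParseError(ValueError):
    pass


def parse_tabular_hits(stream: Union[Iterable[str], str, Path, TextIO]) -> list[HomologyHit]:
    """Parse 12-column BLAST ``outfmt 6`` lines into hits.

    Comment lines (leading ``#``) and blank lines are skipped; a malformed
    line raises :class:`TabularParseError` naming its line number.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return parse_tabular_hits(fh)
    hits = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise TabularParseError(
                f"line {lineno}: expected >=12 tab-separated fields, got {len(fields)}"
            )
        try:
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise TabularParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit], dest: Union[str, Path, TextIO]) -> None:
    """Write hits as 12-column tabular TSV; floats use repr so the
    write/parse round-trip is exact."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_tabular_hits(hits, fh)
            return
    for h in hits:
        dest.write(
            "\t".join(
                str(v)
                for v in (
                    h.query_id,
                    h.subject_id,
                    h.pct_identity,
                    h.aln_length,
                    h.mismatches,
                    h.gap_opens,
                    h.q_start,
                    h.q_end,
                    h.s_start,
                    h.s_end,
                    h.evalue,
                    h.bitscore,
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# internal engine


def _make_aligner(kind: str, mode: str, scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if kind == PROTEIN:
        aligner.substitution_matrix = substitution_matrices.load(scoring.protein_matrix)
        open_, extend = scoring.protein_gap_open, scoring.protein_gap_extend
    else:
        matrix = _nt_matrix(scoring)
        aligner.substitution_matrix = matrix
        open_, extend = scoring.nt_gap_open, scoring.nt_gap_extend
    if mode == UNGAPPED:
        # prohibitive gap cost: the optimal local alignment is the best
        # ungapped segment pair
        aligner.open_gap_score = -1e9
        aligner.extend_gap_score = -1e9
    else:
        # BLAST convention: a gap of length g costs open + g*extend
        aligner.open_gap_score = -(open_ + extend)
        aligner.extend_gap_score = -extend
    return aligner


_NT_ALPHABET = "ACGTURYSWKMBDHVN"


def _nt_matrix(scoring: ScoringParams):
    n = len(_NT_ALPHABET)
    m = substitution_matrices.Array(_NT_ALPHABET, dims=2)
    for i, a in enumerate(_NT_ALPHABET):
        for b in _NT_ALPHABET:
            if a == b and a in "ACGT":
                m[a, b] = scoring.nt_match
            else:
                m[a, b] = scoring.nt_mismatch
    return m


_BLOSUM_CHARS = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize_protein(seq: str) -> str:
    """Map residues missing from the scoring matrix (J/U/O) to X."""
    if set(seq) <= _BLOSUM_CHARS:
        return seq
    return "".join(c if c in _BLOSUM_CHARS else "X" for c in seq)


def _kmer_index(seqs: Sequence[tuple[int, str]], k: int) -> dict[str, list[tuple[int, int]]]:
    """kmer -> [(sequence index, position), ...] postings."""
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for si, s in seqs:
        for pos in range(len(s) - k + 1):
            index[s[pos : pos + k]].append((si, pos))
    return index


def _seeded_subjects(
    query: str, index: dict[str, list[tuple[int, int]]], k: int, min_diag_seeds: int
) -> set[int]:
    """Subjects sharing >= min_diag_seeds exact k-mers on one diagonal."""
    diag_counts: dict[tuple[int, int], int] = defaultdict(int)
    hit_subjects: set[int] = set()
    for qpos in range(len(query) - k + 1):
        postings = index.get(query[qpos : qpos + k])
        if not postings:
            continue
        for si, spos in postings:
            key = (si, qpos - spos)
            c = diag_counts[key] + 1
            diag_counts[key] = c
            if c >= min_diag_seeds:
                hit_subjects.add(si)
    return hit_subjects


def _alignment_stats(alignment, q_seq: str, s_seq: str, kind: str):
    """Columns, identities, mismatches, gap opens and end coords of a
    Biopython local alignment."""
    blocks_q, blocks_s = alignment.aligned
    matches = 0
    mismatches = 0
    gap_opens = 0
    columns = 0
    prev_q_end = prev_s_end = None
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        if prev_q_end is not None:
            gq = qs - prev_q_end
            gs = ss - prev_s_end
            if gq:
                gap_opens += 1
                columns += gq
            if gs:
                gap_opens += 1
                columns += gs
        for a, b in zip(q_seq[qs:qe], s_seq[ss:se]):
            columns += 1
            if a == b and is_unambiguous(a, kind):
                matches += 1
            else:
                mismatches += 1
        prev_q_end, prev_s_end = qe, se
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]), int(blocks_s[-1][1])
    return columns, matches, mismatches, gap_opens, q_start, q_end, s_start, s_end


def _frame_to_query_coords(frame: int, qlen_nt: int, aa_start: int, aa_end: int):
    """Map a [aa_start, aa_end) span on a translated frame back to 1-based
    inclusive nucleotide coordinates on the forward query."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start + 1, off + 3 * aa_end
    # reverse frames were translated from the reverse complement
    rc_start = off + 3 * aa_start + 1
    rc_end = off + 3 * aa_end
    return qlen_nt - rc_end + 1, qlen_nt - rc_start + 1


def search(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    mode: SearchMode = SearchMode(),
    scoring: ScoringParams = ScoringParams(),
) -> list[HomologyHit]:
    """Run the internal engine; one best hit per (query, subject) pair.

    Hits whose E-value exceeds ``scoring.max_evalue`` are not reported.
    """
    if not queries or not subjects:
        return []
    if mode.program == BLASTX_LIKE:
        if any(q.kind != NUCLEOTIDE for q in queries):
            raise ValueError("blastx_like requires nucleotide queries")
        if any(s.kind != PROTEIN for s in subjects):
            raise ValueError("blastx_like requires protein subjects")
        subj_kind = PROTEIN
        k = scoring.protein_word_size
        # random protein pairs frequently share two k=3 words on one
        # diagonal; three is rare by chance yet near-certain for any
        # threshold-passing homolog (>=100 aligned aa at >=40% identity)
        min_seeds = 3
    else:
        if any(q.kind != NUCLEOTIDE for q in queries) or any(
            s.kind != NUCLEOTIDE for s in subjects
        ):
            raise ValueError("blastn_like requires nucleotide queries and subjects")
        subj_kind = NUCLEOTIDE
        k = scoring.nt_word_size
        min_seeds = 1

    index = _kmer_index([(i, s.residues) for i, s in enumerate(subjects)], k)
    aligner = _make_aligner(subj_kind, mode.mode, scoring)
    db_len = sum(len(s) for s in subjects)

    hits: list[HomologyHit] = []
    for q in queries:
        best_per_subject: dict[int, HomologyHit] = {}
        if mode.program == BLASTX_LIKE:
            views = [
                (frame, _sanitize_protein(prot))
                for frame, prot in six_frame_translations(q.residues)
            ]
        else:
            views = [(1, q.residues), (-1, reverse_complement(q.residues))]
        for frame, view in views:
            if len(view) < k:
                continue
            for si in _seeded_subjects(view, index, k, min_seeds):
                subj = subjects[si]
                score = aligner.score(view, subj.residues)
                if score <= 0:
                    continue
                bit = scoring.bitscore(score)
                ev = scoring.evalue(bit, len(q), db_len)
                if ev > scoring.max_evalue:
                    continue
                prev = best_per_subject.get(si)
                if prev is not None and prev.bitscore >= round(bit, 1):
                    continue
                alignment = aligner.align(view, subj.residues)[0]
                (
                    columns,
                    matches,
                    mismatches,
                    gaps,
                    v_start,
                    v_end,
                    s_start0,
                    s_end0,
                ) = _alignment_stats(alignment, view, subj.residues, subj_kind)
                if mode.program == BLASTX_LIKE:
                    q_start, q_end = _frame_to_query_coords(frame, len(q), v_start, v_end)
                    s_start, s_end = s_start0 + 1, s_end0
                else:
                    if frame > 0:
                        q_start, q_end = v_start + 1, v_end
                    else:
                        q_start, q_end = len(q) - v_end + 1, len(q) - v_start
                    s_start, s_end = s_start0 + 1, s_end0
                if frame < 0:
                    # reverse-frame/strand convention: swap subject coords
                    s_start, s_end = s_end, s_start
                hit = HomologyHit(
                    query_id=q.id,
                    subject_id=subj.id,
                    pct_identity=round(100.0 * matches / columns, 2),
                    aln_length=columns,
                    mismatches=mismatches,
                    gap_opens=gaps,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=ev,
                    bitscore=round(bit, 1),
                )
                if prev is None or hit.bitscore > prev.bitscore:
                    best_per_subject[si] = hit
        hits.extend(sorted(best_per_subject.values(), key=lambda h: (-h.bitscore, h.subject_id)))
    return hits
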