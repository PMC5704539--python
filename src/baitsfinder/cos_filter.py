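"""From raw homology hits to clean per-taxon COS assignments.

A focal unigene becomes a putative conserved orthologous sequence (COS)
when its best blastx-like hit against the SCG reference passes all three
thresholds: identity >= 40%, E-value <= 1e-20 and alignment length >= 100
amino-acid positions. Two decontamination screens follow: unigenes with
>= 95% nucleotide identity to a host-plant database are removed (parasite
assemblies may contain host transcripts), and same-taxon unigenes whose
retained hits overlap on the same reference gene by more than a cutoff
are treated as putative paralogs and removed as a group — strictness
over yield, since a hidden paralog poisons a phylogenetic marker.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from . import homology
from .homology import BLASTN_LIKE, GAPPED, HomologyHit, ScoringParams, SearchMode
from .records import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """COS acceptance thresholds, inclusive on every bound.

    ``min_aln_len`` is in amino-acid columns (blastx-like hits); 100 aa
    corresponds to a 300-bp minimum locus length.
    """

    min_identity: float = 40.0
    max_evalue: float = 1e-20
    min_aln_len: int = 100

    def __post_init__(self) -> None:
        if self.min_identity <= 0 or self.max_evalue <= 0 or self.min_aln_len <= 0:
            raise ValueError("all thresholds must be strictly positive")

    def passes(self, hit: HomologyHit) -> bool:
        return (
            hit.pct_identity >= self.min_identity
            and hit.evalue <= self.max_evalue
            and hit.aln_length >= self.min_aln_len
        )


@dataclass(frozen=True)
class CosAssignment:
    """A unigene accepted as COS for exactly one reference gene."""

    unigene: SequenceRecord
    taxon: str
    ref_gene_id: str
    hit: HomologyHit


def best_hit_per_query(
    hits: Sequence[HomologyHit],
    thresholds: FilterThresholds,
    sequences: Mapping[str, SequenceRecord],
    taxon: str,
) -> list[CosAssignment]:
    """Retain, per query, the single best threshold-passing hit.

    Best = max bitscore; ties broken by lower E-value, then longer
    alignment, then lexicographically smaller subject id. Queries with no
    passing hit are absent from the output.
    """
    by_query: dict[str, HomologyHit] = {}
    for h in hits:
        if not thresholds.passes(h):
            continue
        prev = by_query.get(h.query_id)
        if prev is None or _hit_rank(h) < _hit_rank(prev):
            by_query[h.query_id] = h
    out = []
    for qid in sorted(by_query):
        h = by_query[qid]
        if qid not in sequences:
            raise KeyError(f"hit query {qid!r} not found among provided sequences")
        out.append(
            CosAssignment(
                unigene=sequences[qid], taxon=taxon, ref_gene_id=h.subject_id, hit=h
            )
        )
    return out


def _hit_rank(h: HomologyHit):
    # sort ascending: best hit ranks first
    return (-h.bitscore, h.evalue, -h.aln_length, h.subject_id)


def remove_host_like(
    assignments: Sequence[CosAssignment],
    host_db: Sequence[SequenceRecord],
    min_identity: float = 95.0,
    scoring: ScoringParams = ScoringParams(),
) -> list[CosAssignment]:
    """Drop assignments whose unigene matches the host database at
    >= *min_identity* percent nucleotide identity (blastn-like)."""
    if not host_db:
        warnings.warn("empty host database: host screen left input unchanged")
        return list(assignments)
    queries = [a.unigene for a in assignments]
    hits = homology.search(queries, list(host_db), SearchMode(GAPPED, BLASTN_LIKE), scoring)
    contaminated = {h.query_id for h in hits if h.pct_identity >= min_identity}
    kept = [a for a in assignments if a.unigene.id not in contaminated]
    logger.info("host screen: %d -> %d assignments", len(assignments), len(kept))
    return kept


def subject_overlap(a: HomologyHit, b: HomologyHit) -> int:
    """Overlap (in subject residues) of two hits' subject intervals; <=0
    when disjoint."""
    a_lo, a_hi = a.subject_interval
    b_lo, b_hi = b.subject_interval
    return min(a_hi, b_hi) - max(a_lo, b_lo) + 1


def remove_paralogs(
    assignments: Sequence[CosAssignment], overlap_cutoff: int = 30
) -> list[CosAssignment]:
    """Remove whole (taxon, reference gene) groups with overlapping hits.

    Within each same-taxon group assigned to one reference gene, if any
    pair of retained hits overlaps by more than *overlap_cutoff* subject
    residues (amino acids), every member of the group is removed — the
    locus may persist through other taxa. Non-overlapping fragments of a
    single transcript are untouched.
    """
    if overlap_cutoff < 0:
        raise ValueError("paralog overlap cutoff must be non-negative")
    groups: dict[tuple[str, str], list[CosAssignment]] = {}
    for a in assignments:
        groups.setdefault((a.taxon, a.ref_gene_id), []).append(a)
    doomed: set[tuple[str, str]] = set()
    for key, members in groups.items():
        if len(members) < 2:
            continue
        hits = [m.hit for m in members]
        if any(
            subject_overlap(hits[i], hits[j]) > overlap_cutoff
            for i in range(len(hits))
            for j in range(i + 1, len(hits))
        ):
            doomed.add(key)
    return [a for a in assignments if (a.taxon, a.ref_gene_id) not in doomed]


def assembly_n50(transcriptome: Sequence[SequenceRecord]) -> int:
    """N50: the largest length L such that contigs of length >= L hold at
    least half of the total assembly length."""
    if not transcriptome:
        raise ValueError("cannot compute N50 of an empty assembly")
    lengths = sorted((len(r) for r in transcriptome), reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")
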