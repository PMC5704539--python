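"""120-bp bait tiling and the final bait-set filters.

Baits are laid on each degapped exon sequence with 2x tiling (step =
half the bait length) plus one terminal bait flush with the 3' end when
it would not overlap its neighbour by more than 80 bp — from a 160-bp
fragment two baits overlapping by 80 bp can still be extracted. Loci
whose anchor-taxon sequences yield fewer than four baits (i.e. less than
280 bp of tilable sequence) are removed; near-identical baits across
taxa are collapsed by greedy >= 90%-identity clustering (cd-hit-est
style); finally, loci with any bait matching an organelle genome at
>= 90% identity are dropped wholesale, since the chloroplast is vastly
overrepresented in total DNA and would soak up the capture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from . import homology
from .exon_projection import ExonBlock
from .homology import BLASTN_LIKE, GAPPED, ScoringParams, SearchMode
from .records import NUCLEOTIDE, SequenceRecord, is_unambiguous, reverse_complement


@dataclass(frozen=True)
class TilingParams:
    """Bait layout: length 120 bp, step 60 bp (2x tiling), terminal bait
    allowed up to 80 bp overlap with its neighbour."""

    bait_len: int = 120
    step: int = 60
    max_overlap: int = 80

    def __post_init__(self) -> None:
        if self.bait_len <= 0:
            raise ValueError("bait_len must be positive")
        if not (0 < self.step <= self.bait_len):
            raise ValueError("step must satisfy 0 < step <= bait_len")
        if not (0 <= self.max_overlap < self.bait_len):
            raise ValueError("max_overlap must satisfy 0 <= max_overlap < bait_len")


@dataclass(frozen=True)
class Bait:
    """A probe with locus/exon/taxon provenance; ``start`` is the 0-based
    offset within the degapped exon sequence it was cut from."""

    sequence: str
    ref_gene_id: str
    exon_index: int
    taxon: str
    start: int
    member_id: str = ""

    def __post_init__(self) -> None:
        if "-" in self.sequence:
            raise ValueError("bait sequences must be gap-free")
        if self.start < 0:
            raise ValueError("bait start must be non-negative")


def tile_starts(length: int, params: TilingParams = TilingParams()) -> list[int]:
    """Start offsets of all baits on a sequence of the given length.

    Regular baits sit on the step lattice (0, step, 2*step, ...) as long
    as they fit; if the last regular bait does not reach the 3' end, one
    terminal bait flush with the end is added iff its overlap with the
    last regular bait does not exceed ``max_overlap``.
    """
    L, b, s = length, params.bait_len, params.step
    if L < b:
        return []
    starts = list(range(0, L - b + 1, s))
    last_end = starts[-1] + b
    if last_end < L:
        terminal = L - b
        if last_end - terminal <= params.max_overlap:
            starts.append(terminal)
    return starts


def tile_baits(
    seq: str,
    params: TilingParams = TilingParams(),
    *,
    ref_gene_id: str = "",
    exon_index: int = 0,
    taxon: str = "",
    member_id: str = "",
) -> list[Bait]:
    """Cut baits from a gap-free sequence per :func:`tile_starts`."""
    if "-" in seq:
        raise ValueError("tile_baits requires a gap-free sequence")
    return [
        Bait(
            sequence=seq[st : st + params.bait_len],
            ref_gene_id=ref_gene_id,
            exon_index=exon_index,
            taxon=taxon,
            start=st,
            member_id=member_id,
        )
        for st in tile_starts(len(seq), params)
    ]


def design_baits(
    blocks: Sequence[ExonBlock], params: TilingParams = TilingParams()
) -> list[Bait]:
    """Tile every per-taxon exon sequence of every block."""
    baits = []
    for block in blocks:
        for member_id, taxon, seq in block.sequences:
            baits.extend(
                tile_baits(
                    seq,
                    params,
                    ref_gene_id=block.ref_gene_id,
                    exon_index=block.exon_index,
                    taxon=taxon,
                    member_id=member_id,
                )
            )
    return baits


def filter_low_yield_loci(
    baits: Sequence[Bait], anchor: Optional[str], min_baits: int = 4
) -> tuple[set[str], list[Bait]]:
    """Drop loci whose anchor-taxon bait yield is below *min_baits*.

    With ``anchor=None`` the gate is disabled and every locus is kept.
    Returns (retained locus ids, filtered baits); all baits of dropped
    loci are discarded regardless of taxon.
    """
    loci = {b.ref_gene_id for b in baits}
    if anchor is None:
        return loci, list(baits)
    counts: dict[str, int] = {}
    for b in baits:
        if b.taxon == anchor:
            counts[b.ref_gene_id] = counts.get(b.ref_gene_id, 0) + 1
    retained = {g for g in loci if counts.get(g, 0) >= min_baits}
    return retained, [b for b in baits if b.ref_gene_id in retained]


def _bait_identity(a: str, b: str) -> float:
    """Percent of positions with identical unambiguous nucleotides,
    taking the better of forward and reverse-complement orientation."""
    def pct(x: str, y: str) -> float:
        n = sum(
            1 for p, q in zip(x, y) if p == q and is_unambiguous(p, NUCLEOTIDE)
        )
        return 100.0 * n / len(x)

    return max(pct(a, b), pct(a, reverse_complement(b)))


def cluster_redundant(baits: Sequence[Bait], identity: float = 90.0) -> list[Bait]:
    """Greedy cd-hit-style clustering of equal-length baits.

    Baits are sorted deterministically (locus, exon, taxon, start,
    member); each joins the first cluster whose representative it matches
    at >= *identity* percent (position-wise, either strand), else founds
    its own. Representatives are returned in sort order.
    """
    if not baits:
        return []
    lengths = {len(b.sequence) for b in baits}
    if len(lengths) != 1:
        raise ValueError("cluster_redundant expects equal-length baits")
    ordered = sorted(
        baits, key=lambda b: (b.ref_gene_id, b.exon_index, b.taxon, b.start, b.member_id)
    )
    reps: list[Bait] = []
    for b in ordered:
        if not any(_bait_identity(b.sequence, r.sequence) >= identity for r in reps):
            reps.append(b)
    return reps


def drop_organelle_loci(
    baits: Sequence[Bait],
    organelle_db: Sequence[SequenceRecord],
    identity: float = 90.0,
    scoring: ScoringParams = ScoringParams(),
) -> list[Bait]:
    """Remove every bait of any locus with at least one bait hitting the
    organelle database at >= *identity* percent (blastn-like)."""
    if not organelle_db:
        warnings.warn("empty organelle database: screen left input unchanged")
        return list(baits)
    queries = [
        SequenceRecord(f"bait{i}", b.sequence, NUCLEOTIDE, b.taxon)
        for i, b in enumerate(baits)
    ]
    hits = homology.search(queries, list(organelle_db), SearchMode(GAPPED, BLASTN_LIKE), scoring)
    flagged_idx = {
        int(h.query_id[4:]) for h in hits if h.pct_identity >= identity
    }
    doomed = {baits[i].ref_gene_id for i in flagged_idx}
    return [b for b in baits if b.ref_gene_id not in doomed]


def bait_fasta_records(baits: Sequence[Bait]) -> list[SequenceRecord]:
    """Headers encode provenance: ``refgene|exon|taxon|start``."""
    return [
        SequenceRecord(
            f"{b.ref_gene_id}|{b.exon_index}|{b.taxon}|{b.start}",
            b.sequence,
            NUCLEOTIDE,
            b.taxon,
        )
        for b in baits
    ]


def write_bait_manifest(baits: Sequence[Bait], dest: Union[str, Path]) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "ref_gene_id": b.ref_gene_id,
                "exon_index": b.exon_index,
                "taxon": b.taxon,
                "member_id": b.member_id,
                "start": b.start,
                "sequence": b.sequence,
            }
            for b in baits
        ]
    ).to_csv(dest, sep="\t", index=False)
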