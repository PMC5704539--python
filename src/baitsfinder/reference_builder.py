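"""Build the non-redundant single-copy gene (SCG) reference database.

The reference is assembled from a primary species (well annotated, close
to the focal group) and optionally a secondary species (more distant but
better annotated), each screened against a known SCG protein compilation:

1. keep genes with *exactly one* threshold-passing match in the SCG set;
2. all-vs-all comparison within a species removes every gene with a
   non-self match (both members of a similar pair go — either could hide
   a paralog);
3. secondary-species genes are merged in only when they have no match
   against any retained primary gene, avoiding locus redundancy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from . import homology
from .cos_filter import FilterThresholds
from .homology import BLASTX_LIKE, GAPPED, HomologyHit, ScoringParams, SearchMode
from .records import NUCLEOTIDE, PROTEIN, SequenceRecord, translate

PRIMARY = "primary"
SECONDARY = "secondary"


@dataclass(frozen=True)
class ReferenceGene:
    """One candidate reference gene: protein + CDS + exon model."""

    gene_id: str
    protein: SequenceRecord
    cds: SequenceRecord
    species_role: str = PRIMARY
    #: CDS-coordinate intervals, 1-based inclusive, tiling [1, len(cds)]
    exon_model: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.protein.kind != PROTEIN or self.cds.kind != NUCLEOTIDE:
            raise ValueError(f"gene {self.gene_id}: protein/cds kinds are swapped")
        if self.protein.id != self.gene_id or self.cds.id != self.gene_id:
            raise ValueError(
                f"gene {self.gene_id}: protein and CDS records must carry the gene id"
            )
        aa = len(self.cds) // 3
        if abs(aa - len(self.protein)) > 1:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {len(self.cds)} inconsistent "
                f"with protein length {len(self.protein)}"
            )
        if self.exon_model:
            pos = 1
            for start, end in self.exon_model:
                if start != pos or end < start:
                    raise ValueError(
                        f"gene {self.gene_id}: exon model does not tile [1, len(cds)]"
                    )
                pos = end + 1
            if pos != len(self.cds) + 1:
                raise ValueError(
                    f"gene {self.gene_id}: exon model does not cover the CDS"
                )

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.exon_model)


def _passing(hit: HomologyHit, thresholds: FilterThresholds) -> bool:
    return (
        hit.pct_identity >= thresholds.min_identity
        and hit.evalue <= thresholds.max_evalue
        and hit.aln_length >= thresholds.min_aln_len
    )


def find_single_match_genes(
    proteome: Sequence[ReferenceGene],
    scg_db: Sequence[SequenceRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    scoring: ScoringParams = ScoringParams(),
) -> list[ReferenceGene]:
    """Genes whose CDS matches exactly one SCG-database protein.

    A blastx-like search of each gene's CDS against the SCG protein set;
    a gene survives iff its set of distinct threshold-passing subjects
    has cardinality one ("sufficiently high similarity, but only a single
    match").
    """
    if not proteome:
        return []
    hits = homology.search(
        [g.cds for g in proteome], list(scg_db), SearchMode(GAPPED, BLASTX_LIKE), scoring
    )
    matched: dict[str, set[str]] = {}
    for h in hits:
        if _passing(h, thresholds):
            matched.setdefault(h.query_id, set()).add(h.subject_id)
    return [g for g in proteome if len(matched.get(g.cds.id, ())) == 1]


def self_dedup(
    candidates: Sequence[ReferenceGene],
    thresholds: FilterThresholds = FilterThresholds(),
    scoring: ScoringParams = ScoringParams(),
) -> list[ReferenceGene]:
    """All-vs-all screen within one species; any gene with a
    threshold-passing non-self hit is dropped (both members of a pair)."""
    if not candidates:
        return []
    hits = homology.search(
        [g.cds for g in candidates],
        [g.protein for g in candidates],
        SearchMode(GAPPED, BLASTX_LIKE),
        scoring,
    )
    flagged = {
        h.query_id
        for h in hits
        if h.query_id != h.subject_id and _passing(h, thresholds)
    } | {
        h.subject_id
        for h in hits
        if h.query_id != h.subject_id and _passing(h, thresholds)
    }
    return [g for g in candidates if g.gene_id not in flagged]


def merge_references(
    primary: Sequence[ReferenceGene],
    secondary: Sequence[ReferenceGene],
    thresholds: FilterThresholds = FilterThresholds(),
    scoring: ScoringParams = ScoringParams(),
) -> list[ReferenceGene]:
    """Union of all primary genes plus secondary genes with no
    threshold-passing hit against any primary gene."""
    collisions = {g.gene_id for g in primary} & {g.gene_id for g in secondary}
    if collisions:
        raise ValueError(
            f"gene_id collision across species (namespace the ids): {sorted(collisions)}"
        )
    merged = [replace(g, species_role=PRIMARY) for g in primary]
    if not secondary:
        return merged
    if primary:
        hits = homology.search(
            [g.cds for g in secondary],
            [g.protein for g in primary],
            SearchMode(GAPPED, BLASTX_LIKE),
            scoring,
        )
        redundant = {h.query_id for h in hits if _passing(h, thresholds)}
    else:
        redundant = set()
    merged.extend(
        replace(g, species_role=SECONDARY)
        for g in secondary
        if g.gene_id not in redundant
    )
    return merged


def build_reference(
    primary: Sequence[ReferenceGene],
    scg_db: Sequence[SequenceRecord],
    secondary: Sequence[ReferenceGene] = (),
    thresholds: FilterThresholds = FilterThresholds(),
    scoring: ScoringParams = ScoringParams(),
) -> list[ReferenceGene]:
    """Full reference build: single-match screen, self-dedup, merge."""
    kept_primary = self_dedup(
        find_single_match_genes(primary, scg_db, thresholds, scoring), thresholds, scoring
    )
    kept_secondary = (
        self_dedup(
            find_single_match_genes(secondary, scg_db, thresholds, scoring),
            thresholds,
            scoring,
        )
        if secondary
        else []
    )
    return merge_references(kept_primary, kept_secondary, thresholds, scoring)


def write_reference(genes: Sequence[ReferenceGene], out_dir: Union[str, Path]) -> None:
    """Write the merged reference: protein + CDS FASTA and a TSV manifest."""
    from .records import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([g.protein for g in genes], out / "reference_proteins.fa")
    write_fasta([g.cds for g in genes], out / "reference_cds.fa")
    with open(out / "reference_manifest.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "species_role", "cds_length", "exon_count"])
        for g in genes:
            w.writerow([g.gene_id, g.species_role, len(g.cds), len(g.exon_model)])
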