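"""Project reference exon boundaries through locus alignments.

Focal-species exon-intron structure is unknown, so the pipeline assumes
gene structure similar to the reference species and splits each locus
alignment at the reference gene's exon boundaries, read from its GFF3
gene model. Boundaries are taken from CDS features (the aligned
sequences are CDS, so UTR-bearing ``exon`` features would misalign);
when a gene has several mRNAs the longest CDS is used. Exon slices are
degapped per taxon and sequences shorter than the bait length (120 bp)
are dropped individually.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import gffutils

from .locus_assembly import GAP, AlignedRow, LocusBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """Ordered CDS-segment lengths of one gene, in transcript orientation."""

    gene_id: str
    exon_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exon_lengths or any(l < 1 for l in self.exon_lengths):
            raise ValueError(f"gene {self.gene_id}: exon lengths must be >= 1")

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)


@dataclass(frozen=True)
class ExonBlock:
    """A degapped per-taxon slice of a locus, one reference exon wide.

    ``sequences`` holds (member_id, taxon, degapped_sequence) triples;
    ``ref_interval`` is 0-based half-open in reference CDS coordinates.
    """

    ref_gene_id: str
    exon_index: int  # 1-based
    sequences: tuple[tuple[str, str, str], ...]
    ref_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if any(GAP in seq for _, _, seq in self.sequences):
            raise ValueError("ExonBlock sequences must be gap-free")


class GeneModelError(ValueError):
    pass


def parse_gff3_gene_models(
    gff3: Union[str, Path],
    cds_lengths: Optional[Mapping[str, int]] = None,
) -> dict[str, GeneModel]:
    """Read per-gene transcript-space exon lengths from GFF3.

    CDS segments of the chosen mRNA (the one with the longest summed CDS)
    are ordered 5'->3' in transcript orientation: ascending genomic start
    for plus-strand genes, descending for minus-strand genes. Genes
    without CDS features are skipped with a warning. When *cds_lengths*
    provides an expected length, a mismatching model raises
    :class:`GeneModelError`.
    """
    source = str(gff3)
    if "\n" not in source:
        if not Path(source).exists():
            raise FileNotFoundError(source)
        source = Path(source).read_text()
    db = gffutils.create_db(
        source, ":memory:", from_string=True, merge_strategy="create_unique"
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best: Optional[list] = None
        mrnas = list(db.children(gene, featuretype=("mRNA", "transcript")))
        parents = mrnas if mrnas else [gene]
        for parent in parents:
            segs = sorted(
                db.children(parent, featuretype="CDS"), key=lambda f: f.start
            )
            if not segs:
                continue
            if best is None or sum(s.end - s.start + 1 for s in segs) > sum(
                s.end - s.start + 1 for s in best
            ):
                best = segs
        if best is None:
            warnings.warn(f"gene {gene.id}: no CDS features, skipped")
            continue
        if gene.strand == "-":
            best = list(reversed(best))
        lengths = tuple(s.end - s.start + 1 for s in best)
        model = GeneModel(gene.id, lengths)
        if cds_lengths is not None and gene.id in cds_lengths:
            if model.cds_length != cds_lengths[gene.id]:
                raise GeneModelError(
                    f"gene {gene.id}: GFF3 CDS length {model.cds_length} != "
                    f"expected {cds_lengths[gene.id]}"
                )
        models[gene.id] = model
    return models


def project_boundaries(
    alignment: Sequence[AlignedRow], model: GeneModel
) -> list[int]:
    """Map cumulative exon ends to alignment columns via the reference row.

    Returns, per exon, the column index just after the last reference
    residue of that exon (so the final breakpoint for the last exon ends
    at the last reference residue; trailing member-only columns are folded
    into the last exon slice by callers using the alignment width).
    """
    ref_row = _reference_row(alignment)
    ref_len = len(ref_row.degapped())
    if ref_len != model.cds_length:
        raise GeneModelError(
            f"gene {model.gene_id}: model length {model.cds_length} != "
            f"reference row length {ref_len}"
        )
    ends = set()
    acc = 0
    for l in model.exon_lengths:
        acc += l
        ends.add(acc)
    breakpoints = []
    count = 0
    for col, char in enumerate(ref_row.residues):
        if char != GAP:
            count += 1
            if count in ends:
                breakpoints.append(col + 1)
    # the last exon absorbs any trailing insertion columns
    breakpoints[-1] = len(ref_row.residues)
    return breakpoints


def _reference_row(alignment: Sequence[AlignedRow]) -> AlignedRow:
    for row in alignment:
        if row.is_reference:
            return row
    raise ValueError("alignment has no reference row")


def split_and_degap(
    bundle: LocusBundle,
    breakpoints: Sequence[int],
    model: GeneModel,
    min_len: int = 120,
) -> list[ExonBlock]:
    """Slice the alignment at exon breakpoints and degap per taxon.

    Sequences shorter than *min_len* after degapping are dropped
    individually (per member per exon); slices where every member is
    empty or short yield no block.
    """
    alignment = bundle.alignment
    if alignment is None:
        raise ValueError(f"bundle {bundle.ref_gene_id} is not aligned")
    if list(breakpoints) != sorted(breakpoints) or breakpoints[-1] != len(
        alignment[0].residues
    ):
        raise ValueError("breakpoints must ascend and end at the alignment width")
    blocks = []
    col_start = 0
    ref_pos = 0
    for idx, col_end in enumerate(breakpoints, start=1):
        exon_len = model.exon_lengths[idx - 1]
        seqs = []
        for row in alignment:
            if row.is_reference:
                continue
            piece = row.residues[col_start:col_end].replace(GAP, "")
            if len(piece) >= min_len:
                seqs.append((row.seq_id, row.taxon, piece))
        if seqs:
            blocks.append(
                ExonBlock(
                    ref_gene_id=bundle.ref_gene_id,
                    exon_index=idx,
                    sequences=tuple(seqs),
                    ref_interval=(ref_pos, ref_pos + exon_len),
                )
            )
        ref_pos += exon_len
        col_start = col_end
    return blocks


def project_locus(
    bundle: LocusBundle, model: GeneModel, min_len: int = 120
) -> list[ExonBlock]:
    """Convenience: project boundaries then split and degap."""
    return split_and_degap(
        bundle, project_boundaries(bundle.alignment, model), model, min_len
    )
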