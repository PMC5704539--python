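"""Self-contained toy datasets with the structure the pipeline assumes.

The generator emulates the shape of the real inputs — a two-species-style
reference proteome with GFF3 gene models, a known-SCG protein compilation,
and fragmented, unstranded focal transcriptomes of heterogeneous quality —
at desk scale, with planted truth:

* ``n_scg`` true single-copy genes, each echoed (slightly diverged) in the
  SCG database;
* ``n_paralog_pairs`` duplicated gene pairs (intra-pair divergence ~5%)
  that must die in the reference self-deduplication;
* host contaminants: the "host" gene set consists of ~10%-diverged copies
  of reference genes (host plants are plants too, so their conserved
  transcripts do hit the reference), and contaminant unigenes are <=2%
  diverged near-copies of those host genes;
* plastid transcripts copied from a toy plastid genome, plus the genome
  itself as the organelle screening database;
* per-taxon substitution divergence, codon-sized indels (to exercise
  gapped vs. ungapped search) and fragmentation (which controls N50);
  unigenes are emitted on a random strand.

Every unigene is recorded in a truth table with its class
(ortholog/paralog/host/plastid) and source gene. Outputs are functions of
the seed alone: the same configuration yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bait_designer import Bait, TilingParams, tile_starts
from .records import (
    NUCLEOTIDE,
    PROTEIN,
    SequenceRecord,
    reverse_complement,
    translate,
    write_fasta,
)
from .reference_builder import PRIMARY, ReferenceGene

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the toy data generator (see module docstring)."""

    seed: int = 0
    n_scg: int = 50
    n_paralog_pairs: int = 5
    taxa: tuple[str, ...] = ("LiPh", "TrVe", "StHe", "OrAe")
    anchor: str = "LiPh"
    exon_length_range: tuple[int, int] = (120, 600)
    exons_per_gene_range: tuple[int, int] = (1, 4)
    #: per-taxon substitution probability per site
    divergence: dict[str, float] = field(
        default_factory=lambda: {"LiPh": 0.02, "TrVe": 0.05, "StHe": 0.05, "OrAe": 0.06}
    )
    #: per-taxon indel probability per site (indels are codon multiples)
    indel_rate: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in ("LiPh", "TrVe", "StHe", "OrAe")}
    )
    #: per-taxon unigene fragment length range; None = full-length
    fragmentation: dict[str, Optional[tuple[int, int]]] = field(
        default_factory=lambda: {
            "LiPh": None,
            "TrVe": (350, 900),
            "StHe": (350, 900),
            "OrAe": (350, 900),
        }
    )
    scg_db_divergence: float = 0.05
    paralog_divergence: float = 0.05
    host_divergence: float = 0.10
    host_contaminant_divergence: float = 0.02
    plastid_genome_length: int = 6000
    plastid_transcript_divergence: float = 0.01
    n_host_contaminants: int = 8
    n_plastid_transcripts: int = 6

    def __post_init__(self) -> None:
        for d in (self.divergence, self.indel_rate):
            if any(not (0.0 <= v <= 1.0) for v in d.values()):
                raise ValueError("rates must lie in [0, 1]")
        if self.n_scg < 0 or self.n_paralog_pairs < 0:
            raise ValueError("counts must be non-negative")
        if self.anchor not in self.taxa:
            raise ValueError(f"anchor {self.anchor!r} not among taxa {self.taxa}")


@dataclass
class SimulatedReference:
    """Reference side of a simulated study."""

    genes: list[ReferenceGene]  # all candidates incl. paralog duplicates
    scg_db: list[SequenceRecord]
    gff3: str
    scg_ids: list[str]  # planted true single-copy genes
    paralog_ids: list[str]  # members of planted duplicated pairs
    host_db: list[SequenceRecord]
    plastid_genome: SequenceRecord


@dataclass
class SimulatedStudy:
    reference: SimulatedReference
    transcriptomes: dict[str, list[SequenceRecord]]
    truth: pd.DataFrame  # unigene_id, taxon, label, source_gene, strand


# ---------------------------------------------------------------------------
# low-level mutators


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS, size=n_codons))


def _substitute_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alternatives = [b for b in _BASES if b != arr[i]]
        arr[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(arr)


def _substitute_cds(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitutions that never create an in-frame stop codon (reference
    CDS must translate cleanly)."""
    out = _substitute_nt(rng, seq, rate)
    codons = [out[i : i + 3] for i in range(0, len(out), 3)]
    for i, codon in enumerate(codons):
        if codon in _STOPS:
            codons[i] = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
    return "".join(codons)


def _substitute_aa(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alternatives = [a for a in _AA if a != arr[i]]
        arr[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(arr)


def _plant_indels(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Insert/delete codon-multiple chunks at codon boundaries, keeping
    the reading frame intact downstream."""
    if rate <= 0:
        return seq
    n = rng.poisson(rate * len(seq))
    for _ in range(n):
        size = 3 * int(rng.integers(1, 4))
        pos = 3 * int(rng.integers(0, max(1, len(seq) // 3)))
        if rng.random() < 0.5 and len(seq) > size + 6:
            seq = seq[:pos] + seq[pos + size :]
        else:
            seq = seq[:pos] + _random_cds(rng, size // 3) + seq[pos:]
    return seq


def _exon_layout(
    rng: np.random.Generator, config: SimulationConfig, tiling: TilingParams
) -> list[int]:
    """Sample exon lengths whose gene is recoverable end-to-end: total a
    codon multiple of >= 300 bp and a default-tiling yield of >= 4 baits."""
    lo, hi = config.exon_length_range
    e_lo, e_hi = config.exons_per_gene_range
    while True:
        k = int(rng.integers(e_lo, e_hi + 1))
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(k)]
        rem = sum(lengths) % 3
        if rem:
            lengths[int(np.argmax(lengths))] -= rem
        if sum(lengths) < 300:
            continue
        yield_ = sum(len(tile_starts(l, tiling)) for l in lengths if l >= tiling.bait_len)
        if yield_ >= 4:
            return lengths


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(config: SimulationConfig) -> SimulatedReference:
    rng = np.random.default_rng(config.seed)
    tiling = TilingParams()
    genes: list[ReferenceGene] = []
    scg_db: list[SequenceRecord] = []
    scg_ids: list[str] = []
    paralog_ids: list[str] = []
    gff_rows: list[str] = []
    cursor = 1  # genomic coordinate cursor on the toy chromosome

    def add_gene(gene_id: str, cds: str, exon_lengths: Sequence[int], strand: str):
        nonlocal cursor
        protein = translate(cds)
        genes.append(
            ReferenceGene(
                gene_id=gene_id,
                protein=SequenceRecord(gene_id, protein, PROTEIN),
                cds=SequenceRecord(gene_id, cds, NUCLEOTIDE),
                species_role=PRIMARY,
                exon_model=_intervals(exon_lengths),
            )
        )
        # genomic CDS segments with 100-bp introns; minus-strand genes have
        # their transcript-order first exon at the genomic 3' end
        genomic = list(exon_lengths) if strand == "+" else list(reversed(exon_lengths))
        start = cursor
        segs = []
        for L in genomic:
            segs.append((cursor, cursor + L - 1))
            cursor += L + 100
        end = segs[-1][1]
        cursor = end + 200
        gff_rows.append(
            f"chr1\ttoysim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}"
        )
        gff_rows.append(
            f"chr1\ttoysim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={gene_id}.1;Parent={gene_id}"
        )
        for i, (s, e) in enumerate(segs, 1):
            gff_rows.append(
                f"chr1\ttoysim\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                f"ID={gene_id}.1.cds{i};Parent={gene_id}.1"
            )

    for i in range(config.n_scg):
        gid = f"Eg_g{i + 1:03d}"
        lengths = _exon_layout(rng, config, tiling)
        cds = _random_cds(rng, sum(lengths) // 3)
        strand = "+" if rng.random() < 0.5 else "-"
        add_gene(gid, cds, lengths, strand)
        scg_ids.append(gid)
        scg_db.append(
            SequenceRecord(
                f"At_g{i + 1:03d}",
                _substitute_aa(rng, translate(cds), config.scg_db_divergence),
                PROTEIN,
            )
        )

    for i in range(config.n_paralog_pairs):
        lengths = _exon_layout(rng, config, tiling)
        ancestor = _random_cds(rng, sum(lengths) // 3)
        for copy in "ab":
            gid = f"Eg_p{i + 1:03d}{copy}"
            cds = _substitute_cds(rng, ancestor, config.paralog_divergence / 2)
            strand = "+" if rng.random() < 0.5 else "-"
            add_gene(gid, cds, lengths, strand)
            paralog_ids.append(gid)
        scg_db.append(
            SequenceRecord(
                f"At_p{i + 1:03d}",
                _substitute_aa(rng, translate(ancestor), config.scg_db_divergence),
                PROTEIN,
            )
        )

    # host genes: diverged copies of a subset of the true SCGs
    host_db = []
    n_host_genes = min(config.n_host_contaminants, config.n_scg)
    for i in range(n_host_genes):
        src = genes[i]  # the i-th true SCG
        host_db.append(
            SequenceRecord(
                f"host_g{i + 1:03d}",
                _substitute_nt(rng, src.cds.residues, config.host_divergence),
                NUCLEOTIDE,
            )
        )

    plastid = SequenceRecord(
        "toy_plastid",
        "".join(rng.choice(list(_BASES), size=config.plastid_genome_length)),
        NUCLEOTIDE,
    )
    gff3 = "##gff-version 3\n" + "\n".join(gff_rows) + "\n"
    return SimulatedReference(
        genes=genes,
        scg_db=scg_db,
        gff3=gff3,
        scg_ids=scg_ids,
        paralog_ids=paralog_ids,
        host_db=host_db,
        plastid_genome=plastid,
    )


def _intervals(lengths: Sequence[int]) -> tuple[tuple[int, int], ...]:
    out = []
    pos = 1
    for L in lengths:
        out.append((pos, pos + L - 1))
        pos += L
    return tuple(out)


# ---------------------------------------------------------------------------
# focal transcriptomes


def generate_focal_transcriptomes(
    config: SimulationConfig, reference: SimulatedReference
) -> SimulatedStudy:
    rng = np.random.default_rng(config.seed + 1)
    transcriptomes: dict[str, list[SequenceRecord]] = {t: [] for t in config.taxa}
    truth_rows = []

    def emit(taxon: str, base_id: str, seq: str, label: str, source: str):
        strand = "+" if rng.random() < 0.5 else "-"
        out = seq if strand == "+" else reverse_complement(seq)
        uid = f"{taxon}_{base_id}"
        transcriptomes[taxon].append(SequenceRecord(uid, out, NUCLEOTIDE, taxon))
        truth_rows.append(
            {
                "unigene_id": uid,
                "taxon": taxon,
                "label": label,
                "source_gene": source,
                "strand": strand,
            }
        )

    gene_by_id = {g.gene_id: g for g in reference.genes}
    for taxon in config.taxa:
        div = config.divergence.get(taxon, 0.0)
        indel = config.indel_rate.get(taxon, 0.0)
        frag = config.fragmentation.get(taxon)
        for gid in reference.scg_ids + reference.paralog_ids:
            label = "ortholog" if gid in set(reference.scg_ids) else "paralog"
            seq = gene_by_id[gid].cds.residues
            seq = _substitute_nt(rng, seq, div)
            seq = _plant_indels(rng, seq, indel)
            if frag is None:
                emit(taxon, f"{gid}_u1", seq, label, gid)
            else:
                for j, piece in enumerate(_fragment(rng, seq, frag), 1):
                    emit(taxon, f"{gid}_u{j}", piece, label, gid)

    # contaminants go into the non-anchor taxa (parasite builds)
    sinks = [t for t in config.taxa if t != config.anchor] or list(config.taxa)
    for i in range(min(config.n_host_contaminants, len(reference.host_db))):
        host_gene = reference.host_db[i]
        taxon = sinks[i % len(sinks)]
        seq = _substitute_nt(
            rng, host_gene.residues, config.host_contaminant_divergence
        )
        emit(taxon, f"host{i + 1:03d}", seq, "host", host_gene.id)

    genome = reference.plastid_genome.residues
    for i in range(config.n_plastid_transcripts):
        taxon = config.taxa[i % len(config.taxa)]
        length = int(rng.integers(400, 1200))
        start = int(rng.integers(0, max(1, len(genome) - length)))
        seq = _substitute_nt(
            rng, genome[start : start + length], config.plastid_transcript_divergence
        )
        emit(taxon, f"pt{i + 1:03d}", seq, "plastid", reference.plastid_genome.id)

    truth = pd.DataFrame(
        truth_rows, columns=["unigene_id", "taxon", "label", "source_gene", "strand"]
    )
    return SimulatedStudy(reference=reference, transcriptomes=transcriptomes, truth=truth)


def _fragment(
    rng: np.random.Generator, seq: str, length_range: tuple[int, int]
) -> list[str]:
    """Chop a CDS into non-overlapping codon-aligned fragments."""
    lo, hi = length_range
    pieces = []
    pos = 0
    while pos < len(seq):
        want = int(rng.integers(lo, hi + 1))
        want -= want % 3
        piece = seq[pos : pos + want]
        if len(piece) < 60:  # absorb tiny tails into the previous fragment
            if pieces:
                pieces[-1] += piece
            else:
                pieces.append(piece)
        else:
            pieces.append(piece)
        pos += want
    return [p for p in pieces if p]


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Reference plus focal transcriptomes plus truth table."""
    return generate_focal_transcriptomes(config, generate_reference(config))


def write_study(study: SimulatedStudy, out_dir: Union[str, Path]) -> None:
    """Write the simulated study as FASTA/GFF3/TSV fixture files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = study.reference
    write_fasta([g.protein for g in ref.genes], out / "reference_proteins.fa")
    write_fasta([g.cds for g in ref.genes], out / "reference_cds.fa")
    (out / "reference.gff3").write_text(ref.gff3)
    write_fasta(ref.scg_db, out / "scg_db.fa")
    if ref.host_db:
        write_fasta(ref.host_db, out / "host_db.fa")
    write_fasta([ref.plastid_genome], out / "plastid.fa")
    for taxon, records in study.transcriptomes.items():
        write_fasta(records, out / f"transcriptome_{taxon}.fa")
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
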