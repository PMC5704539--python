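"""End-to-end orchestration: reference build to bait FASTA.

The stages mirror the workflow the individual modules implement:

1. reference build (or load a prebuilt reference)
2. homology search of every focal transcriptome against the reference
3. best-hit threshold filter (COS assignment)
4. host-contaminant screen (optional)
5. paralog overlap removal
6. bundling by reference gene
7. anchor-taxon locus filter (optional)
8. per-locus alignment (reference CDS as anchor row)
9. exon projection and length filtering
10. bait design (tiling, minimum-yield filter, redundancy clustering,
    organelle screen)

Each stage contributes a report row with input/output counts; optional
stages that are turned off appear as ``skipped``. The run is fully
deterministic: rerunning an identical configuration yields identical
baits and report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import bait_designer, cos_filter, exon_projection, homology, locus_assembly
from . import reference_builder
from .bait_designer import Bait, TilingParams
from .cos_filter import CosAssignment, FilterThresholds
from .exon_projection import ExonBlock, GeneModel, parse_gff3_gene_models
from .homology import BLASTX_LIKE, GAPPED, ScoringParams, SearchMode
from .locus_assembly import INTERNAL, LocusBundle
from .records import NUCLEOTIDE, PROTEIN, SequenceRecord, as_mapping, read_fasta
from .reference_builder import ReferenceGene

logger = logging.getLogger(__name__)


@dataclass
class StageRow:
    stage: str
    input_count: int
    output_count: int
    skipped: bool = False
    detail: str = ""


@dataclass
class PipelineSettings:
    """All tunables of a run; every optional screen can be disabled."""

    search_mode: SearchMode = field(default_factory=SearchMode)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    host_min_identity: float = 95.0
    paralog_overlap: int = 30
    anchor: Optional[str] = None
    aligner: str = INTERNAL
    min_exon: int = 120
    tiling: TilingParams = field(default_factory=TilingParams)
    min_baits: int = 4
    cluster_identity: float = 90.0
    organelle_identity: float = 90.0


@dataclass
class PipelineResult:
    report: list[StageRow]
    reference: list[ReferenceGene]
    assignments: list[CosAssignment]
    bundles: list[LocusBundle]
    blocks: list[ExonBlock]
    baits: list[Bait]

    @property
    def recovered_loci(self) -> set[str]:
        return {b.ref_gene_id for b in self.baits}

    @property
    def mean_assigned_length(self) -> float:
        """Average recovered SCG length: mean unigene length over the
        surviving assignments."""
        if not self.assignments:
            return 0.0
        return sum(len(a.unigene) for a in self.assignments) / len(self.assignments)

    @property
    def mean_locus_length(self) -> float:
        """Average recovered locus length in bp: per locus in the final
        bait set, the longest matched region (hit query span) among its
        assignments — ungapped search recovers shorter matched regions,
        so this statistic tracks the search mode."""
        lens: dict[str, int] = {}
        recovered = self.recovered_loci
        for a in self.assignments:
            if a.ref_gene_id in recovered:
                span = abs(a.hit.q_end - a.hit.q_start) + 1
                lens[a.ref_gene_id] = max(lens.get(a.ref_gene_id, 0), span)
        if not lens:
            return 0.0
        return sum(lens.values()) / len(lens)

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.report])


def run_pipeline(
    transcriptomes: dict[str, Sequence[SequenceRecord]],
    settings: PipelineSettings,
    *,
    reference: Optional[Sequence[ReferenceGene]] = None,
    primary: Sequence[ReferenceGene] = (),
    secondary: Sequence[ReferenceGene] = (),
    scg_db: Sequence[SequenceRecord] = (),
    gene_models: Optional[dict[str, GeneModel]] = None,
    gff3: Optional[Union[str, Path]] = None,
    host_db: Sequence[SequenceRecord] = (),
    organelle_db: Sequence[SequenceRecord] = (),
) -> PipelineResult:
    """Run the full workflow on in-memory inputs.

    Provide either a prebuilt *reference* or the build inputs (*primary*,
    optional *secondary*, *scg_db*); exon models come from *gene_models*
    or are parsed from *gff3*.
    """
    report: list[StageRow] = []

    # 1. reference
    if reference is None:
        reference = reference_builder.build_reference(
            primary, scg_db, secondary, settings.thresholds, settings.scoring
        )
        report.append(
            StageRow(
                "reference_build",
                len(primary) + len(secondary),
                len(reference),
                detail=f"scg_db={len(scg_db)}",
            )
        )
    else:
        reference = list(reference)
        report.append(
            StageRow("reference_build", len(reference), len(reference), skipped=True,
                     detail="prebuilt reference loaded")
        )
    ref_proteins = [g.protein for g in reference]
    ref_cds = {g.gene_id: g.cds for g in reference}

    if gene_models is None:
        if gff3 is None:
            gene_models = {
                g.gene_id: GeneModel(g.gene_id, g.exon_lengths)
                for g in reference
                if g.exon_model
            }
        else:
            gene_models = parse_gff3_gene_models(
                gff3, {g.gene_id: len(g.cds) for g in reference}
            )

    # 2. search + 3. best-hit filter, per taxon
    n_unigenes = sum(len(v) for v in transcriptomes.values())
    all_hits = 0
    assignments: list[CosAssignment] = []
    for taxon in sorted(transcriptomes):
        records = list(transcriptomes[taxon])
        hits = homology.search(records, ref_proteins, settings.search_mode, settings.scoring)
        all_hits += len(hits)
        assignments.extend(
            cos_filter.best_hit_per_query(
                hits, settings.thresholds, as_mapping(records), taxon
            )
        )
    report.append(StageRow("search", n_unigenes, all_hits,
                           detail=f"mode={settings.search_mode.mode}"))
    report.append(StageRow("threshold_filter", n_unigenes, len(assignments)))

    # 4. host screen
    if host_db:
        before = len(assignments)
        assignments = cos_filter.remove_host_like(
            assignments, list(host_db), settings.host_min_identity, settings.scoring
        )
        report.append(StageRow("host_removal", before, len(assignments)))
    else:
        report.append(
            StageRow("host_removal", len(assignments), len(assignments), skipped=True)
        )

    # 5. paralog removal
    before = len(assignments)
    assignments = cos_filter.remove_paralogs(assignments, settings.paralog_overlap)
    report.append(StageRow("paralog_removal", before, len(assignments)))

    # 6. bundling
    bundles = locus_assembly.bundle_by_reference(assignments)
    report.append(StageRow("bundling", len(assignments), len(bundles)))

    # 7. anchor filter
    if settings.anchor is not None:
        before = len(bundles)
        bundles = locus_assembly.require_anchor_taxon(
            bundles, settings.anchor, set(transcriptomes)
        )
        report.append(StageRow("anchor_filter", before, len(bundles)))
    else:
        report.append(StageRow("anchor_filter", len(bundles), len(bundles), skipped=True))

    # 8. alignment
    aligned = [
        locus_assembly.align_locus(
            b, ref_cds[b.ref_gene_id], settings.aligner, settings.scoring
        )
        for b in bundles
    ]
    report.append(StageRow("alignment", len(bundles), len(aligned)))

    # 9. exon projection
    blocks: list[ExonBlock] = []
    for b in aligned:
        model = gene_models.get(b.ref_gene_id)
        if model is None:
            raise KeyError(f"no gene model for reference gene {b.ref_gene_id}")
        blocks.extend(exon_projection.project_locus(b, model, settings.min_exon))
    report.append(StageRow("exon_projection", len(aligned), len(blocks),
                           detail="exon blocks"))

    # 10. bait design
    baits = bait_designer.design_baits(blocks, settings.tiling)
    tiled = len(baits)
    _, baits = bait_designer.filter_low_yield_loci(
        baits, settings.anchor, settings.min_baits
    )
    after_yield = len(baits)
    baits = bait_designer.cluster_redundant(baits, settings.cluster_identity)
    after_cluster = len(baits)
    if organelle_db:
        baits = bait_designer.drop_organelle_loci(
            baits, list(organelle_db), settings.organelle_identity, settings.scoring
        )
        org_note = f"organelle screen kept {len(baits)}"
    else:
        org_note = "organelle screen skipped"
    report.append(
        StageRow(
            "bait_design",
            tiled,
            len(baits),
            detail=(
                f"tiled={tiled} yield_filtered={after_yield} "
                f"clustered={after_cluster}; {org_note}"
            ),
        )
    )
    result = PipelineResult(
        report=report,
        reference=list(reference),
        assignments=assignments,
        bundles=aligned,
        blocks=blocks,
        baits=baits,
    )
    for row in report:
        logger.info(
            "%-16s in=%-6d out=%-6d %s%s",
            row.stage, row.input_count, row.output_count,
            "(skipped) " if row.skipped else "", row.detail,
        )
    return result


# ---------------------------------------------------------------------------
# file-based configuration (CLI `run`)


@dataclass
class PipelineConfig:
    """Flat, YAML-compatible description of a run (all values are paths
    or scalars; every CLI flag overrides its key)."""

    out_dir: str
    transcriptomes: dict[str, str] = field(default_factory=dict)  # taxon -> FASTA
    primary_proteins: Optional[str] = None
    primary_cds: Optional[str] = None
    primary_gff: Optional[str] = None
    secondary_proteins: Optional[str] = None
    secondary_cds: Optional[str] = None
    secondary_gff: Optional[str] = None
    scg_db: Optional[str] = None
    host_db: Optional[str] = None
    organelle_db: Optional[str] = None
    search_mode: str = "gapped"
    min_identity: float = 40.0
    max_evalue: float = 1e-20
    min_aln_len: int = 100
    host_min_identity: float = 95.0
    paralog_overlap: int = 30
    anchor: Optional[str] = None
    aligner: str = INTERNAL
    min_exon: int = 120
    bait_len: int = 120
    step: int = 60
    max_bait_overlap: int = 80
    min_baits: int = 4
    cluster_identity: float = 90.0
    organelle_identity: float = 90.0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def settings(self) -> PipelineSettings:
        return PipelineSettings(
            search_mode=SearchMode(self.search_mode, BLASTX_LIKE),
            thresholds=FilterThresholds(
                self.min_identity, self.max_evalue, self.min_aln_len
            ),
            host_min_identity=self.host_min_identity,
            paralog_overlap=self.paralog_overlap,
            anchor=self.anchor,
            aligner=self.aligner,
            min_exon=self.min_exon,
            tiling=TilingParams(self.bait_len, self.step, self.max_bait_overlap),
            min_baits=self.min_baits,
            cluster_identity=self.cluster_identity,
            organelle_identity=self.organelle_identity,
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Aggregate all configuration problems (not fail-fast)."""
    errors: list[str] = []
    if not config.transcriptomes:
        errors.append("transcriptomes: at least one taxon FASTA is required")
    for taxon, path in config.transcriptomes.items():
        if not Path(path).exists():
            errors.append(f"transcriptomes[{taxon}]: missing file {path}")
    needed = ("primary_proteins", "primary_cds", "primary_gff", "scg_db")
    for name in needed:
        value = getattr(config, name)
        if value is None:
            errors.append(f"{name}: required (no prebuilt reference support in config)")
        elif not Path(value).exists():
            errors.append(f"{name}: missing file {value}")
    for name in ("secondary_proteins", "secondary_cds", "secondary_gff",
                 "host_db", "organelle_db"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            errors.append(f"{name}: missing file {value}")
    if config.search_mode not in ("gapped", "ungapped"):
        errors.append(f"search_mode: unknown value {config.search_mode!r}")
    if config.anchor is not None and config.anchor not in config.transcriptomes:
        errors.append(f"anchor: taxon {config.anchor!r} has no transcriptome")
    if not (0 < config.cluster_identity <= 100):
        errors.append("cluster_identity: must be in (0, 100]")
    if not (0 < config.organelle_identity <= 100):
        errors.append("organelle_identity: must be in (0, 100]")
    if config.paralog_overlap < 0:
        errors.append("paralog_overlap: must be non-negative")
    try:
        config.settings()
    except ValueError as exc:
        errors.append(str(exc))
    return errors


def _load_reference_species(
    proteins_path: str, cds_path: str, role: str
) -> list[ReferenceGene]:
    proteins = as_mapping(read_fasta(proteins_path, kind=PROTEIN))
    cds = as_mapping(read_fasta(cds_path, kind=NUCLEOTIDE))
    missing = set(proteins) ^ set(cds)
    if missing:
        raise ValueError(f"protein/CDS id mismatch for ids {sorted(missing)[:5]}")
    return [
        ReferenceGene(gid, proteins[gid], cds[gid], species_role=role)
        for gid in sorted(proteins)
    ]


def run_from_config(config: PipelineConfig) -> PipelineResult:
    """Load all configured files, run the pipeline, write outputs."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    primary = _load_reference_species(
        config.primary_proteins, config.primary_cds, reference_builder.PRIMARY
    )
    secondary = (
        _load_reference_species(
            config.secondary_proteins, config.secondary_cds, reference_builder.SECONDARY
        )
        if config.secondary_proteins
        else []
    )
    scg_db = read_fasta(config.scg_db, kind=PROTEIN)
    transcriptomes = {
        taxon: read_fasta(path, kind=NUCLEOTIDE, taxon=taxon)
        for taxon, path in config.transcriptomes.items()
    }
    host_db = read_fasta(config.host_db, kind=NUCLEOTIDE) if config.host_db else []
    organelle_db = (
        read_fasta(config.organelle_db, kind=NUCLEOTIDE) if config.organelle_db else []
    )
    gene_models = parse_gff3_gene_models(config.primary_gff)
    if config.secondary_gff:
        gene_models.update(parse_gff3_gene_models(config.secondary_gff))
    result = run_pipeline(
        transcriptomes,
        config.settings(),
        primary=primary,
        secondary=secondary,
        scg_db=scg_db,
        gene_models=gene_models,
        host_db=host_db,
        organelle_db=organelle_db,
    )
    write_outputs(result, config.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: Union[str, Path]) -> None:
    from .records import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bait_designer.bait_fasta_records(result.baits), out / "baits.fa")
    bait_designer.write_bait_manifest(result.baits, out / "baits.tsv")
    result.report_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    summary = {
        "n_loci": len(result.recovered_loci),
        "n_baits": len(result.baits),
        "mean_assigned_length": result.mean_assigned_length,
        "mean_locus_length": result.mean_locus_length,
        "stages": [asdict(r) for r in result.report],
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2) + "\n")
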