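import io
import math
import random
import shutil
import subprocess

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baitsfinder.homology import (
    BLASTN_LIKE,
    BLASTX_LIKE,
    GAPPED,
    UNGAPPED,
    HomologyHit,
    ScoringParams,
    SearchMode,
    TabularParseError,
    parse_tabular_hits,
    search,
    write_tabular_hits,
)
from baitsfinder.records import (
    NUCLEOTIDE,
    PROTEIN,
    SequenceRecord,
    reverse_complement,
    translate,
    write_fasta,
)

from ._oracles import best_ungapped_segment, protein_score, smith_waterman_affine
from .conftest import mutate_nt, random_cds


# ---------------------------------------------------------------------------
# tabular interchange


def test_parse_tabular_basic_line():
    line = "u1\tg1\t45.0\t150\t80\t2\t1\t450\t1\t150\t1e-30\t120"
    (hit,) = parse_tabular_hits([line])
    assert hit.query_id == "u1"
    assert hit.subject_id == "g1"
    assert hit.pct_identity == 45.0
    assert hit.aln_length == 150
    assert hit.evalue == 1e-30
    assert hit.bitscore == 120.0


def test_parse_tabular_empty_and_comments():
    assert parse_tabular_hits([]) == []
    assert parse_tabular_hits(["# comment", "", "  "]) == []


def test_parse_tabular_rejects_short_line():
    with pytest.raises(TabularParseError, match="line 2"):
        parse_tabular_hits(
            [
                "u1\tg1\t45.0\t150\t80\t2\t1\t450\t1\t150\t1e-30\t120",
                "u2\tg1\t45.0\t150\t80\t2\t1\t450\t1\t150\t1e-30",
            ]
        )


hit_strategy = st.builds(
    HomologyHit,
    query_id=st.text(alphabet="abcXYZ09_", min_size=1, max_size=8),
    subject_id=st.text(alphabet="abcXYZ09_", min_size=1, max_size=8),
    pct_identity=st.floats(0, 100, allow_nan=False),
    aln_length=st.integers(1, 10_000),
    mismatches=st.integers(0, 10_000),
    gap_opens=st.integers(0, 100),
    q_start=st.integers(1, 10_000),
    q_end=st.integers(1, 10_000),
    s_start=st.integers(1, 10_000),
    s_end=st.integers(1, 10_000),
    evalue=st.floats(0, 10, allow_nan=False),
    bitscore=st.floats(-100, 1e4, allow_nan=False),
)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(hit_strategy, max_size=10))
def test_tabular_write_parse_round_trip(hits):
    buf = io.StringIO()
    write_tabular_hits(hits, buf)
    assert parse_tabular_hits(buf.getvalue().splitlines()) == hits


# ---------------------------------------------------------------------------
# internal engine vs. exhaustive DP oracles


def _raw_score(hit: HomologyHit, scoring: ScoringParams) -> float:
    """Invert the bitscore transform back to the raw alignment score."""
    return (hit.bitscore * math.log(2) + math.log(scoring.karlin_k)) / scoring.karlin_lambda


def test_self_hit_is_perfect(rng):
    cds = random_cds(rng, 120)
    q = SequenceRecord("q", cds, NUCLEOTIDE)
    s = SequenceRecord("s", translate(cds), PROTEIN)
    for mode in (GAPPED, UNGAPPED):
        (hit,) = search([q], [s], SearchMode(mode, BLASTX_LIKE))
        assert hit.pct_identity == 100.0
        assert hit.aln_length == 120  # translated length
        assert hit.gap_opens == 0
        assert (hit.q_start, hit.q_end) == (1, 360)
        assert (hit.s_start, hit.s_end) == (1, 120)


def test_blastn_self_hit(rng):
    seq = random_cds(rng, 100)
    q = SequenceRecord("q", seq, NUCLEOTIDE)
    s = SequenceRecord("s", seq, NUCLEOTIDE)
    (hit,) = search([q], [s], SearchMode(GAPPED, BLASTN_LIKE))
    assert hit.pct_identity == 100.0
    assert hit.aln_length == len(seq)


def test_reverse_frame_hit_swaps_subject_coords(rng):
    cds = random_cds(rng, 150)
    q = SequenceRecord("q", reverse_complement(cds), NUCLEOTIDE)
    s = SequenceRecord("s", translate(cds), PROTEIN)
    (hit,) = search([q], [s], SearchMode(GAPPED, BLASTX_LIKE))
    assert hit.pct_identity == 100.0
    assert hit.s_start > hit.s_end
    assert hit.is_reverse
    assert hit.q_start < hit.q_end


def test_internal_insertion_gapped_vs_ungapped(rng):
    """A 9-nt internal insertion: the gapped alignment spans both flanks
    with at least one gap open; the ungapped best hit covers one flank
    only, so it is shorter. Scores must match the exhaustive DPs."""
    cds = random_cds(rng, 150)  # 450 nt
    with_ins = cds[:225] + "GGTGGTGGA" + cds[225:]
    q = SequenceRecord("q", with_ins, NUCLEOTIDE)
    s = SequenceRecord("s", translate(cds), PROTEIN)
    scoring = ScoringParams()

    (gapped,) = search([q], [s], SearchMode(GAPPED, BLASTX_LIKE), scoring)
    (ungapped,) = search([q], [s], SearchMode(UNGAPPED, BLASTX_LIKE), scoring)
    assert gapped.gap_opens >= 1
    assert ungapped.gap_opens == 0
    assert gapped.aln_length > ungapped.aln_length

    frame = translate(with_ins)
    sw = smith_waterman_affine(frame, s.residues)
    seg_score, seg_len = best_ungapped_segment(frame, s.residues)
    assert _raw_score(gapped, scoring) == pytest.approx(sw, abs=0.2)
    assert _raw_score(ungapped, scoring) == pytest.approx(seg_score, abs=0.2)
    assert ungapped.aln_length == seg_len


def test_random_mutated_pairs_match_oracles(rng):
    """On seeded mutated pairs, engine scores equal the exhaustive DP
    scores and ungapped never aligns more columns than gapped."""
    scoring = ScoringParams()
    for trial in range(12):
        cds = random_cds(rng, rng.randint(60, 120))
        mutated = mutate_nt(rng, cds, 0.05)
        if rng.random() < 0.5:  # sprinkle a codon indel
            pos = 3 * rng.randint(1, len(mutated) // 3 - 2)
            mutated = mutated[:pos] + mutated[pos + 3 :]
        q = SequenceRecord("q", mutated, NUCLEOTIDE)
        s = SequenceRecord("s", translate(cds), PROTEIN)
        hits_g = search([q], [s], SearchMode(GAPPED, BLASTX_LIKE), scoring)
        hits_u = search([q], [s], SearchMode(UNGAPPED, BLASTX_LIKE), scoring)
        assert hits_g, "homologous pair must be found in gapped mode"
        frames = [translate(mutated[i:]) for i in range(3)]
        sw_best = max(smith_waterman_affine(f, s.residues) for f in frames)
        seg_best = max(best_ungapped_segment(f, s.residues)[0] for f in frames)
        assert _raw_score(hits_g[0], scoring) == pytest.approx(sw_best, abs=0.2)
        if hits_u:
            assert _raw_score(hits_u[0], scoring) == pytest.approx(seg_best, abs=0.2)
            assert hits_u[0].aln_length <= hits_g[0].aln_length


def test_gapped_hit_set_superset_of_ungapped(rng):
    """With indels planted, gapped search finds every query ungapped
    finds (same thresholds), and possibly more."""
    subjects = []
    queries = []
    for i in range(6):
        cds = random_cds(rng, 120)
        subjects.append(SequenceRecord(f"g{i}", translate(cds), PROTEIN))
        mutated = mutate_nt(rng, cds, 0.03)
        pos = 3 * rng.randint(10, 100)
        mutated = mutated[:pos] + random_cds(rng, 2) + mutated[pos:]
        queries.append(SequenceRecord(f"u{i}", mutated, NUCLEOTIDE))
    hits_g = search(queries, subjects, SearchMode(GAPPED, BLASTX_LIKE))
    hits_u = search(queries, subjects, SearchMode(UNGAPPED, BLASTX_LIKE))
    assert {h.query_id for h in hits_u} <= {h.query_id for h in hits_g}


def test_no_shared_kmer_means_no_hits():
    q = SequenceRecord("q", "A" * 300, NUCLEOTIDE)
    s = SequenceRecord("s", "W" * 100, PROTEIN)
    assert search([q], [s], SearchMode(GAPPED, BLASTX_LIKE)) == []


def test_empty_inputs_and_kind_errors(rng):
    q = SequenceRecord("q", random_cds(rng, 50), NUCLEOTIDE)
    p = SequenceRecord("p", "MEEPQRST" * 10, PROTEIN)
    assert search([], [p], SearchMode()) == []
    assert search([q], [], SearchMode()) == []
    with pytest.raises(ValueError, match="nucleotide queries"):
        search([p], [p], SearchMode(GAPPED, BLASTX_LIKE))
    with pytest.raises(ValueError, match="protein subjects"):
        search([q], [q], SearchMode(GAPPED, BLASTX_LIKE))
    with pytest.raises(ValueError):
        search([q], [p], SearchMode(GAPPED, BLASTN_LIKE))


@pytest.mark.skipif(shutil.which("blastx") is None, reason="NCBI BLAST+ not on PATH")
def test_best_subjects_agree_with_ncbi_blastx(tmp_path, rng):
    """Cross-check against a real blastx run: each mutated query's best
    subject must be its source gene in both engines."""
    genes = {f"g{i}": random_cds(rng, 110) for i in range(6)}
    subjects = [SequenceRecord(g, translate(c), PROTEIN) for g, c in genes.items()]
    queries = [
        SequenceRecord(f"q_{g}", mutate_nt(rng, c, 0.05), NUCLEOTIDE)
        for g, c in genes.items()
    ]
    db = tmp_path / "db.fa"
    qf = tmp_path / "q.fa"
    write_fasta(subjects, db)
    write_fasta(queries, qf)
    subprocess.run(
        ["makeblastdb", "-in", str(db), "-dbtype", "prot"],
        check=True, capture_output=True,
    )
    out = subprocess.run(
        ["blastx", "-query", str(qf), "-db", str(db), "-outfmt", "6",
         "-evalue", "1e-10"],
        check=True, capture_output=True, text=True,
    )
    blast_best = {}
    for hit in parse_tabular_hits(out.stdout.splitlines()):
        blast_best.setdefault(hit.query_id, hit.subject_id)
    ours = search(queries, subjects, SearchMode(GAPPED, BLASTX_LIKE))
    our_best = {}
    for hit in ours:
        if hit.query_id not in our_best:
            our_best[hit.query_id] = hit.subject_id
    assert our_best == blast_best == {f"q_{g}": g for g in genes}
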