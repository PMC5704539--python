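import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baitsfinder.bait_designer import (
    Bait,
    TilingParams,
    cluster_redundant,
    design_baits,
    drop_organelle_loci,
    filter_low_yield_loci,
    tile_baits,
    tile_starts,
)
from baitsfinder.records import NUCLEOTIDE, SequenceRecord, reverse_complement
from baitsfinder.simulate import SimulationConfig, generate_study

from ._oracles import tiling_bait_count
from .conftest import random_cds


class TestTiling:
    @pytest.mark.parametrize(
        "length,expected_starts",
        [
            (119, []),
            (120, [0]),
            (160, [0, 40]),  # two baits overlapping by exactly 80 bp
            (279, [0, 60, 120]),  # terminal bait would overlap 81 > 80
            (280, [0, 60, 120, 160]),
            (360, [0, 60, 120, 180, 240]),
        ],
    )
    def test_known_layouts(self, length, expected_starts):
        assert tile_starts(length) == expected_starts

    def test_160_bp_worked_example(self, rng):
        seq = random_cds(rng, 54)[:160]
        baits = tile_baits(seq, ref_gene_id="g", exon_index=1, taxon="t")
        assert len(baits) == 2
        first, second = baits
        overlap = (first.start + 120) - second.start
        assert overlap == 80
        assert all(len(b.sequence) == 120 for b in baits)
        assert all(seq[b.start : b.start + 120] == b.sequence for b in baits)

    def test_minimum_length_for_k_baits(self):
        """Smallest L yielding k = 1..4 baits: 120, 160, 220, 280."""
        first_l = {}
        for L in range(1, 401):
            k = len(tile_starts(L))
            first_l.setdefault(k, L)
        assert [first_l[k] for k in (1, 2, 3, 4)] == [120, 160, 220, 280]

    def test_matches_enumeration_oracle_up_to_1000(self):
        for L in range(1, 1001):
            assert len(tile_starts(L)) == tiling_bait_count(L), f"L={L}"

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        length=st.integers(1, 2000),
        bait=st.integers(20, 200),
        step_frac=st.integers(1, 10),
        overlap=st.integers(0, 199),
    )
    def test_tiling_invariants(self, length, bait, step_frac, overlap):
        step = max(1, bait // step_frac)
        overlap = min(overlap, bait - 1)
        params = TilingParams(bait, step, overlap)
        starts = tile_starts(length, params)
        assert all(0 <= s <= length - bait for s in starts)
        assert starts == sorted(set(starts))
        assert len(starts) == tiling_bait_count(length, bait, step, overlap)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            TilingParams(bait_len=0)
        with pytest.raises(ValueError):
            TilingParams(step=0)
        with pytest.raises(ValueError):
            TilingParams(step=121)
        with pytest.raises(ValueError):
            TilingParams(max_overlap=120)
        with pytest.raises(ValueError):
            tile_baits("AC-GT" * 50)


def bait(gene="g1", exon=1, taxon="t1", start=0, seq=None, member=""):
    return Bait(seq or "ACGT" * 30, gene, exon, taxon, start, member)


class TestYieldFilter:
    def test_anchor_count_spans_exons(self, rng):
        seqs = [random_cds(rng, 40) for _ in range(4)]
        baits = [
            bait("g1", 1, "anchor", 0, seqs[0]),
            bait("g1", 1, "anchor", 60, seqs[1]),
            bait("g1", 2, "anchor", 0, seqs[2]),  # 3 anchor baits: dropped
            bait("g1", 1, "other", 0, seqs[3]),
            bait("g2", 1, "anchor", 0, seqs[0]),
            bait("g2", 1, "anchor", 60, seqs[1]),
            bait("g2", 2, "anchor", 0, seqs[2]),
            bait("g2", 2, "anchor", 60, seqs[3]),  # 4 anchor baits: kept
        ]
        retained, kept = filter_low_yield_loci(baits, "anchor", 4)
        assert retained == {"g2"}
        assert {b.ref_gene_id for b in kept} == {"g2"}

    def test_dropping_discards_other_taxa_baits_too(self, rng):
        baits = [bait("g1", 1, "anchor", 0), bait("g1", 1, "other", 0)]
        retained, kept = filter_low_yield_loci(baits, "anchor", 4)
        assert retained == set() and kept == []

    def test_single_280bp_anchor_exon_survives(self, rng):
        seq = random_cds(rng, 94)[:280]
        tiled = tile_baits(seq, ref_gene_id="g1", exon_index=1, taxon="anchor")
        retained, kept = filter_low_yield_loci(tiled, "anchor", 4)
        assert retained == {"g1"}
        assert len(kept) == 4

    def test_disabled_filter_is_identity(self):
        baits = [bait("g1", 1, "anchor", 0)]
        retained, kept = filter_low_yield_loci(baits, None, 4)
        assert retained == {"g1"} and kept == baits


class TestClustering:
    def _mutated(self, seq, n):
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        out = list(seq)
        for i in range(n):
            out[3 * i] = flip[out[3 * i]]
        return "".join(out)

    def test_identical_baits_collapse(self, rng):
        seq = random_cds(rng, 40)
        baits = [bait(taxon="t1", seq=seq), bait(taxon="t2", seq=seq)]
        assert len(cluster_redundant(baits)) == 1

    def test_90_percent_boundary(self, rng):
        seq = random_cds(rng, 40)
        twelve = self._mutated(seq, 12)  # 108/120 = 90.0% -> removed
        thirteen = self._mutated(seq, 13)  # 107/120 = 89.2% -> retained
        assert len(cluster_redundant([bait(seq=seq), bait(taxon="t2", seq=twelve)])) == 1
        assert len(cluster_redundant([bait(seq=seq), bait(taxon="t2", seq=thirteen)])) == 2

    def test_reverse_complement_counts_as_identity(self, rng):
        seq = random_cds(rng, 40)
        baits = [bait(seq=seq), bait(taxon="t2", seq=reverse_complement(seq))]
        assert len(cluster_redundant(baits)) == 1

    def test_no_retained_pair_matches_and_deterministic(self, rng):
        seqs = [random_cds(rng, 40) for _ in range(5)]
        baits = []
        for i, s in enumerate(seqs):
            baits.append(bait(gene=f"g{i}", seq=s))
            baits.append(bait(gene=f"g{i}", taxon="t2", seq=self._mutated(s, 6)))
        reps = cluster_redundant(baits)
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                matches = sum(1 for x, y in zip(a.sequence, b.sequence) if x == y)
                rc = reverse_complement(b.sequence)
                matches_rc = sum(1 for x, y in zip(a.sequence, rc) if x == y)
                assert max(matches, matches_rc) / 120 < 0.9
        assert cluster_redundant(baits[::-1]) == reps  # input order irrelevant


class TestOrganelleScreen:
    def test_single_hit_dooms_whole_locus(self, rng):
        genome = random_cds(rng, 400)
        clean = [bait("g1", 1, "t", 0, random_cds(rng, 40)) for _ in range(3)]
        plastid_like = bait("g1", 2, "t", 0, genome[100:220])
        other = bait("g2", 1, "t", 0, random_cds(rng, 40))
        db = [SequenceRecord("plastid", genome, NUCLEOTIDE)]
        kept = drop_organelle_loci(clean + [plastid_like, other], db)
        assert {b.ref_gene_id for b in kept} == {"g2"}

    def test_below_90_identity_keeps_locus(self, rng):
        genome = random_cds(rng, 400)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        diverged = list(genome[100:220])
        for i in range(0, 117, 9):  # 13 substitutions -> 89.2%
            diverged[i] = flip[diverged[i]]
        b = bait("g1", 1, "t", 0, "".join(diverged))
        db = [SequenceRecord("plastid", genome, NUCLEOTIDE)]
        assert drop_organelle_loci([b], db) == [b]

    def test_empty_db_warns_and_keeps(self, rng):
        b = bait(seq=random_cds(rng, 40))
        with pytest.warns(UserWarning, match="empty organelle"):
            assert drop_organelle_loci([b], []) == [b]

    def test_planted_plastid_transcripts_are_screened_out(self):
        """Baits tiled from plastid-derived unigenes are always removed at
        default settings (transcript divergence well under 10%)."""
        study = generate_study(SimulationConfig(seed=3, n_scg=4, n_plastid_transcripts=4))
        plastid_ids = set(
            study.truth.loc[study.truth.label == "plastid", "unigene_id"]
        )
        baits = []
        for taxon, records in study.transcriptomes.items():
            for rec in records:
                if rec.id in plastid_ids:
                    baits.extend(
                        tile_baits(rec.residues, ref_gene_id=rec.id, exon_index=1,
                                   taxon=taxon, member_id=rec.id)
                    )
        assert baits
        kept = drop_organelle_loci(baits, [study.reference.plastid_genome])
        assert kept == []
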