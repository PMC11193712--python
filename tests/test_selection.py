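"""Degeneracy classes, Fisher tests, cross-species mapping, GERP classes."""

import math

import numpy as np
import pytest

from cpatac.core import AnnotationSet, CircularGenome, Gene, GenomicInterval
from cpatac import selection as sel


def _genome(seq, name="toy"):
    return CircularGenome(name=name, sequence=seq)


def _cds_annotation(seq_len, start, end, strand="+"):
    g = Gene("g1", GenomicInterval(start, end, strand=strand), feature_type="CDS")
    return AnnotationSet(genes=[g], genome_length=seq_len)


class TestClassifyDegenerateSites:
    def test_gly_codon_third_position_is_4ds(self):
        # GGA: GGN all encode Gly
        genome = _genome("GGA" + "A" * 27)
        track = sel.classify_degenerate_sites(genome, _cds_annotation(30, 0, 3))
        assert track.classes[2] == sel.FOURFOLD
        assert track.classes[0] == sel.NONDEG or track.classes[0] == sel.OTHERCDS

    def test_atg_third_position_is_nondeg(self):
        genome = _genome("ATG" + "C" * 27)
        track = sel.classify_degenerate_sites(genome, _cds_annotation(30, 0, 3))
        assert track.classes[2] == sel.NONDEG

    def test_minus_strand_cds_read_as_revcomp(self):
        # genome TCC..., minus-strand CDS at [0,3) reads GGA -> third pos of
        # the codon is genome position 0
        genome = _genome("TCC" + "G" * 27)
        track = sel.classify_degenerate_sites(genome, _cds_annotation(30, 0, 3, "-"))
        assert track.classes[0] == sel.FOURFOLD

    def test_non_cds_positions_labeled(self):
        genome = _genome("GGA" + "A" * 27)
        track = sel.classify_degenerate_sites(genome, _cds_annotation(30, 0, 3))
        assert np.all(track.classes[3:] == sel.NONCDS)

    def test_overlapping_cds_vetoes_4ds(self):
        # same interval annotated on both strands; + strand GGA has a 4DS at
        # pos 2, but pos 2 is a first codon position on the - strand
        seq = "GGATCC"
        genes = [Gene("p", GenomicInterval(0, 6, strand="+"), feature_type="CDS"),
                 Gene("m", GenomicInterval(0, 6, strand="-"), feature_type="CDS")]
        ann = AnnotationSet(genes=genes, genome_length=6)
        track = sel.classify_degenerate_sites(_genome(seq), ann)
        assert track.classes[2] == sel.NONDEG  # vetoed, still a third-codon site

    def test_toy_cds_matches_substitution_translation_oracle(self):
        """30 random codons against a brute-force translate-all-4 oracle."""
        from Bio.Seq import Seq

        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 90)])
        genome = _genome(seq)
        track = sel.classify_degenerate_sites(genome, _cds_annotation(90, 0, 90))
        for k in range(30):
            aas = {str(Seq(seq[3 * k:3 * k + 2] + b).translate(table=11))
                   for b in "ACGT"}
            stops = {str(Seq(seq[3 * k:3 * k + 2] + b).translate(table=11)) == "*"
                     for b in "ACGT"}
            expect = sel.FOURFOLD if len(aas) == 1 and aas != {"*"} else sel.NONDEG
            assert track.classes[3 * k + 2] == expect, f"codon {k}"


class TestOverlapContingency:
    def _setup(self):
        genes = [Gene("g1", GenomicInterval(0, 60, strand="+"), feature_type="CDS")]
        ann = AnnotationSet(genes=genes, genome_length=100)
        return ann

    def test_no_footprints_zero_overlap_column(self):
        ann = self._setup()
        tab = sel.overlap_contingency([], "basepair", 100, annotation=ann)
        assert tab.table[:, 1].sum() == 0
        assert tab.table.sum() == 100

    def test_full_coverage_zero_nonoverlap_column(self):
        ann = self._setup()
        tab = sel.overlap_contingency([GenomicInterval(0, 100)], "basepair", 100,
                                      annotation=ann)
        assert tab.table[:, 0].sum() == 0

    def test_hand_built_enumeration(self):
        ann = self._setup()
        # one 10-bp footprint straddling the genic/intergenic boundary
        tab = sel.overlap_contingency([GenomicInterval(55, 65)], "basepair", 100,
                                      annotation=ann)
        # genic: 60 bases, 5 covered; intergenic: 40 bases, 5 covered
        assert tab.table.tolist() == [[55, 5], [35, 5]]


class TestFisherExact:
    def test_printed_distribution_preference_table(self):
        res = sel.fisher_exact(np.array([[98669, 6896], [26634, 2326]]))
        assert round(res.odds_ratio, 2) == 1.25
        assert res.p < 2.2e-16 and res.p_floored == 2.2e-16

    def test_printed_degenerate_site_table(self):
        res = sel.fisher_exact(np.array([[8894, 646], [16431, 2296]]))
        assert round(res.odds_ratio, 2) == 1.92

    def test_small_table_full_enumeration_value(self):
        res = sel.fisher_exact(np.array([[3, 1], [1, 3]]))
        assert res.odds_ratio == 9.0
        assert res.p == pytest.approx(34 / 70, rel=1e-12)

    def test_zero_cell_odds_ratio_undefined(self):
        res = sel.fisher_exact(np.array([[0, 5], [3, 2]]))
        assert math.isnan(res.odds_ratio)
        assert 0 <= res.p <= 1


class TestFootprintConservation:
    def _pair(self, rng, L=4000):
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, L)])
        return _genome(seq, "qa"), _genome(seq, "tb")

    def test_identical_genomes_all_conserved_shared(self):
        rng = np.random.default_rng(1)
        qg, tg = self._pair(rng)
        ivs = [GenomicInterval(s, s + 20) for s in (500, 1500, 2500)]
        mapping = sel.footprint_conservation(qg, ivs, tg, ivs)
        assert (mapping["category"] == "conserved+shared").all()
        assert np.allclose(mapping["score"], 100.0)

    def test_two_vs_three_mismatch_score_boundary(self):
        """2 interior mismatches score 90 (pass); 3 score 85 (fail)."""
        rng = np.random.default_rng(2)
        qg, tg = self._pair(rng)
        iv = [GenomicInterval(1000, 1020)]  # window center 1010: [985, 1035)
        def mutate(genome, positions):
            seq = list(genome.sequence)
            for p in positions:
                seq[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p]]
            return _genome("".join(seq), genome.name)
        two = sel.footprint_conservation(mutate(qg, [995, 1010]), iv, tg, iv)
        assert two["score"].iloc[0] == 90.0
        assert two["category"].iloc[0] == "conserved+shared"
        three = sel.footprint_conservation(mutate(qg, [995, 1010, 1025]), iv, tg, iv)
        assert three["category"].iloc[0] == "not conserved"

    def test_45bp_exact_match_fails_length_threshold(self):
        rng = np.random.default_rng(3)
        qg, tg = self._pair(rng)
        # diverge the last 5 bases of the 50-bp window in the query
        iv = [GenomicInterval(1000, 1020)]
        seq = list(qg.sequence)
        for p in range(1030, 1035):
            seq[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p]]
        qmut = _genome("".join(seq), "qa")
        mapping = sel.footprint_conservation(qmut, iv, tg, iv)
        assert mapping["aligned_length"].iloc[0] <= 45
        assert mapping["category"].iloc[0] == "not conserved"

    def test_conserved_but_unshared_category(self):
        rng = np.random.default_rng(4)
        qg, tg = self._pair(rng)
        mapping = sel.footprint_conservation(qg, [GenomicInterval(500, 520)], tg,
                                             [GenomicInterval(3000, 3020)])
        assert mapping["category"].iloc[0] == "conserved+unshared"

    def test_genome_shorter_than_window_errors(self):
        g = _genome("ACGTACGTAC")
        with pytest.raises(ValueError):
            sel.footprint_conservation(g, [], g, [])


class TestMultiwayConserved:
    def test_identical_trio_returns_all(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 3000)])
        g = _genome(seq)
        ivs = [GenomicInterval(s, s + 20) for s in (400, 1400, 2400)]
        res = sel.multiway_conserved(g, ivs, [(g, ivs), (g, ivs)])
        assert res["conserved_in_all"].all()

    def test_one_empty_genome_gives_empty_intersection(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 3000)])
        g = _genome(seq)
        ivs = [GenomicInterval(400, 420)]
        res = sel.multiway_conserved(g, ivs, [(g, ivs), (g, [])])
        assert not res["conserved_in_all"].any()


class TestGerpClassTest:
    def test_identical_sets_z_zero_p_one(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(-1, 0.42, 1000)
        mask = np.ones(1000, dtype=bool)
        res = sel.gerp_class_test(scores, mask, mask)
        assert np.allclose(res["z"], 0.0) and np.allclose(res["p"], 1.0)

    def test_closed_form_two_proportion_case(self):
        # High class: 600/1000 covered vs 500/1000 background
        scores = np.concatenate([np.full(600, 0.42), np.full(400, -0.5),
                                 np.full(500, 0.42), np.full(500, -0.5)])
        covered = np.arange(2000) < 1000
        res = sel.gerp_class_test(scores, covered, ~covered)
        high = res[res["class"] == "High"].iloc[0]
        pooled = 0.55
        z_expect = 0.1 / math.sqrt(pooled * (1 - pooled) * (2 / 1000))
        assert high["z"] == pytest.approx(z_expect, rel=1e-9)
        from scipy import stats
        assert high["p"] == pytest.approx(2 * stats.norm.sf(z_expect), rel=1e-9)

    def test_class_boundaries(self):
        track = sel.ConservationTrack(np.array([-0.1, 0.0, 0.41, 0.42, np.nan]))
        assert track.classify().tolist() == [0, 1, 1, 2, -1]

    def test_empty_covered_set_errors(self):
        scores = np.zeros(10)
        with pytest.raises(ValueError):
            sel.gerp_class_test(scores, np.zeros(10, dtype=bool),
                                np.ones(10, dtype=bool))
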