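"""Footprint scoring, calling, FPD, bias correction, merging, differences."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpatac.core import GenomicInterval, InsertionTrack
from cpatac.footprinting import (
    FootprintCallParams,
    bias_correct,
    detect_footprints,
    differential_fpd,
    flank_accessibility,
    fpd,
    fpd_correlation,
    merge_footprints,
    presence_counts,
    wellington_score,
)


def _track(counts):
    return InsertionTrack(genome_name="toy", counts=np.asarray(counts, dtype=float))


def _binom_logcdf_oracle(f, n, p):
    """Independent exact lower-tail binomial CDF (direct pmf summation)."""
    total = sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k) for k in range(f + 1))
    return math.log10(total)


class TestWellingtonScore:
    def test_empty_window_scores_zero(self):
        assert wellington_score(_track(np.zeros(500)), 100, 10) == 0.0

    def test_total_depletion_matches_closed_form(self):
        # f=0, s=70, L=10, S=35: log10((1-0.125)^70)
        counts = np.zeros(500)
        counts[65:100] = 1.0
        counts[110:145] = 1.0
        t = _track(counts)
        assert wellington_score(t, 100, 10) == pytest.approx(
            70 * math.log10(1 - 0.125), abs=1e-9)
        assert wellington_score(t, 100, 10) == pytest.approx(-4.0594, abs=1e-3)

    def test_partial_depletion_matches_exact_cdf_oracle(self):
        counts = np.zeros(500)
        counts[65:100] = 1.0
        counts[110:145] = 1.0
        counts[100:105] = 1.0  # f = 5
        t = _track(counts)
        assert wellington_score(t, 100, 10) == pytest.approx(
            _binom_logcdf_oracle(5, 75, 0.125), rel=1e-9)

    @given(f=st.integers(0, 30), extra=st.integers(0, 40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_shoulder_and_footprint_counts(self, f, extra):
        """More shoulder signal (deeper relative depletion) never raises the
        score; more footprint signal never lowers it."""
        def score(fc, sc):
            counts = np.zeros(300)
            counts[100:110] = fc / 10.0
            counts[65:100] = sc / 70.0
            counts[110:145] = sc / 70.0
            return wellington_score(_track(counts), 100, 10)

        s = 40
        assert score(f, s + extra) <= score(f, s) + 1e-9
        assert score(f + extra, s) >= score(f, s) - 1e-9

    def test_no_underflow_at_extreme_depth(self):
        counts = np.zeros(1000)
        counts[0:35] = 1e4
        counts[55:90] = 1e4
        sc = wellington_score(_track(counts), 35, 20)
        assert np.isfinite(sc) and sc < -1e4


class TestFpd:
    def test_uniform_rate_gives_zero(self, uniform_track):
        assert fpd(uniform_track, GenomicInterval(500, 520)) == pytest.approx(0.0)

    def test_full_protection_gives_one(self):
        counts = np.full(1000, 3.0)
        counts[400:420] = 0.0
        assert fpd(_track(counts), GenomicInterval(400, 420)) == pytest.approx(1.0)

    def test_printed_formula_case(self):
        # L=20, FPI=10, FKI=200 -> (2-0.5)/(2+0.5) = 0.6
        counts = np.zeros(1000)
        counts[400:420] = 0.5      # 10 insertions inside
        counts[350:400] = 2.0      # 100 per flank
        counts[420:470] = 2.0
        assert fpd(_track(counts), GenomicInterval(400, 420)) == pytest.approx(0.6)

    def test_empty_everything_is_nan_not_zero(self):
        assert math.isnan(fpd(_track(np.zeros(1000)), GenomicInterval(400, 420)))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, 1000).astype(float) + 1
        iv = GenomicInterval(300, 321)
        assert fpd(_track(counts), iv) == pytest.approx(fpd(_track(7 * counts), iv))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(rng.uniform(0.1, 5), 500).astype(float)
        v = fpd(_track(counts), GenomicInterval(100, 120))
        assert math.isnan(v) or -1.0 <= v <= 1.0


class TestBiasCorrect:
    def test_zero_gdna_is_identity(self):
        raw = _track(np.arange(10, dtype=float))
        out = bias_correct(raw, _track(np.zeros(10)))
        assert np.array_equal(out.counts, raw.counts)

    def test_printed_formula_value(self):
        out = bias_correct(_track([10.0]), _track([4.0]))
        assert out.counts[0] == 2.0

    def test_zero_raw_stays_zero(self):
        out = bias_correct(_track([0.0, 0.0]), _track([9.0, 0.0]))
        assert np.all(out.counts == 0.0)

    def test_idempotent_with_zero_gdna(self):
        raw = _track(np.arange(10, dtype=float))
        zero = _track(np.zeros(10))
        once = bias_correct(raw, zero)
        twice = bias_correct(once, zero)
        assert np.array_equal(once.counts, twice.counts)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            bias_correct(_track(np.ones(10)), _track(np.ones(11)))


class TestFpdCorrelation:
    def _fps(self, track, ivs):
        from cpatac.footprinting import Footprint, FootprintSet
        fps = [Footprint(interval=iv, score=-5.0, fdr=0.01, fpi=0, fki=0,
                         fpd=fpd(track, iv)) for iv in ivs]
        return FootprintSet(sample="t", footprints=fps)

    def test_identical_tracks_give_one(self):
        rng = np.random.default_rng(1)
        t = _track(rng.poisson(5.0, 2000))
        ivs = [GenomicInterval(i, i + 20) for i in range(200, 1800, 200)]
        assert fpd_correlation(self._fps(t, ivs), t, t) == pytest.approx(1.0)

    def test_single_footprint_errors(self):
        t = _track(np.ones(500))
        with pytest.raises(ValueError):
            fpd_correlation(self._fps(t, [GenomicInterval(100, 120)]), t, t)

    def test_mild_bias_keeps_high_correlation(self, small_truth):
        """Correction against the planted bias preserves FPD ordering."""
        from cpatac import simulate as sim
        track = sim.simulate_atac(small_truth, seed=21)
        gdna = sim.simulate_gdna(small_truth, seed=22)
        corrected = bias_correct(track, gdna)
        ivs = [f.interval for f in small_truth.footprints]
        r = fpd_correlation(self._fps(track, ivs), track, corrected)
        assert r > 0.5


class TestDetectFootprints:
    def test_zero_track_empty_set(self):
        fps = detect_footprints(_track(np.zeros(2000)), seed=1)
        assert len(fps) == 0

    def test_single_planted_footprint_recovered(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, 5000).astype(float)
        counts[2000:2020] = 0.0  # full protection, 20 bp
        fps = detect_footprints(_track(counts), seed=3)
        assert len(fps) == 1
        iv = fps.footprints[0].interval
        inter = max(0, min(iv.end, 2020) - max(iv.start, 2000))
        union = max(iv.end, 2020) - min(iv.start, 2000)
        assert inter / union >= 0.5

    def test_uniform_track_yields_no_calls(self):
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            counts = rng.poisson(5.0, 5000).astype(float)
            fps = detect_footprints(_track(counts), seed=seed)
            assert len(fps) == 0

    def test_calls_are_non_overlapping(self, small_track):
        fps = detect_footprints(small_track, seed=4)
        assert len(fps) > 0
        occupied = np.zeros(small_track.length, dtype=int)
        for iv in fps.intervals():
            occupied[iv.positions(small_track.length)] += 1
        assert occupied.max() == 1

    def test_deterministic_given_seed(self, small_track):
        a = detect_footprints(small_track, seed=5).to_frame()
        b = detect_footprints(small_track, seed=5).to_frame()
        assert a.equals(b)


class TestFlankAccessibility:
    def test_uniform_rate(self, uniform_track):
        assert flank_accessibility(uniform_track, GenomicInterval(500, 520)) == 5.0

    def test_zero_flanks(self):
        counts = np.zeros(1000)
        counts[400:420] = 3.0
        assert flank_accessibility(_track(counts), GenomicInterval(400, 420)) == 0.0

    def test_hand_built_case(self):
        counts = np.zeros(1000)
        counts[350:400] = 1.0  # 50
        counts[420:470] = 3.0  # 150
        assert flank_accessibility(_track(counts), GenomicInterval(400, 420)) == 2.0


class TestMergeFootprints:
    def _set(self, sample, pairs):
        from cpatac.footprinting import Footprint, FootprintSet
        return FootprintSet(sample=sample, footprints=[
            Footprint(interval=GenomicInterval(a, b), score=-5, fdr=0.01,
                      fpi=0, fki=0, fpd=0.5, sample=sample) for a, b in pairs])

    def test_one_bp_overlap_merges(self):
        merged = merge_footprints([self._set("a", [(10, 20)]), self._set("b", [(19, 30)])])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (10, 30)
        assert merged[0].samples == {"a", "b"}

    def test_adjacent_half_open_does_not_merge(self):
        merged = merge_footprints([self._set("a", [(10, 20)]), self._set("b", [(20, 30)])])
        assert len(merged) == 2

    def test_chained_single_linkage(self):
        merged = merge_footprints([self._set("a", [(10, 20), (19, 28), (27, 40)])])
        assert len(merged) == 1 and merged[0].interval.end == 40

    def test_presence_queries(self):
        sets = [self._set("t1", [(10, 20), (100, 110)]),
                self._set("t2", [(15, 25)])]
        merged = merge_footprints(sets)
        frac = presence_counts(merged, n_samples=2)
        assert frac["in_all"] == pytest.approx(0.5)
        assert frac["in_one"] == pytest.approx(0.5)


class TestDifferentialFpd:
    def test_identical_replicates_p_one(self):
        a = np.array([[0.5, 0.5], [0.2, 0.2]])
        res = differential_fpd(a, a)
        assert np.allclose(res["p"], 1.0)

    def test_closed_form_welch_case(self):
        # {0.1, 0.2} vs {0.8, 0.9}: t = -0.7/sqrt(0.005) with df = 2
        res = differential_fpd(np.array([[0.1, 0.2]]), np.array([[0.8, 0.9]]))
        t_expect = -0.7 / math.sqrt(0.005)
        p_expect = 1 - abs(t_expect) / math.sqrt(t_expect ** 2 + 2)  # t-dist, df=2
        assert res["t"].iloc[0] == pytest.approx(t_expect, rel=1e-9)
        assert res["p"].iloc[0] == pytest.approx(p_expect, rel=1e-6)
        assert bool(res["significant"].iloc[0])

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError):
            differential_fpd(np.array([[0.1]]), np.array([[0.8, 0.9]]))

    def test_bh_correction_is_monotone(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.5, 0.05, (20, 3))
        b = rng.normal(0.5, 0.05, (20, 3))
        b[0] += 0.5
        res = differential_fpd(a, b, correction="bh")
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert res["p_adj"].max() <= 1.0
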