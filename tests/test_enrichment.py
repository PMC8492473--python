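import numpy as np
import pytest

from oracles import exact_binom_lower, exact_binom_upper
from tereawaken.annotations import TEAnnotation, TECopy
from tereawaken.enrichment import (
    OverlapTotals,
    cross_with_de,
    enrichment_test,
    family_enrichment,
    observed_overlap,
    pad_te_intervals,
    shuffle_te_null,
)
from tereawaken.intervals import GenomeModel, GenomicInterval
from tereawaken.peaks import Peak, PeakSet
from tereawaken.synthetic import simulate_genome, simulate_te_annotation


def peakset(*segs, chrom="chr1"):
    return PeakSet("p", [Peak(GenomicInterval(chrom, s, e)) for s, e in segs])


class TestPadTEIntervals:
    def test_pad_clipped_to_chromosome(self):
        genome = GenomeModel({"chr1": 1200})
        te = TEAnnotation(
            [TECopy("c1", "f", "ERV1", "LTR", GenomicInterval("chr1", 500, 700))]
        )
        padded = pad_te_intervals(te, 1000, genome)
        iv = padded.copies[0].interval
        assert (iv.start, iv.end) == (0, 1200)

    def test_zero_pad_identity(self, small_genome, toy_te):
        padded = pad_te_intervals(toy_te, 0, small_genome)
        assert [c.interval for c in padded.copies] == [c.interval for c in toy_te.copies]


class TestObservedOverlap:
    def test_no_peaks_all_zero(self, toy_te):
        assert set(observed_overlap(PeakSet("p", []), toy_te).values()) == {0}

    def test_single_peak_in_single_copy(self, toy_te):
        counts = observed_overlap(peakset((1100, 1200)), toy_te)
        assert counts["famA:ERV1:LTR"] == 1
        assert counts["famB:L1:LINE"] == 0

    def test_one_peak_over_k_copies_counts_k_events(self):
        te = TEAnnotation(
            [
                TECopy("c1", "f", "ERV1", "LTR", GenomicInterval("chr1", 100, 200)),
                TECopy("c2", "f", "ERV1", "LTR", GenomicInterval("chr1", 150, 260)),
            ]
        )
        counts = observed_overlap(peakset((120, 220)), te)
        assert counts["f:ERV1:LTR"] == 2

    def test_matches_all_pairs_brute_force(self):
        from oracles import brute_overlap_pairs

        rng = np.random.default_rng(17)
        for trial in range(20):
            copies = [
                TECopy(
                    f"c{i}", f"fam{i % 4}", "ERV1", "LTR",
                    GenomicInterval(
                        "chr1", s := int(rng.integers(0, 30_000)),
                        s + int(rng.integers(100, 900)),
                    ),
                )
                for i in range(60)
            ]
            te = TEAnnotation(copies)
            segs = [
                (int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 31_000, 150), rng.integers(50, 600, 150))
            ]
            pk = peakset(*segs)
            got = observed_overlap(pk, te)
            for fam in te.families:
                fam_tuples = [
                    ("chr1", c.interval.start, c.interval.end)
                    for c in copies if c.label == fam
                ]
                peak_tuples = [("chr1", s, e) for s, e in segs]
                assert got[fam] == brute_overlap_pairs(peak_tuples, fam_tuples)


class TestShuffleNull:
    def test_fully_excluded_genome_errors(self):
        genome = GenomeModel({"chr1": 1000}, [GenomicInterval("chr1", 0, 1000)])
        te = TEAnnotation(
            [TECopy("c1", "f", "ERV1", "LTR", GenomicInterval("chr1", 0, 100))]
        )
        with pytest.raises(RuntimeError):
            shuffle_te_null(te, genome, peakset((0, 10)), n_shuffles=5)

    def test_null_mean_matches_uniform_expectation(self):
        # closed form: a single copy of length L and m peaks of length P on a
        # chromosome with S valid starts overlaps E[hits] = m * (#hit starts)/S
        genome = GenomeModel({"chr1": 1_000_000})
        L = 2_000
        te = TEAnnotation(
            [TECopy("c1", "f", "ERV1", "LTR", GenomicInterval("chr1", 0, L))]
        )
        m, P = 200, 500
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 999_000, m)
        pk = peakset(*[(int(s), int(s) + P) for s in starts])
        n_sh = 1000
        null = shuffle_te_null(te, genome, pk, n_shuffles=n_sh, seed=1)["f:ERV1:LTR"]
        S = 1_000_000 - L + 1
        p_hit_per_peak = np.array([
            (min(s + P - 1, S - 1) - max(0, s - L + 1) + 1) / S for s in starts
        ])
        expected = p_hit_per_peak.sum()
        se = null.std(ddof=1) / np.sqrt(n_sh)
        assert abs(null.mean() - expected) <= 3 * se

    def test_shuffles_preserve_copy_counts_and_avoid_excluded(self):
        genome = simulate_genome(2, 100_000, 0.2, seed=2)
        te = simulate_te_annotation(genome, 3, 10, (100, 300), seed=2)
        pk = peakset((5_000, 5_500))
        null = shuffle_te_null(te, genome, pk, n_shuffles=50, seed=3)
        assert set(null) == set(te.families)
        assert all(len(v) == 50 for v in null.values())


class TestEnrichmentTest:
    def test_observed_equal_to_null_mean_is_ns(self):
        null = np.full(100, 10)
        totals = OverlapTotals(100, 1000, 100_000, 5000, 60)
        r = enrichment_test(10, null, totals)
        assert r.direction == "ns"

    def test_upper_tail_matches_exact_binomial(self):
        null = np.full(200, 10.0)
        totals = OverlapTotals(100, 1000, 100_000, 5000, 60)
        r = enrichment_test(30, null, totals)
        assert r.p_binomial == pytest.approx(exact_binom_upper(30, 100, 0.1), abs=1e-10)
        assert r.direction == "enriched"

    def test_depletion_lower_tail(self):
        null = np.full(200, 10.0)
        totals = OverlapTotals(100, 1000, 100_000, 5000, 0)
        r = enrichment_test(0, null, totals)
        assert r.p_binomial == pytest.approx(exact_binom_lower(0, 100, 0.1), abs=1e-10)
        assert r.direction == "depleted"

    def test_degenerate_zero_null_zero_observed(self):
        r = enrichment_test(0, np.zeros(10), OverlapTotals(100, 0, 1000, 0, 0))
        assert r.direction == "ns" and r.p_binomial == 1.0


class TestCrossWithDE:
    def _results(self):
        totals = OverlapTotals(100, 1000, 100_000, 5000, 60)
        return [
            enrichment_test(30, np.full(100, 10.0), totals, family="up_and_enriched"),
            enrichment_test(30, np.full(100, 10.0), totals, family="enriched_only"),
            enrichment_test(10, np.full(100, 10.0), totals, family="up_only"),
        ]

    def test_flag_requires_both_de_and_enrichment(self):
        table = cross_with_de(self._results(), {"up_and_enriched", "up_only"})
        assert bool(table.loc["up_and_enriched", "flagged"])
        assert not bool(table.loc["enriched_only", "flagged"])
        assert not bool(table.loc["up_only", "flagged"])

    def test_empty_de_set_no_flags(self):
        table = cross_with_de(self._results(), set())
        assert not table["flagged"].any()


class TestFamilyEnrichmentEndToEnd:
    def test_planted_family_detected(self):
        from tereawaken.synthetic import simulate_peaks

        genome = simulate_genome(2, 500_000, 0.0, seed=8)
        te = simulate_te_annotation(genome, 4, 15, (300, 500), seed=8)
        fam = te.families[0]
        pk, _ = simulate_peaks(genome, te, {fam}, 8.0, 150, peak_len=400, seed=8)
        results = family_enrichment(te, genome, pk, pad=1000, n_shuffles=300, seed=8)
        by_fam = {r.family: r for r in results}
        assert by_fam[fam].direction == "enriched"
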