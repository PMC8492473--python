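import numpy as np
import pytest

from oracles import exact_binom_upper, exact_fisher_two_sided, exact_hypergeom_upper
from tereawaken.annotations import Gene, GeneAnnotation, TECopy
from tereawaken.intervals import GenomicInterval
from tereawaken.proximity import (
    binomial_vs_null,
    closest_gene,
    observed_overlap_test,
    proximal_genes,
    proximity_analysis,
    resampled_background,
)


def gene(gid, chrom, start, end, strand="+"):
    return Gene(gid, GenomicInterval(chrom, start, end, strand))


def copy(cid, chrom, start, end, strand="+"):
    return TECopy(cid, "f", "ERV1", "LTR", GenomicInterval(chrom, start, end, strand))


class TestClosestGene:
    def test_nearest_tss_and_distance_magnitude(self):
        genes = GeneAnnotation([gene("g1", "chr1", 1000, 3000),
                                gene("g2", "chr1", 5000, 7000)])
        got = closest_gene([copy("c1", "chr1", 1200, 1300)], genes)
        gid, d = got["c1"]
        assert gid == "g1" and abs(d) == 200

    def test_copy_spanning_tss_distance_zero(self):
        genes = GeneAnnotation([gene("g1", "chr1", 1000, 3000)])
        got = closest_gene([copy("c1", "chr1", 900, 1100)], genes)
        assert got["c1"] == ("g1", 0)

    def test_equidistant_tie_first_by_sort_order(self):
        genes = GeneAnnotation([gene("g2", "chr1", 2000, 2500),
                                gene("g1", "chr1", 1000, 1500)])
        # copy at [1450,1550): g1 TSS 1000 -> 450; g2 TSS 2000 -> 451; nearest g1
        got = closest_gene([copy("c1", "chr1", 1450, 1550)], genes)
        assert got["c1"][0] == "g1"
        # exactly equidistant: TSS 1000 and 1900, copy [1450,1451)
        genes2 = GeneAnnotation([gene("gb", "chr1", 1900, 2500),
                                 gene("ga", "chr1", 1000, 1500)])
        got2 = closest_gene([copy("c2", "chr1", 1450, 1451)], genes2)
        assert got2["c2"][0] == "ga"  # first in (chrom, start) order

    def test_sign_follows_te_orientation(self):
        genes = GeneAnnotation([gene("g1", "chr1", 5000, 6000)])
        plus = closest_gene([copy("c1", "chr1", 1000, 1100, "+")], genes)
        minus = closest_gene([copy("c2", "chr1", 1000, 1100, "-")], genes)
        assert plus["c1"][1] > 0  # gene downstream of + strand copy
        assert minus["c2"][1] < 0  # same gene is upstream in - orientation

    def test_copy_without_genes_on_chromosome_omitted(self):
        genes = GeneAnnotation([gene("g1", "chr1", 100, 200)])
        got = closest_gene([copy("c1", "chr2", 100, 200)], genes)
        assert got == {}


class TestProximalGenes:
    @pytest.mark.parametrize("dist,included", [(30_000, True), (30_001, False)])
    def test_window_boundary_inclusive(self, dist, included):
        asg = {"c1": ("g1", dist)}
        assert (("g1" in proximal_genes(asg, 30_000)) is included)


class TestObservedOverlapTest:
    def test_empty_deg_set(self):
        universe = {f"g{i}" for i in range(100)}
        p_f, p_h, k = observed_overlap_test(set(list(universe)[:10]), set(), universe)
        assert k == 0 and p_h == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        universe = {f"g{i}" for i in range(100)}
        proximal = {f"g{i}" for i in range(10)}
        degs = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 65)}
        k = len(proximal & degs)
        assert k == 5
        p_f, p_h, k_got = observed_overlap_test(proximal, degs, universe)
        assert k_got == 5
        assert p_h == pytest.approx(exact_hypergeom_upper(5, 100, 10, 20), abs=1e-10)
        table = [[5, 5], [15, 75]]
        assert p_f == pytest.approx(exact_fisher_two_sided(table), abs=1e-10)

    def test_proximal_equals_universe_tail_one(self):
        universe = {f"g{i}" for i in range(20)}
        degs = {f"g{i}" for i in range(7)}
        _, p_h, k = observed_overlap_test(universe, degs, universe)
        assert k == 7 and p_h == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            observed_overlap_test(set(), set(), set())


class TestResampledBackground:
    def test_disjoint_pools_give_all_zero(self):
        remaining = {f"r{i}" for i in range(50)}
        null, mean = resampled_background(10, remaining, {"x", "y"}, 200, seed=1)
        assert mean == 0.0 and (null == 0).all()

    def test_mean_matches_hypergeometric_expectation(self):
        remaining = {f"r{i}" for i in range(200)}
        proximal = {f"r{i}" for i in range(40)}
        n = 5_000
        null, mean = resampled_background(30, remaining, proximal, n, seed=2)
        expected = 30 * 40 / 200
        se = null.std(ddof=1) / np.sqrt(n)
        assert abs(mean - expected) <= 3 * se

    def test_seed_reproducibility(self):
        remaining = {f"r{i}" for i in range(100)}
        proximal = {f"r{i}" for i in range(20)}
        a, _ = resampled_background(10, remaining, proximal, 100, seed=7)
        b, _ = resampled_background(10, remaining, proximal, 100, seed=7)
        assert np.array_equal(a, b)

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError):
            resampled_background(11, {f"r{i}" for i in range(10)}, set(), 10)


class TestBinomialVsNull:
    def test_zero_observed_p_one(self):
        assert binomial_vs_null(0, 20, 5.0) == 1.0

    def test_matches_exact_enumeration(self):
        p = binomial_vs_null(5, 20, 2.0)  # n=20, p=0.1
        assert p == pytest.approx(exact_binom_upper(5, 20, 0.1), abs=1e-10)

    def test_full_overlap_closed_form(self):
        # P(X = n) = p^n when observed == degs_size
        p = binomial_vs_null(20, 20, 2.0)
        assert p == pytest.approx(0.1**20, rel=1e-9)

    def test_degenerate_null_warns_and_returns_zero(self):
        assert binomial_vs_null(3, 20, 0.0) == 0.0


class TestProximityAnalysisEndToEnd:
    def test_coupled_truth_detected(self):
        from tereawaken.synthetic import (
            simulate_gene_annotation,
            simulate_genome,
            simulate_te_annotation,
        )

        genome = simulate_genome(2, 2_000_000, 0.0, seed=12)
        te = simulate_te_annotation(genome, 2, 15, (300, 500), seed=12)
        targets = [c.copy_id for c in te.copies if c.label == te.families[0]]
        genes, truth = simulate_gene_annotation(
            genome, 800, te, frac_proximal=0.1, window=30_000, seed=12,
            target_copies=targets,
        )
        prox_truth = {g for _, g in truth.proximal_pairs}
        rng = np.random.default_rng(12)
        degs = set(rng.choice(sorted(prox_truth), 40, replace=False))
        degs |= set(rng.choice(sorted(set(g.gene_id for g in genes.genes) - prox_truth),
                               40, replace=False))
        by_id = te.by_id()
        res = proximity_analysis(
            [by_id[c] for c in targets], genes, degs, window=30_000,
            n_resamples=2_000, seed=12,
        )
        assert res.p_binomial_vs_null < 0.01
        assert res.p_hypergeom < 0.01
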