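import numpy as np
import pytest

from tereawaken import synthetic
from tereawaken.intervals import GenomicInterval
from tereawaken.synthetic import (
    simulate_counts,
    simulate_gene_annotation,
    simulate_genome,
    simulate_insertion_profiles,
    simulate_peaks,
    simulate_reads,
    simulate_te_annotation,
)


class TestSimulateGenome:
    def test_zero_fraction_gives_no_excluded_regions(self):
        g = simulate_genome(1, 1_000_000, 0.0, seed=1)
        assert g.excluded_regions == []
        assert g.chrom_sizes == {"chr1": 1_000_000}

    def test_excluded_length_close_to_target(self):
        g = simulate_genome(2, 1_000_000, 0.1, seed=7)
        for chrom in g.chrom_sizes:
            total = sum(e - s for s, e in g.excluded_by_chrom(chrom))
            assert 0.08e6 <= total <= 0.12e6

    def test_deterministic_for_fixed_seed(self):
        a = simulate_genome(3, 500_000, 0.2, seed=5)
        b = simulate_genome(3, 500_000, 0.2, seed=5)
        assert a.chrom_sizes == b.chrom_sizes
        assert a.excluded_regions == b.excluded_regions

    def test_rejects_half_excluded(self):
        with pytest.raises(ValueError):
            simulate_genome(1, 1000, 0.5, seed=0)


class TestSimulateTEAnnotation:
    def test_single_copy_exact_length(self):
        g = simulate_genome(1, 100_000, 0.0, seed=0)
        te = simulate_te_annotation(g, 1, 1, 100, seed=0)
        assert len(te) == 1
        assert len(te.copies[0].interval) == 100

    def test_copies_avoid_excluded_regions_brute_force(self):
        g = simulate_genome(2, 200_000, 0.2, seed=3)
        te = simulate_te_annotation(g, 10, 50, (100, 500), seed=3)
        assert len(te) == 500
        for c in te.copies:
            assert c.interval.end <= g.chrom_sizes[c.interval.chrom]
            for s, e in g.excluded_by_chrom(c.interval.chrom):
                assert not (c.interval.start < e and s < c.interval.end)

    def test_zero_families_empty(self):
        g = simulate_genome(1, 10_000, 0.0, seed=0)
        assert len(simulate_te_annotation(g, 0, 5, 100, seed=0)) == 0

    def test_family_labels_parseable(self):
        g = simulate_genome(1, 500_000, 0.0, seed=0)
        te = simulate_te_annotation(g, 6, 2, 100, seed=0)
        for label in te.families:
            name, superfam, cls = label.split(":")
            assert name and superfam and cls


class TestSimulateGeneAnnotation:
    def test_frac_zero_places_all_genes_beyond_window(self):
        g = simulate_genome(1, 500_000, 0.0, seed=1)
        te = simulate_te_annotation(g, 2, 3, 200, seed=1)
        genes, truth = simulate_gene_annotation(g, 30, te, 0.0, window=5_000, seed=1)
        assert truth.proximal_pairs == set()
        for gene in genes.genes:
            for c in te.copies:
                d = synthetic._point_interval_distance(gene.tss, c.interval)
                assert d > 5_000

    def test_frac_one_records_pair_per_gene(self):
        g = simulate_genome(1, 500_000, 0.0, seed=2)
        te = simulate_te_annotation(g, 1, 5, 200, seed=2)
        genes, truth = simulate_gene_annotation(g, 10, te, 1.0, window=30_000, seed=2)
        assert len(truth.proximal_pairs) == 10
        copies = te.by_id()
        for cid, gid in truth.proximal_pairs:
            gene = genes.by_id()[gid]
            d = synthetic._point_interval_distance(gene.tss, copies[cid].interval)
            assert d <= 30_000

    def test_tss_convention(self):
        g = simulate_genome(1, 500_000, 0.0, seed=3)
        te = simulate_te_annotation(g, 1, 2, 200, seed=3)
        genes, _ = simulate_gene_annotation(g, 50, te, 0.5, seed=3)
        for gene in genes.genes:
            if gene.interval.strand == "+":
                assert gene.tss == gene.interval.start
            else:
                assert gene.tss == gene.interval.end - 1

    def test_window_larger_than_chromosome_rejected(self):
        g = simulate_genome(1, 10_000, 0.0, seed=0)
        te = simulate_te_annotation(g, 1, 1, 100, seed=0)
        with pytest.raises(ValueError):
            simulate_gene_annotation(g, 5, te, 0.5, window=20_000, seed=0)


class TestSimulateCounts:
    def test_poisson_limit_mean(self):
        ids = [f"f{i}" for i in range(10_000)]
        cm, _ = simulate_counts(ids, 2, 100.0, 0.0, seed=1)
        for col in cm.samples:
            assert abs(cm.counts[col].mean() - 100) < 1.0

    def test_fold_change_reflected_in_condition_means(self):
        ids = [f"f{i}" for i in range(200)]
        cm, truth = simulate_counts(ids, 50, 100.0, 0.05, fold_changes={"f0": 4.0}, seed=2)
        a = cm.counts.loc["f0", [c for c in cm.samples if c.startswith("A")]].mean()
        b = cm.counts.loc["f0", [c for c in cm.samples if c.startswith("B")]].mean()
        assert 3.0 < b / a < 5.0
        assert truth.fold_changes == {"f0": 4.0}

    def test_zero_reps_empty(self):
        cm, _ = simulate_counts(["f1"], 0, 10.0, 0.1, seed=0)
        assert cm.counts.shape == (1, 0)

    def test_library_size_factors_scale_means(self):
        ids = [f"f{i}" for i in range(5_000)]
        sf = np.array([1.0, 2.0, 1.0, 1.0])
        cm, _ = simulate_counts(ids, 2, 100.0, 0.0, lib_size_factors=sf, seed=3)
        assert abs(cm.counts["A_2"].mean() / cm.counts["A_1"].mean() - 2.0) < 0.1

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(["f1"], 2, -1.0, 0.1)
        with pytest.raises(ValueError):
            simulate_counts(["f1"], 2, 10.0, -0.5)


class TestSimulatePeaks:
    def test_uniform_placement_matches_chi_square(self):
        g = simulate_genome(1, 1_000_000, 0.0, seed=4)
        te = simulate_te_annotation(g, 2, 10, 300, seed=4)
        peaks, _ = simulate_peaks(g, te, set(), 1.0, 2_000, peak_len=100, seed=4)
        from scipy.stats import chisquare

        starts = np.array([p.interval.start for p in peaks.peaks])
        observed, _ = np.histogram(starts, bins=20, range=(0, 1_000_000))
        _, p = chisquare(observed)
        assert p > 0.01

    def test_enrichment_factor_inflates_near_family_placement(self):
        g = simulate_genome(1, 1_000_000, 0.0, seed=5)
        te = simulate_te_annotation(g, 1, 20, 500, seed=5)  # ~1% of genome
        fam = te.families[0]
        peaks, truth = simulate_peaks(g, te, {fam}, 10.0, 2_000, peak_len=100,
                                      pad=0, seed=5)
        assert truth.enriched_families == {fam}
        near = 0
        for p in peaks.peaks:
            if any(p.interval.overlaps(c.interval) for c in te.copies):
                near += 1
        # uniform expectation: fraction of starts overlapping a copy
        from tereawaken.intervals import StartSpace

        space = StartSpace.for_length(g, 100)
        regions = {}
        for c in te.copies:
            regions.setdefault(c.interval.chrom, []).append(
                (max(0, c.interval.start - 99), c.interval.end)
            )
        q = space.restrict(regions).total / space.total
        assert near >= 5 * q * 2_000

    def test_zero_peaks_empty(self):
        g = simulate_genome(1, 10_000, 0.0, seed=0)
        te = simulate_te_annotation(g, 1, 1, 100, seed=0)
        peaks, _ = simulate_peaks(g, te, set(), 1.0, 0, seed=0)
        assert len(peaks) == 0

    def test_peaks_avoid_excluded_regions(self):
        g = simulate_genome(1, 200_000, 0.2, seed=6)
        te = simulate_te_annotation(g, 1, 5, 200, seed=6)
        peaks, _ = simulate_peaks(g, te, set(), 1.0, 300, peak_len=150, seed=6)
        for p in peaks.peaks:
            for s, e in g.excluded_by_chrom(p.interval.chrom):
                assert not (p.interval.start < e and s < p.interval.end)


class TestSimulateInsertionProfiles:
    def test_full_depth_empties_motif(self):
        pset = simulate_insertion_profiles(200, 50, 10, 0.5, 1.0, seed=1)
        assert pset.counts[:, :, 50:60].sum() == 0

    def test_zero_depth_flat_profile(self):
        pset = simulate_insertion_profiles(1_000, 50, 10, 0.5, 0.0, seed=2)
        center = pset.counts[:, :, 50:60].mean()
        flank = np.concatenate(
            [pset.counts[:, :, :50], pset.counts[:, :, 60:]], axis=2
        ).mean()
        assert abs(center - flank) / flank < 0.05

    def test_seed_reproducibility(self):
        a = simulate_insertion_profiles(50, 30, 8, 0.4, 0.5, seed=9)
        b = simulate_insertion_profiles(50, 30, 8, 0.4, 0.5, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            simulate_insertion_profiles(10, 10, 5, 0.5, 1.5)


class TestSimulateReads:
    def test_read_counts_track_expression(self):
        g = simulate_genome(1, 500_000, 0.0, seed=7)
        te = simulate_te_annotation(g, 2, 5, (300, 400), seed=7)
        expr = {c.copy_id: 20.0 for c in te.copies}
        reads = simulate_reads(te, expr, multimap_frac=0.0, seed=7)
        assert all(r.unique for r in reads)
        assert abs(len(reads) - 200) < 60  # Poisson(20) x 10 copies

    def test_multimappers_stay_within_family(self):
        g = simulate_genome(1, 500_000, 0.0, seed=8)
        te = simulate_te_annotation(g, 2, 5, (300, 400), seed=8)
        copies = te.by_id()
        reads = simulate_reads(te, {c.copy_id: 20.0 for c in te.copies},
                               multimap_frac=1.0, seed=8)
        from oracles import brute_best_copy

        tuples = [(c.copy_id, c.interval.chrom, c.interval.start, c.interval.end)
                  for c in te.copies]
        for r in reads:
            fams = set()
            for locus in r.candidate_loci:
                cid = brute_best_copy((locus.chrom, locus.start, locus.end), tuples)
                assert cid is not None
                fams.add(copies[cid].label)
            assert len(fams) == 1
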