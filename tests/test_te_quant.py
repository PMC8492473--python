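import numpy as np
import pytest

from oracles import brute_best_copy
from tereawaken.annotations import TEAnnotation, TECopy
from tereawaken.intervals import GenomicInterval
from tereawaken.te_quant import (
    AlignedRead,
    count_te_copies,
    count_te_families,
    mixture_log_likelihood,
)


def read(rid, *loci):
    return AlignedRead(rid, [GenomicInterval(c, s, e) for c, s, e in loci])


class TestCountTECopies:
    def test_unique_read_inside_copy(self, toy_te):
        cm = count_te_copies([read("r1", ("chr1", 1100, 1150))], toy_te)
        assert cm.counts.loc["a1", "sample"] == 1
        assert cm.counts.drop("a1").sum().sum() == 0

    def test_multimapper_contributes_nothing(self, toy_te):
        cm = count_te_copies(
            [read("r1", ("chr1", 1100, 1150), ("chr1", 50_100, 50_150))], toy_te
        )
        assert cm.counts.sum().sum() == 0

    def test_largest_overlap_wins_ties_lexicographic(self):
        te = TEAnnotation(
            [
                TECopy("x2", "f", "ERV1", "LTR", GenomicInterval("chr1", 100, 200)),
                TECopy("x1", "f", "ERV1", "LTR", GenomicInterval("chr1", 150, 250)),
            ]
        )
        # overlap 50 bp with x2, 100 bp with x1
        cm = count_te_copies([read("r1", ("chr1", 150, 250))], te)
        assert cm.counts.loc["x1", "sample"] == 1
        # symmetric overlap: lexicographically smaller copy_id wins
        cm2 = count_te_copies([read("r2", ("chr1", 140, 210))], te)
        assert cm2.counts.loc["x1", "sample"] == 1  # 60 vs 60 bp -> x1 < x2

    def test_unknown_chromosome_skipped_and_reported(self, toy_te):
        cm = count_te_copies(
            [read("r1", ("chrUn", 0, 50))], toy_te, known_chroms={"chr1", "chr2"}
        )
        assert cm.meta["skipped_unknown_chrom"] == 1
        assert cm.counts.sum().sum() == 0

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            copies = []
            for i in range(50):
                s = int(rng.integers(0, 40_000))
                copies.append(
                    TECopy(
                        f"c{i:03d}", f"fam{i % 5}", "ERV1", "LTR",
                        GenomicInterval("chr1", s, s + int(rng.integers(50, 600))),
                    )
                )
            te = TEAnnotation(copies)
            reads = []
            for j in range(200):
                s = int(rng.integers(0, 41_000))
                reads.append(read(f"r{j}", ("chr1", s, s + 50)))
            cm = count_te_copies(reads, te)
            tuples = [(c.copy_id, "chr1", c.interval.start, c.interval.end) for c in copies]
            expected = {c.copy_id: 0 for c in copies}
            for r in reads:
                locus = r.candidate_loci[0]
                cid = brute_best_copy((locus.chrom, locus.start, locus.end), tuples)
                if cid:
                    expected[cid] += 1
            assert cm.counts["sample"].to_dict() == expected


class TestCountTEFamilies:
    def test_uniform_split_symmetric(self, toy_te):
        # one ambiguous read hitting famA (a1) and famB (b1)
        cm = count_te_families(
            [read("r1", ("chr1", 1100, 1150), ("chr1", 70_100, 70_150))],
            toy_te,
            mode="uniform",
        )
        assert cm.counts.loc["famA:ERV1:LTR", "sample"] == pytest.approx(0.5)
        assert cm.counts.loc["famB:L1:LINE", "sample"] == pytest.approx(0.5)

    def test_em_assigns_ambiguous_mass_to_dominant_family(self, toy_te):
        reads = [read(f"u{i}", ("chr1", 1100, 1150)) for i in range(9)]
        reads.append(read("u9", ("chr1", 70_100, 70_150)))
        reads += [
            read(f"m{i}", ("chr1", 1100, 1150), ("chr1", 70_100, 70_150))
            for i in range(10)
        ]
        cm = count_te_families(reads, toy_te, mode="em", em_iters=50)
        a = cm.counts.loc["famA:ERV1:LTR", "sample"]
        assert (a - 9) / 10 > 0.8  # ambiguous mass converges toward famA

    def test_no_multimappers_modes_agree(self, toy_te):
        reads = [read(f"r{i}", ("chr1", 1100, 1150)) for i in range(5)]
        u = count_te_families(reads, toy_te, mode="uniform")
        e = count_te_families(reads, toy_te, mode="em")
        assert np.allclose(u.counts.to_numpy(), e.counts.to_numpy())

    def test_mass_conservation_with_sink(self, toy_te):
        reads = [
            read("r1", ("chr1", 1100, 1150)),
            read("r2", ("chr1", 30_000, 30_050)),  # outside any copy -> sink
            read("r3", ("chr1", 1100, 1150), ("chr1", 30_000, 30_050)),
        ]
        for mode in ("uniform", "em"):
            cm = count_te_families(reads, toy_te, mode=mode)
            total = cm.counts["sample"].sum() + cm.meta["non_te_sink"]
            assert total == pytest.approx(len(reads))

    def test_em_likelihood_nondecreasing(self, toy_te):
        rng = np.random.default_rng(4)
        reads = [read(f"u{i}", ("chr1", 1100, 1150)) for i in range(6)]
        reads += [
            read(f"m{i}", ("chr1", 1100, 1150), ("chr1", 70_100, 70_150))
            for i in range(8)
        ]
        lls = []
        for iters in (1, 2, 5, 10, 30):
            cm = count_te_families(reads, toy_te, mode="em", em_iters=iters)
            weights = cm.counts["sample"].to_dict()
            lls.append(mixture_log_likelihood(reads, toy_te, weights))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_copy_counts_bounded_by_family_counts(self, toy_te):
        rng = np.random.default_rng(5)
        reads = []
        for j in range(100):
            s = int(rng.integers(0, 80_000))
            reads.append(read(f"r{j}", ("chr1", s, s + 60)))
        copy_cm = count_te_copies(reads, toy_te)
        fam_cm = count_te_families(reads, toy_te, mode="uniform")
        for fam, cids in toy_te.family_index.items():
            copy_sum = copy_cm.counts.loc[cids, "sample"].sum()
            assert copy_sum <= fam_cm.counts.loc[fam, "sample"] + 1e-9

    def test_invalid_mode_rejected(self, toy_te):
        with pytest.raises(ValueError):
            count_te_families([], toy_te, mode="bogus")
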