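"""Validation experiments: calibration, power, and oracle-agreement studies.

Each function runs a self-contained simulation study against the library
and returns summary numbers.  The overlap-agreement checks compare the
production interval engines against deliberately naive O(n*m) scans kept
in this module (separate code paths from the sorted-array and
interval-tree implementations they check).
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .annotations import TEAnnotation, TECopy
from .config import PipelineConfig
from .counts import CountMatrix
from .differential import classify, nb_test
from .enrichment import cross_with_de, family_enrichment, observed_overlap, pad_te_intervals
from .footprint import fos
from .intervals import GenomeModel, GenomicInterval
from .peaks import Peak, PeakSet, gained_lost, merge_peaks
from .proximity import (
    binomial_vs_null,
    closest_gene,
    proximal_genes,
    resampled_background,
)
from .te_quant import AlignedRead, count_te_copies, count_te_families


# ------------------------------------------------------------ naive oracles
def _naive_union(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    segs = sorted(segs)
    out: list[list[int]] = []
    for s, e in segs:
        placed = False
        for seg in out:
            if s <= seg[1] and seg[0] <= e:
                seg[0], seg[1] = min(seg[0], s), max(seg[1], e)
                placed = True
                break
        if not placed:
            out.append([s, e])
    # repeated passes until stable (naive but obviously correct)
    changed = True
    while changed:
        changed = False
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                a, b = out[i], out[j]
                if a and b and a[0] <= b[1] and b[0] <= a[1]:
                    a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                    out[j] = []
                    changed = True
        out = [seg for seg in out if seg]
    return sorted((s, e) for s, e in out)


def _naive_overlap_events(
    peaks: list[tuple[int, int]], copies: list[tuple[int, int]]
) -> int:
    return sum(1 for ps, pe in peaks for cs, ce in copies if ps < ce and cs < pe)


def _naive_best_copy(
    locus: tuple[int, int], copies: list[tuple[str, int, int]]
) -> str | None:
    best = None
    for cid, s, e in copies:
        ov = min(e, locus[1]) - max(s, locus[0])
        if ov > 0 and (best is None or (-ov, cid) < best):
            best = (-ov, cid)
    return best[1] if best else None


# ------------------------------------------------------ criterion experiments
def overlap_oracle_agreement(n_fixtures: int = 100, seed: int = 0) -> float:
    """Fraction of random fixtures on which the production overlap engines
    (copy counting, consensus merge, family overlap events) agree exactly
    with naive all-pairs scans."""
    rng = np.random.default_rng(seed)
    agree = 0
    for trial in range(n_fixtures):
        n = int(rng.integers(50, 1001))
        m = int(rng.integers(50, 501))
        span = 50_000
        copy_tuples = []
        copies = []
        for i in range(m):
            s = int(rng.integers(0, span))
            e = s + int(rng.integers(50, 800))
            copy_tuples.append((f"c{i:04d}", s, e))
            copies.append(
                TECopy(f"c{i:04d}", f"fam{i % 6}", "ERV1", "LTR",
                       GenomicInterval("chr1", s, e))
            )
        te = TEAnnotation(copies)
        peak_segs = []
        reads = []
        for j in range(n):
            s = int(rng.integers(0, span))
            e = s + int(rng.integers(30, 500))
            peak_segs.append((s, e))
            reads.append(AlignedRead(f"r{j}", [GenomicInterval("chr1", s, e)]))
        ok = True
        # copy counting vs naive largest-overlap assignment
        cm = count_te_copies(reads, te)
        expect = {cid: 0 for cid, _, _ in copy_tuples}
        for s, e in peak_segs:
            cid = _naive_best_copy((s, e), copy_tuples)
            if cid:
                expect[cid] += 1
        ok &= cm.counts["sample"].to_dict() == expect
        # consensus merge vs naive union
        a = PeakSet("a", [Peak(GenomicInterval("chr1", s, e)) for s, e in peak_segs[: n // 2]])
        b = PeakSet("b", [Peak(GenomicInterval("chr1", s, e)) for s, e in peak_segs[n // 2 :]])
        merged = merge_peaks(a, b)
        ok &= [
            (p.interval.start, p.interval.end) for p in merged.peaks
        ] == _naive_union(peak_segs)
        # family overlap events vs naive all-pairs count
        pk = PeakSet("p", [Peak(GenomicInterval("chr1", s, e)) for s, e in peak_segs])
        got = observed_overlap(pk, te)
        for fam in te.families:
            fam_segs = [(c.interval.start, c.interval.end) for c in copies if c.label == fam]
            ok &= got[fam] == _naive_overlap_events(peak_segs, fam_segs)
        agree += bool(ok)
    return agree / n_fixtures


def exact_statistics_max_error(seed: int = 0) -> float:
    """Max |implementation - enumeration/closed form| over the exact tests."""
    import math
    from fractions import Fraction

    from scipy import stats

    from .enrichment import OverlapTotals, enrichment_test
    from .footprint import compare_fos
    from .proximity import observed_overlap_test

    errs = []
    # exact binomial tails (enrichment + proximity paths)
    for k, n, p in [(30, 100, 0.1), (5, 20, 0.1), (1, 10, 0.5), (17, 40, 0.3)]:
        pf = Fraction(p)
        upper = float(
            sum(math.comb(n, i) * pf**i * (1 - pf) ** (n - i) for i in range(k, n + 1))
        )
        got = binomial_vs_null(k, n, p * n)
        errs.append(abs(got - upper))
        r = enrichment_test(
            k, np.full(50, p * n), OverlapTotals(n, 10, 1000, 10, 5)
        )
        if k >= p * n:
            errs.append(abs(r.p_binomial - upper))
    # hypergeometric tail + two-sided Fisher
    for N, K, n, k in [(100, 10, 20, 5), (60, 12, 15, 6), (40, 8, 10, 2)]:
        pmf = lambda i: Fraction(
            math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n)
        )
        upper = float(sum(pmf(i) for i in range(k, min(K, n) + 1)))
        universe = {f"g{i}" for i in range(N)}
        prox = {f"g{i}" for i in range(K)}
        degs = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + n - k)}
        p_f, p_h, k_got = observed_overlap_test(prox, degs, universe)
        assert k_got == k
        errs.append(abs(p_h - upper))
        obs_pmf = pmf(k)
        two_sided = float(
            sum(
                pmf(i)
                for i in range(max(0, n + K - N), min(K, n) + 1)
                if pmf(i) <= obs_pmf
            )
        )
        errs.append(abs(p_f - two_sided))
    # Welch t and paired t against textbook formulas
    rng = np.random.default_rng(seed)
    a = list(rng.normal(10, 2, 5))
    b = list(rng.normal(8, 3, 7))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t_w = (ma - mb) / math.sqrt(se2)
    df_w = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_w = 2 * stats.t.sf(abs(t_w), df_w)
    t_got, p_got = stats.ttest_ind(a, b, equal_var=False)
    errs.append(abs(p_got - p_w))
    # paired t via compare_fos on hand-built FOS records
    from .footprint import FOSRecord

    x = rng.uniform(0.5, 2.0, 12)
    y = x * rng.uniform(0.7, 1.3, 12)
    ra = [FOSRecord(f"s{i}", 0, 0, 0, float(v)) for i, v in enumerate(x)]
    rb = [FOSRecord(f"s{i}", 0, 0, 0, float(v)) for i, v in enumerate(y)]
    _, t_got2, p_got2 = compare_fos(ra, rb)
    d = np.log2(x) - np.log2(y)
    t_exp = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    p_exp = 2 * stats.t.sf(abs(t_exp), len(d) - 1)
    errs.append(abs(t_got2 - t_exp))
    errs.append(abs(p_got2 - p_exp))
    return float(max(errs))


def proximity_null_rejection_rate(
    n_datasets: int = 500, n_resamples: int = 1000, seed: int = 0,
    n_degs: int = 150, n_genes: int = 2000, alpha: float = 0.05,
) -> float:
    """Type-I calibration of the resampled-background binomial test.

    Genes are placed uniformly (independently of TEs) and deregulated
    genes drawn at random, so any association between TE proximity and
    deregulation is spurious; returns the fraction of datasets with
    p < alpha.
    """
    genome = synthetic.simulate_genome(2, 10_000_000, 0.05, seed=seed)
    te = synthetic.simulate_te_annotation(genome, 10, 20, (300, 600), seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    rejections = 0
    for d in range(n_datasets):
        genes, _ = synthetic.simulate_gene_annotation(
            genome, n_genes, te, frac_proximal=None, seed=int(rng.integers(2**31 - 1))
        )
        universe = {g.gene_id for g in genes.genes}
        degs = set(
            np.random.default_rng(int(rng.integers(2**31 - 1))).choice(
                sorted(universe), size=n_degs, replace=False
            )
        )
        assignments = closest_gene(te.copies, genes)
        prox = proximal_genes(assignments, 30_000)
        remaining = universe - degs
        _, null_mean = resampled_background(
            n_degs, remaining, prox, n_resamples=n_resamples,
            seed=int(rng.integers(2**31 - 1)),
        )
        k = len(prox & degs)
        p = binomial_vs_null(k, n_degs, min(null_mean, n_degs))
        rejections += p < alpha
    return rejections / n_datasets


def nb_type_i_rate(
    n_seeds: int = 10, n_features: int = 5000, dispersion: float = 0.1, seed: int = 0
) -> float:
    """Raw p < 0.05 fraction of the NB test under no true fold changes."""
    cfg = PipelineConfig()
    ids = [f"f{i}" for i in range(n_features)]
    rates = []
    for s in range(n_seeds):
        cm, _ = synthetic.simulate_counts(ids, 3, 100.0, dispersion, seed=seed + s)
        res = nb_test(cm, ["A"] * 3 + ["B"] * 3, cfg)
        p = np.array([r.p_value for r in res if r.status != "untested"])
        rates.append(float((p < 0.05).mean()))
    return float(np.mean(rates))


def nb_power_recovery(
    n_features: int = 2000, n_planted: int = 300, seed: int = 0
) -> float:
    """Recovery of planted 4-fold (log2 fc = 2) features at base mean 500,
    dispersion 0.05, 3 vs 3, by the 1.5-fold / p_adj < 0.05 classifier."""
    cfg = PipelineConfig()
    ids = [f"f{i}" for i in range(n_features)]
    fc = {f"f{i}": 4.0 for i in range(n_planted)}
    recovered = []
    for s in range(3):
        cm, _ = synthetic.simulate_counts(
            ids, 3, 500.0, 0.05, fold_changes=fc, seed=seed + s
        )
        res = nb_test(cm, ["A"] * 3 + ["B"] * 3, cfg)
        up, _ = classify(res, cfg.fc_cutoff, cfg.alpha)
        recovered.append(len(up & set(fc)) / len(fc))
    return float(np.mean(recovered))


def enrichment_flag_rate(
    n_seeds: int = 100, enrichment_factor: float = 5.0, n_shuffles: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of seeded runs in which the planted (upregulated and
    peak-enriched) family is flagged by the expression x accessibility join."""
    flagged = 0
    for s in range(n_seeds):
        genome = synthetic.simulate_genome(2, 500_000, 0.05, seed=seed + 7 * s)
        te = synthetic.simulate_te_annotation(genome, 5, 20, (300, 600), seed=seed + 7 * s + 1)
        fam = te.families[0]
        peaks, _ = synthetic.simulate_peaks(
            genome, te, {fam}, enrichment_factor, 150, peak_len=400, pad=1000,
            seed=seed + 7 * s + 2,
        )
        fam_cm, _ = synthetic.simulate_counts(
            te.families, 3, 200.0, 0.05, fold_changes={fam: 4.0},
            seed=seed + 7 * s + 3, kind="te_family",
        )
        res = nb_test(fam_cm, ["A"] * 3 + ["B"] * 3, PipelineConfig())
        up, _ = classify(res)
        enr = family_enrichment(
            te, genome, peaks, pad=1000, n_shuffles=n_shuffles, seed=seed + 7 * s + 4
        )
        table = cross_with_de(enr, up)
        flagged += bool(table.loc[fam, "flagged"])
    return flagged / n_seeds


def shuffle_null_agreement_z(seed: int = 0, n_shuffles: int = 1000) -> float:
    """z-score of the shuffle-null mean against the closed-form
    uniform-placement expectation for a single-copy family."""
    from .enrichment import shuffle_te_null

    genome = GenomeModel({"chr1": 1_000_000})
    L, m, P = 2_000, 200, 500
    te = TEAnnotation(
        [TECopy("c1", "f", "ERV1", "LTR", GenomicInterval("chr1", 0, L))]
    )
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, 999_000, m)
    pk = PeakSet("p", [Peak(GenomicInterval("chr1", int(s), int(s) + P)) for s in starts])
    null = shuffle_te_null(te, genome, pk, n_shuffles=n_shuffles, seed=seed + 1)["f:ERV1:LTR"]
    S = 1_000_000 - L + 1
    expected = float(
        sum((min(s + P - 1, S - 1) - max(0, s - L + 1) + 1) / S for s in starts)
    )
    se = null.std(ddof=1) / np.sqrt(n_shuffles)
    return float((null.mean() - expected) / se)


def resample_null_agreement_z(seed: int = 0, n_resamples: int = 10_000) -> float:
    """z-score of the resampled-background mean against the hypergeometric
    expectation degs_size * |proximal| / |remaining|."""
    remaining = {f"r{i}" for i in range(500)}
    proximal = {f"r{i}" for i in range(80)}
    degs_size = 60
    null, mean = resampled_background(degs_size, remaining, proximal, n_resamples, seed=seed)
    expected = degs_size * 80 / 500
    se = null.std(ddof=1) / np.sqrt(n_resamples)
    return float((mean - expected) / se)


def fos_depth_monotonicity(seed: int = 0, n_sites: int = 200) -> float:
    """Spearman rho between simulated footprint depth and mean FOS."""
    from scipy.stats import spearmanr

    depths = np.linspace(0, 1, 11)
    means = []
    for i, d in enumerate(depths):
        pset = synthetic.simulate_insertion_profiles(
            n_sites, 50, 10, 0.5, float(d), seed=seed + i
        )
        means.append(float(np.mean([r.fos for r in fos(pset, flank_width=35)])))
    rho, _ = spearmanr(depths, means)
    return float(rho)


def partition_and_conservation_checks(seed: int = 0, n_fixtures: int = 50) -> dict:
    """Pipeline invariants: gained/lost/common partition the consensus on
    random fixtures, and family counting conserves read mass."""
    rng = np.random.default_rng(seed)
    partition_ok = 0
    for _ in range(n_fixtures):
        nt, nz = int(rng.integers(5, 120)), int(rng.integers(5, 120))
        mk = lambda n: PeakSet(
            "x",
            [
                Peak(GenomicInterval("chr1", s, s + int(l)))
                for s, l in zip(
                    rng.integers(0, 40_000, n).astype(int),
                    rng.integers(50, 600, n),
                )
            ],
        )
        t, z = mk(nt), mk(nz)
        cons = merge_peaks(t, z)
        gained, lost, common = gained_lost(cons, t, z)
        partition_ok += len(gained) + len(lost) + len(common) == len(cons)
    # read-mass conservation on a synthetic read set with multi-mappers
    genome = synthetic.simulate_genome(1, 500_000, 0.0, seed=seed)
    te = synthetic.simulate_te_annotation(genome, 4, 10, (300, 500), seed=seed + 1)
    reads = synthetic.simulate_reads(
        te, {c.copy_id: 15.0 for c in te.copies}, multimap_frac=0.4, seed=seed + 2
    )
    mass_err = []
    for mode in ("uniform", "em"):
        cm = count_te_families(reads, te, mode=mode)
        total = float(cm.counts["sample"].sum() + cm.meta["non_te_sink"])
        mass_err.append(abs(total - len(reads)))
    return {
        "partition_fraction": partition_ok / n_fixtures,
        "mass_conservation_error": max(mass_err),
    }


def end_to_end(seed: int = 0, n_shuffles: int = 1000, n_resamples: int = 10_000) -> dict:
    """Full default pipeline; returns truth-recovery summaries."""
    from .pipeline import run_default_pipeline

    res = run_default_pipeline(seed=seed, n_shuffles=n_shuffles, n_resamples=n_resamples)
    truth = res["truth"]
    planted = next(iter(truth.enriched_families))
    return {
        "family_recovered": truth.up_families <= res["up_families"],
        "planted_family_flagged": bool(res["crossed"].loc[planted, "flagged"]),
        "proximity_p": res["proximity"].p_binomial_vs_null,
        "fos_p": res["fos_p"],
        "partition_ok": len(res["gained"]) + len(res["lost"]) + len(res["common"])
        == len(res["consensus"]),
        "deg_recall": len(res["detected_degs"] & truth.de_genes) / max(len(truth.de_genes), 1),
    }
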