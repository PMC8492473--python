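"""Proximity of upregulated TE copies to deregulated genes.

Each upregulated copy is assigned to its closest gene TSS (ties broken by
gene sort order, matching closest-feature `-t first` semantics), with the
distance signed relative to the copy's orientation (`-D a` semantics: a
gene downstream of the TE in the TE's reading direction gets a positive
sign).  Copies whose closest TSS lies within a +/-30 kb window define the
proximal-gene list; its overlap with the deregulated-gene set is tested
with a hypergeometric upper tail and a two-sided Fisher exact test, and
against a resampled background: draw |DEG| genes at random from the
remaining genes 10,000 times, record the overlap with the proximal list
each time, and use the mean as the expected count of an exact binomial
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotations import GeneAnnotation, TECopy
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class ProximityResult:
    n_te_copies: int
    proximal_genes: set[str]
    n_observed_overlap: int
    universe_size: int
    p_fisher: float
    p_hypergeom: float
    null_mean_overlap: float
    p_binomial_vs_null: float
    n_resamples: int


def _interval_tss_distance(iv: GenomicInterval, tss: int) -> int:
    """Unsigned bp distance between a TSS point and a half-open interval."""
    if tss < iv.start:
        return iv.start - tss
    if tss >= iv.end:
        return tss - (iv.end - 1)
    return 0


def closest_gene(
    te_copies: list[TECopy], genes: GeneAnnotation
) -> dict[str, tuple[str, int]]:
    """Map copy_id -> (closest gene_id, signed distance).

    Distance 0 when the copy spans the TSS.  Sign: positive when the gene
    lies downstream of the copy in the copy's orientation ('.' treated as
    '+'), negative upstream.  Ties on |distance| go to the first gene in
    (chrom, start, gene_id) order.  Copies on chromosomes without genes
    are omitted (and logged).
    """
    if not genes.genes:
        raise ValueError("gene annotation is empty")
    ordered = sorted(genes.genes, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    by_chrom: dict[str, list] = {}
    for g in ordered:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    tss_sorted: dict[str, tuple[np.ndarray, list]] = {}
    for chrom, gl in by_chrom.items():
        order = sorted(range(len(gl)), key=lambda i: (gl[i].tss, i))
        tss_sorted[chrom] = (np.array([gl[i].tss for i in order]), [gl[i] for i in order])
    out: dict[str, tuple[str, int]] = {}
    unassigned = 0
    for c in te_copies:
        chrom = c.interval.chrom
        if chrom not in tss_sorted:
            unassigned += 1
            continue
        tss_arr, gl = tss_sorted[chrom]
        best = None  # (dist, tss-order index, gene)
        # candidates: the TSS flanking the copy plus any TSS inside it
        lo = int(np.searchsorted(tss_arr, c.interval.start, side="left"))
        hi = int(np.searchsorted(tss_arr, c.interval.end, side="right"))
        for j in range(max(0, lo - 1), min(len(gl), hi + 1)):
            g = gl[j]
            d = _interval_tss_distance(c.interval, g.tss)
            if best is None or d < best[0] or (
                d == best[0]
                and (g.interval.chrom, g.interval.start, g.gene_id)
                < (best[2].interval.chrom, best[2].interval.start, best[2].gene_id)
            ):
                best = (d, j, g)
        assert best is not None
        g = best[2]
        d = best[0]
        te_strand = c.interval.strand if c.interval.strand in {"+", "-"} else "+"
        if d == 0:
            signed = 0
        else:
            downstream_genomic = g.tss >= c.interval.end
            downstream = downstream_genomic if te_strand == "+" else not downstream_genomic
            signed = d if downstream else -d
        out[c.copy_id] = (g.gene_id, signed)
    if unassigned:
        logger.warning("closest_gene: %d copies on chromosomes without genes", unassigned)
    return out


def proximal_genes(
    assignments: dict[str, tuple[str, int]], window: int
) -> set[str]:
    """Genes whose TSS lies within `window` bp (inclusive) of an assigned copy."""
    if window <= 0:
        raise ValueError("window must be positive")
    return {gene for gene, d in assignments.values() if abs(d) <= window}


def observed_overlap_test(
    proximal: set[str], degs: set[str], universe: set[str]
) -> tuple[float, float, int]:
    """(two-sided Fisher p, hypergeometric upper-tail p, overlap count)."""
    if not universe:
        raise ValueError("empty gene universe")
    if not proximal <= universe or not degs <= universe:
        raise ValueError("proximal and DEG sets must be subsets of the universe")
    N, K, n = len(universe), len(proximal), len(degs)
    k = len(proximal & degs)
    p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n))
    table = [[k, K - k], [n - k, N - K - (n - k)]]
    _, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    return float(p_fisher), p_hyper, k


def resampled_background(
    degs_size: int,
    remaining: set[str],
    proximal: set[str],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null overlap counts from resampling DEG-sized gene sets.

    Each resample draws `degs_size` genes without replacement from
    `remaining` and records the overlap with `proximal`; returns all
    overlaps and their mean (the expected count for the binomial test).
    """
    if degs_size > len(remaining):
        raise ValueError("degs_size exceeds the background gene pool")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if degs_size == 0:
        return np.zeros(n_resamples, dtype=np.int64), 0.0
    rng = np.random.default_rng(seed)
    pool = np.array(sorted(remaining))
    is_prox = np.isin(pool, np.array(sorted(proximal))) if proximal else np.zeros(
        len(pool), dtype=bool
    )
    # random-key selection: the degs_size smallest keys per row are a uniform
    # without-replacement draw; chunked to bound memory
    overlaps = np.empty(n_resamples, dtype=np.int64)
    chunk = max(1, min(n_resamples, 20_000_000 // max(len(pool), 1)))
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        keys = rng.random((m, len(pool)))
        idx = np.argpartition(keys, degs_size - 1, axis=1)[:, :degs_size]
        overlaps[done : done + m] = is_prox[idx].sum(axis=1)
        done += m
    return overlaps, float(overlaps.mean())


def binomial_vs_null(observed: int, degs_size: int, null_mean: float) -> float:
    """Exact binomial upper tail P(X >= observed), n = degs_size,
    p = null_mean / degs_size."""
    if not (0 <= null_mean <= degs_size):
        raise ValueError("null_mean must lie in [0, degs_size]")
    if observed == 0:
        return 1.0
    if null_mean == 0:
        logger.warning("binomial_vs_null: degenerate null (mean 0) with observed > 0")
        return 0.0
    p = null_mean / degs_size
    return float(stats.binom.sf(observed - 1, degs_size, p))


def proximity_analysis(
    up_copies: list[TECopy],
    genes: GeneAnnotation,
    degs: set[str],
    window: int = 30_000,
    n_resamples: int = 10_000,
    seed: int = 0,
    background: str = "non-deg",
) -> ProximityResult:
    """Full proximity pipeline for a set of upregulated TE copies."""
    if background not in {"non-deg", "all"}:
        raise ValueError("background must be 'non-deg' or 'all'")
    universe = {g.gene_id for g in genes.genes}
    assignments = closest_gene(up_copies, genes)
    proximal = proximal_genes(assignments, window)
    p_fisher, p_hyper, k = observed_overlap_test(proximal, degs, universe)
    remaining = universe - degs if background == "non-deg" else universe
    null, null_mean = resampled_background(
        len(degs), remaining, proximal, n_resamples=n_resamples, seed=seed
    )
    p_binom = binomial_vs_null(k, len(degs), min(null_mean, len(degs)))
    return ProximityResult(
        n_te_copies=len(up_copies),
        proximal_genes=proximal,
        n_observed_overlap=k,
        universe_size=len(universe),
        p_fisher=p_fisher,
        p_hypergeom=p_hyper,
        null_mean_overlap=null_mean,
        p_binomial_vs_null=p_binom,
        n_resamples=n_resamples,
    )
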