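"""TE-family enrichment in accessible chromatin against a shuffle null.

Each TE copy is padded by +/-1 kb (configurable) and the number of
(peak, copy) overlap events per family is counted.  The null relocates
every padded copy uniformly within its own chromosome's allowed space
(chromosome minus excluded regions), preserving lengths, and recounts —
the empirical distribution of family overlap counts under random TE
placement given the family's genomic abundance.  Significance is
summarized two ways: an exact binomial tail with n = number of peaks and
p = null_mean / n_peaks, and a hypergeometric tail on base pairs (urn =
genome bp, successes = padded family bp, draws = total peak bp, observed
= overlap bp).  Families are then crossed with the differential
expression calls: the interesting hits are families both deregulated and
enriched/depleted in (gained) accessible chromatin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import TEAnnotation, TECopy
from .intervals import GenomeModel, GenomicInterval, StartSpace, merge_segments
from .peaks import PeakSet


@dataclass
class EnrichmentResult:
    family: str
    n_copies: int
    observed_hits: int
    null_mean: float
    null_sd: float
    p_binomial: float
    p_hypergeometric: float
    direction: str  # enriched | depleted | ns


@dataclass
class OverlapTotals:
    """Base-pair bookkeeping for the hypergeometric variant."""

    n_peaks: int
    family_padded_bp: int
    genome_bp: int
    total_peak_bp: int
    overlap_bp: int


def pad_te_intervals(te: TEAnnotation, pad: int, genome: GenomeModel) -> TEAnnotation:
    """Extend every copy by `pad` bp on both sides, clipped to the chromosome."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    padded = []
    for c in te.copies:
        clen = genome.chrom_sizes[c.interval.chrom]
        iv = GenomicInterval(
            c.interval.chrom,
            max(0, c.interval.start - pad),
            min(clen, c.interval.end + pad),
            c.interval.strand,
        )
        padded.append(TECopy(c.copy_id, c.family, c.superfamily, c.te_class, iv))
    return TEAnnotation(padded)


def observed_overlap(peaks: PeakSet, padded_te: TEAnnotation) -> dict[str, int]:
    """(peak, copy) overlap events per family; a peak overlapping k copies
    of a family contributes k events."""
    arrays = peaks.by_chrom_arrays()
    out = {f: 0 for f in padded_te.families}
    for c in padded_te.copies:
        if c.interval.chrom not in arrays:
            continue
        starts, ends = arrays[c.interval.chrom]
        n = int(
            np.searchsorted(starts, c.interval.end, side="left")
            - np.searchsorted(ends, c.interval.start, side="right")
        )
        out[c.label] += n
    return out


def _family_padded_segments(
    padded_te: TEAnnotation, family: str
) -> dict[str, list[tuple[int, int]]]:
    segs: dict[str, list[tuple[int, int]]] = {}
    for c in padded_te.copies:
        if c.label == family:
            segs.setdefault(c.interval.chrom, []).append((c.interval.start, c.interval.end))
    return {chrom: merge_segments(s) for chrom, s in segs.items()}


def shuffle_te_null(
    padded_te: TEAnnotation,
    genome: GenomeModel,
    peaks: PeakSet,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-family overlap-event counts under uniform same-chromosome
    relocation of every padded copy (lengths preserved; shuffled copies
    may overlap each other)."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    arrays = peaks.by_chrom_arrays()
    families = padded_te.families
    null = {f: np.zeros(n_shuffles, dtype=np.int64) for f in families}
    # group copies by (chromosome, length) so placement is vectorized
    spaces: dict[tuple[str, int], StartSpace] = {}
    for c in padded_te.copies:
        L = len(c.interval)
        key = (c.interval.chrom, L)
        if key not in spaces:
            windows = [
                (c.interval.chrom, s, e - L + 1)
                for s, e in genome.allowed_segments(c.interval.chrom)
                if e - s >= L
            ]
            space = StartSpace(windows)
            if space.total == 0:
                raise RuntimeError(
                    f"no room to shuffle a {L} bp padded copy on {c.interval.chrom}"
                )
            spaces[key] = space
        L_check = len(c.interval)
        assert L_check == L  # lengths preserved by construction
        space = spaces[key]
        new_starts = space.sample_positions(rng, n_shuffles)  # (n_shuffles,)
        if c.interval.chrom in arrays:
            starts, ends = arrays[c.interval.chrom]
            hits = np.searchsorted(starts, new_starts + L, side="left") - np.searchsorted(
                ends, new_starts, side="right"
            )
        else:
            hits = np.zeros(n_shuffles, dtype=np.int64)
        null[c.label] += hits
    return null


def enrichment_test(
    observed: int,
    null: np.ndarray,
    totals: OverlapTotals,
    alpha: float = 0.05,
    family: str = "",
    n_copies: int = 0,
) -> EnrichmentResult:
    """Binomial and hypergeometric tails for one family versus its null."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empty null distribution")
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    if null_mean == 0 and observed == 0:
        return EnrichmentResult(
            family, n_copies, observed, null_mean, null_sd, 1.0, 1.0, "ns"
        )
    p0 = min(null_mean / totals.n_peaks, 1.0) if totals.n_peaks > 0 else 0.0
    if observed >= null_mean:
        p_binom = float(stats.binom.sf(observed - 1, totals.n_peaks, p0))
        hyper_tail = "upper"
    else:
        p_binom = float(stats.binom.cdf(observed, totals.n_peaks, p0))
        hyper_tail = "lower"
    M, n_succ, N = totals.genome_bp, totals.family_padded_bp, totals.total_peak_bp
    k = totals.overlap_bp
    if hyper_tail == "upper":
        p_hyper = float(stats.hypergeom.sf(k - 1, M, n_succ, N))
    else:
        p_hyper = float(stats.hypergeom.cdf(k, M, n_succ, N))
    direction = "ns"
    if p_binom < alpha:
        direction = "enriched" if observed >= null_mean else "depleted"
    return EnrichmentResult(
        family, n_copies, observed, null_mean, null_sd, p_binom, p_hyper, direction
    )


def overlap_bp(peaks: PeakSet, segments: dict[str, list[tuple[int, int]]]) -> int:
    """Total bp of peaks covered by the (merged) segments."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks.peaks:
        by_chrom.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
    for chrom, plist in by_chrom.items():
        segs = segments.get(chrom, [])
        if not segs:
            continue
        seg_starts = np.array([s for s, _ in segs])
        seg_ends = np.array([e for _, e in segs])
        for ps, pe in plist:
            lo = np.maximum(seg_starts, ps)
            hi = np.minimum(seg_ends, pe)
            total += int(np.maximum(hi - lo, 0).sum())
    return total


def family_enrichment(
    te: TEAnnotation,
    genome: GenomeModel,
    peaks: PeakSet,
    pad: int = 1000,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Full per-family enrichment analysis: pad, observe, shuffle, test."""
    padded = pad_te_intervals(te, pad, genome)
    obs = observed_overlap(peaks, padded)
    null = shuffle_te_null(padded, genome, peaks, n_shuffles=n_shuffles, seed=seed)
    total_peak_bp = sum(len(p.interval) for p in peaks.peaks)
    genome_bp = genome.total_size()
    fam_sizes = {f: len(ids) for f, ids in padded.family_index.items()}
    results = []
    for fam in padded.families:
        segs = _family_padded_segments(padded, fam)
        fam_bp = sum(e - s for ss in segs.values() for s, e in ss)
        totals = OverlapTotals(
            n_peaks=len(peaks),
            family_padded_bp=fam_bp,
            genome_bp=genome_bp,
            total_peak_bp=total_peak_bp,
            overlap_bp=overlap_bp(peaks, segs),
        )
        results.append(
            enrichment_test(
                obs[fam], null[fam], totals, alpha=alpha,
                family=fam, n_copies=fam_sizes[fam],
            )
        )
    return results


def cross_with_de(
    enrichment: list[EnrichmentResult],
    de_up: set[str],
    de_down: set[str] = frozenset(),
) -> pd.DataFrame:
    """Join accessibility enrichment with differential expression calls.

    A family is flagged when it is simultaneously differentially expressed
    and enriched/depleted in the tested peak set.
    """
    rows = []
    for r in enrichment:
        de_status = "up" if r.family in de_up else ("down" if r.family in de_down else "ns")
        rows.append(
            {
                "family": r.family,
                "n_copies": r.n_copies,
                "observed_hits": r.observed_hits,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "p_binomial": r.p_binomial,
                "p_hypergeometric": r.p_hypergeometric,
                "accessibility": r.direction,
                "expression": de_status,
                "flagged": r.direction != "ns" and de_status != "ns",
            }
        )
    return pd.DataFrame(rows).set_index("family")
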