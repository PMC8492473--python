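"""Tn5 digital footprinting: insertion shifting, strand-split average
profiles, footprint occupancy scores (FOS), and the paired condition test.

The Tn5 transposase inserts with a 9-bp staggered duplication, so ATAC
fragment 5' ends are shifted +4 bp on the + strand and -5 bp on the -
strand to centre the insertion event on the transposition site.  A bound
motif protects its span from insertion, producing a local depression of
the insertion profile; the FOS summarizes this per site as a
centre-to-flank ratio

    fos = (C + 1) / max(L, 1) + (C + 1) / max(R, 1)

with C the insertion count inside the motif span and L, R the counts in
fixed-width windows immediately left and right.  Lower FOS means deeper
protection (an occupied motif).  Condition comparisons are paired
two-tailed t-tests on log2(FOS), pairing sites by id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class FootprintProfileSet:
    """Per-site, per-strand insertion counts over [-flank, motif, +flank]."""

    sites: list[GenomicInterval]
    counts: np.ndarray  # shape (n_sites, 2, motif_len + 2*flank); [:,0]=+ strand
    flank: int
    motif_len: int

    def __post_init__(self) -> None:
        width = self.motif_len + 2 * self.flank
        if self.counts.shape != (len(self.sites), 2, width):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({len(self.sites)}, 2, {width})"
            )
        if (self.counts < 0).any():
            raise ValueError("negative insertion counts")

    def average_profile(self, normalize: str = "none") -> np.ndarray:
        """Strand-split per-position mean across sites; shape (2, width)."""
        return aggregate_counts(self.counts, normalize=normalize)


@dataclass
class FOSRecord:
    site_id: str
    center_count: int
    left_flank_count: int
    right_flank_count: int
    fos: float


def shift_insertions(
    fragments: list[tuple[GenomicInterval, str]],
    chrom_sizes: dict[str, int] | None = None,
    shift: tuple[int, int] = (4, -5),
) -> tuple[list[tuple[str, int, str]], int]:
    """Convert fragment 5' ends to Tn5 insertion positions.

    + strand fragments yield an insertion at start + 4; - strand fragments
    at end + (-5) (half-open end).  Returns (insertions, n_dropped) where
    insertions are (chrom, position, strand) and dropped events fell
    outside the chromosome after shifting.
    """
    plus_shift, minus_shift = shift
    out: list[tuple[str, int, str]] = []
    dropped = 0
    for iv, strand in fragments:
        if strand == "+":
            pos = iv.start + plus_shift
        elif strand == "-":
            pos = iv.end + minus_shift
        else:
            raise ValueError(f"fragment strand must be + or -, got {strand!r}")
        limit = chrom_sizes.get(iv.chrom) if chrom_sizes else None
        if pos < 0 or (limit is not None and pos >= limit):
            dropped += 1
            continue
        out.append((iv.chrom, pos, strand))
    if dropped:
        logger.warning("shift_insertions: dropped %d out-of-bounds events", dropped)
    return out, dropped


def aggregate_counts(counts: np.ndarray, normalize: str = "none") -> np.ndarray:
    """Average (n_sites, 2, width) counts to a (2, width) profile."""
    if counts.shape[0] == 0:
        raise ValueError("no sites to aggregate")
    prof = counts.mean(axis=0).astype(float)
    if normalize == "per-bp-rate":
        for s in range(2):
            total = prof[s].sum()
            if total > 0:
                prof[s] /= total
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return prof


def profile_from_insertions(
    insertions: list[tuple[str, int, str]],
    sites: list[GenomicInterval],
    flank: int,
) -> FootprintProfileSet:
    """Bin insertion events into per-site strand-split windows.

    Every site window spans [site.start - flank, site.end + flank); all
    sites must share one motif length.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not sites:
        raise ValueError("no sites given")
    motif_lens = {len(s) for s in sites}
    if len(motif_lens) != 1:
        raise ValueError("sites must share one motif length")
    motif_len = motif_lens.pop()
    width = motif_len + 2 * flank
    counts = np.zeros((len(sites), 2, width), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, strand in insertions:
        by_chrom.setdefault(chrom, []).append((pos, 0 if strand == "+" else 1))
    for i, site in enumerate(sites):
        lo = site.start - flank
        for pos, s in by_chrom.get(site.chrom, ()):
            off = pos - lo
            if 0 <= off < width:
                counts[i, s, off] += 1
    return FootprintProfileSet(sites, counts, flank, motif_len)


def aggregate_profile(
    insertions: list[tuple[str, int, str]],
    sites: list[GenomicInterval],
    flank: int,
    normalize: str = "none",
) -> np.ndarray:
    """Strand-split average insertion profile around motif sites."""
    pset = profile_from_insertions(insertions, sites, flank)
    return pset.average_profile(normalize=normalize)


def fos(profile_set: FootprintProfileSet, flank_width: int = 35) -> list[FOSRecord]:
    """Footprint occupancy score per site; lower = deeper footprint."""
    if flank_width < 1:
        raise ValueError("flank_width must be >= 1")
    if flank_width > profile_set.flank:
        raise ValueError("flank_width exceeds the profiled flank")
    f = profile_set.flank
    m = profile_set.motif_len
    both = profile_set.counts.sum(axis=1)  # strands pooled, (n_sites, width)
    records = []
    for i, site in enumerate(profile_set.sites):
        c = int(both[i, f : f + m].sum())
        left = int(both[i, f - flank_width : f].sum())
        right = int(both[i, f + m : f + m + flank_width].sum())
        score = (c + 1) / max(left, 1) + (c + 1) / max(right, 1)
        records.append(FOSRecord(f"site_{i:05d}", c, left, right, score))
    return records


def compare_fos(
    fos_a: list[FOSRecord], fos_b: list[FOSRecord]
) -> tuple[float, float, float]:
    """Paired two-tailed t-test on log2(FOS), sites paired by id.

    Returns (mean log2(a) - log2(b) difference, t statistic, p value).
    A negative mean difference means condition a has deeper footprints.
    """
    if len(fos_a) != len(fos_b):
        raise ValueError("FOS lists must pair one-to-one")
    if len(fos_a) < 2:
        raise ValueError("need >= 2 paired sites")
    b_by_id = {r.site_id: r for r in fos_b}
    try:
        pairs = [(r.fos, b_by_id[r.site_id].fos) for r in fos_a]
    except KeyError as e:
        raise ValueError(f"site {e} missing from second condition") from e
    a = np.log2([p[0] for p in pairs])
    b = np.log2([p[1] for p in pairs])
    diff = a - b
    if np.allclose(diff, 0):
        return 0.0, 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(diff.mean()), float(t), float(p)
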