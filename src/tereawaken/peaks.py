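"""Peak-set operations: consensus merging, gained/lost/common partition,
size filtering, and count-based differential accessibility.

Gained peaks for a time point versus baseline are built in two steps, the
way bedtools users do it: merge the two peak lists into disjoint consensus
regions (overlapping or bookended intervals fused), then label each
consensus region by which input sets it overlaps.  A region overlapping
the later time point but not baseline is *gained*; the reverse is *lost*;
both is *common*.  Overlap means >= 1 shared bp, so bookended intervals
merge in the consensus but do not count as overlapping for the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .counts import CountMatrix
from .intervals import GenomicInterval


@dataclass
class Peak:
    interval: GenomicInterval
    score: float = 0.0


@dataclass
class PeakSet:
    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.peaks:
            if not np.isfinite(p.score):
                raise ValueError("non-finite peak score")
        self.peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def by_chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Sorted start/end arrays per chromosome, for overlap queries."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by: dict[str, list[tuple[int, int]]] = {}
        for p in self.peaks:
            by.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
        for chrom, segs in by.items():
            starts = np.array(sorted(s for s, _ in segs), dtype=np.int64)
            ends = np.array(sorted(e for _, e in segs), dtype=np.int64)
            out[chrom] = (starts, ends)
        return out


def merge_peaks(a: PeakSet, b: PeakSet, label: str | None = None) -> PeakSet:
    """Union of two peak sets with overlapping/bookended intervals fused.

    Scores are not propagated (merged regions get score 0), matching
    coordinate-only consensus construction.
    """
    by: dict[str, list[tuple[int, int]]] = {}
    for ps in (a, b):
        for p in ps.peaks:
            by.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
    merged: list[Peak] = []
    for chrom in sorted(by):
        segs = sorted(by[chrom])
        cur_s, cur_e = segs[0]
        for s, e in segs[1:]:
            if s <= cur_e:  # overlap or bookended: fuse
                cur_e = max(cur_e, e)
            else:
                merged.append(Peak(GenomicInterval(chrom, cur_s, cur_e)))
                cur_s, cur_e = s, e
        merged.append(Peak(GenomicInterval(chrom, cur_s, cur_e)))
    return PeakSet(label or f"consensus({a.label},{b.label})", merged)


def _overlaps_any(iv: GenomicInterval, arrays: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    if iv.chrom not in arrays:
        return False
    starts, ends = arrays[iv.chrom]
    # number of peaks with start < iv.end minus those with end <= iv.start
    n = np.searchsorted(starts, iv.end, side="left") - np.searchsorted(
        ends, iv.start, side="right"
    )
    return n > 0


def gained_lost(
    consensus: PeakSet, peaks_t: PeakSet, peaks_0: PeakSet
) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Partition consensus regions into (gained, lost, common) versus baseline."""
    cons_arrays = consensus.by_chrom_arrays()
    for ps in (peaks_t, peaks_0):
        for p in ps.peaks:
            if not _overlaps_any(p.interval, cons_arrays):
                raise ValueError(
                    f"consensus does not cover peak {p.interval} of {ps.label}; "
                    "pass merge_peaks(peaks_t, peaks_0) as consensus"
                )
    t_arrays = peaks_t.by_chrom_arrays()
    z_arrays = peaks_0.by_chrom_arrays()
    gained, lost, common = [], [], []
    for p in consensus.peaks:
        in_t = _overlaps_any(p.interval, t_arrays)
        in_0 = _overlaps_any(p.interval, z_arrays)
        if in_t and in_0:
            common.append(p)
        elif in_t:
            gained.append(p)
        elif in_0:
            lost.append(p)
        else:
            raise ValueError(
                f"consensus region {p.interval} overlaps neither input peak set"
            )
    return (
        PeakSet(f"gained({peaks_t.label})", gained),
        PeakSet(f"lost({peaks_t.label})", lost),
        PeakSet(f"common({peaks_t.label})", common),
    )


def filter_min_length(peaks: PeakSet, min_len: int) -> PeakSet:
    """Discard peaks shorter than min_len (length >= min_len retained)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [p for p in peaks.peaks if len(p.interval) >= min_len]
    return PeakSet(peaks.label, kept)


def peak_count_significance(
    consensus: PeakSet,
    peak_counts: pd.DataFrame,
    condition_labels: list[str],
    config: PipelineConfig | None = None,
    **kwargs,
):
    """NB differential test on per-peak read counts over consensus regions.

    `peak_counts` rows are peak ids (one per consensus region), columns are
    samples.  Returns the per-peak results; "gained" significance is
    status == "up".
    """
    from .differential import nb_test

    if len(consensus) == 0 or peak_counts.empty:
        return []
    if len(peak_counts) != len(consensus):
        raise ValueError("one count row per consensus peak required")
    cm = CountMatrix(peak_counts, "peak")
    return nb_test(cm, condition_labels, config or PipelineConfig(), **kwargs)
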