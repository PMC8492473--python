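"""Genomic intervals, genome models, and uniform-placement sampling spaces.

All coordinates are 0-based half-open ([start, end)), the native BED
convention.  A :class:`GenomeModel` is a set of chromosome sizes plus
*excluded* regions (assembly gaps, blacklist, chrM-like contigs) that are
barred from random placement; the complement defines the shuffle space used
by the peak simulator and the TE shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

Strand = str  # one of "+", "-", "."

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_segments(segments: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended (gap 0) [start, end) segments."""
    segs = sorted(segments)
    merged: list[tuple[int, int]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def complement_segments(
    segments: Sequence[tuple[int, int]], chrom_len: int
) -> list[tuple[int, int]]:
    """Complement of merged segments within [0, chrom_len)."""
    out: list[tuple[int, int]] = []
    pos = 0
    for s, e in merge_segments(segments):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < chrom_len:
        out.append((pos, chrom_len))
    return out


def intersect_segments(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two merged, sorted segment lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_segments(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """a minus b, both merged and sorted."""
    if not a:
        return []
    span_end = max(e for _, e in a)
    return intersect_segments(a, complement_segments(b, span_end))


@dataclass
class GenomeModel:
    """Chromosome sizes plus regions excluded from random placement."""

    chrom_sizes: dict[str, int]
    excluded_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        normalized: list[GenomicInterval] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.excluded_regions:
            if iv.chrom not in self.chrom_sizes:
                raise ValueError(f"excluded region on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"excluded region {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self.chrom_sizes[iv.chrom]}"
                )
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom in sorted(by_chrom):
            for s, e in merge_segments(by_chrom[chrom]):
                normalized.append(GenomicInterval(chrom, s, e))
        self.excluded_regions = normalized

    def excluded_by_chrom(self, chrom: str) -> list[tuple[int, int]]:
        return [
            (iv.start, iv.end) for iv in self.excluded_regions if iv.chrom == chrom
        ]

    def allowed_segments(self, chrom: str) -> list[tuple[int, int]]:
        """Chromosome minus excluded regions: the shuffle/placement space."""
        return complement_segments(self.excluded_by_chrom(chrom), self.chrom_sizes[chrom])

    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def allowed_size(self) -> int:
        return self.total_size() - sum(len(iv) for iv in self.excluded_regions)


class StartSpace:
    """Uniform sampler over valid start positions for fixed-length features.

    Valid starts are windows [s, e - L + 1) within each allowed segment
    [s, e) that can contain a length-L feature.  Sampling is uniform over
    the union of windows across chromosomes.
    """

    def __init__(self, windows: list[tuple[str, int, int]]):
        # windows: (chrom, lo, hi) half-open ranges of valid start positions
        self.windows = [w for w in windows if w[2] > w[1]]
        sizes = np.array([hi - lo for _, lo, hi in self.windows], dtype=np.int64)
        self._cum = np.concatenate([[0], np.cumsum(sizes)])
        self.total = int(self._cum[-1])

    @classmethod
    def for_length(
        cls, genome: GenomeModel, length: int, chroms: Sequence[str] | None = None
    ) -> "StartSpace":
        windows = []
        for chrom in chroms if chroms is not None else sorted(genome.chrom_sizes):
            for s, e in genome.allowed_segments(chrom):
                if e - s >= length:
                    windows.append((chrom, s, e - length + 1))
        return cls(windows)

    def restrict(self, regions: dict[str, list[tuple[int, int]]]) -> "StartSpace":
        """Start positions also falling inside per-chromosome regions."""
        out = []
        for chrom, lo, hi in self.windows:
            for s, e in intersect_segments([(lo, hi)], merge_segments(regions.get(chrom, []))):
                out.append((chrom, s, e))
        return StartSpace(out)

    def subtract(self, other: "StartSpace") -> "StartSpace":
        """Start positions in self but not in other."""
        other_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, lo, hi in other.windows:
            other_by_chrom.setdefault(chrom, []).append((lo, hi))
        out = []
        for chrom, lo, hi in self.windows:
            for s, e in subtract_segments(
                [(lo, hi)], merge_segments(other_by_chrom.get(chrom, []))
            ):
                out.append((chrom, s, e))
        return StartSpace(out)

    def sample(self, rng: np.random.Generator, size: int) -> list[tuple[str, int]]:
        """Draw `size` (chrom, start) pairs uniformly over valid starts."""
        if self.total == 0:
            raise ValueError("empty start space: no room to place features")
        r = rng.integers(0, self.total, size=size)
        idx = np.searchsorted(self._cum, r, side="right") - 1
        return [
            (self.windows[i][0], int(self.windows[i][1] + (r[k] - self._cum[i])))
            for k, i in enumerate(idx)
        ]

    def sample_positions(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Vectorized variant for single-chromosome spaces: start positions only."""
        if self.total == 0:
            raise ValueError("empty start space: no room to place features")
        r = rng.integers(0, self.total, size=size)
        idx = np.searchsorted(self._cum, r, side="right") - 1
        los = np.array([w[1] for w in self.windows], dtype=np.int64)
        return los[idx] + (r - self._cum[idx])
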