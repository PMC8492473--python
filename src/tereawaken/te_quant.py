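"""Family- and copy-level TE read counting.

Copy-level quantification uses uniquely aligned reads only (multi-mappers
carry no positional evidence at copy resolution): a unique read increments
the copy it overlaps by >= 1 bp; if it overlaps several copies it goes to
the copy with the largest overlap, ties broken by lexicographically
smallest copy_id.  Counting is unstranded.

Family-level quantification keeps multi-mappers: a read with several
candidate loci distributes one unit of weight across the families those
loci fall in, either uniformly or by EM reweighting proportional to the
current family abundances (the multi-mapper model used by family-level TE
quantifiers).  Candidate loci outside any TE copy feed an explicit
"non-TE" sink so read mass is conserved and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotations import TEAnnotation
from .counts import CountMatrix
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

SINK = "__non_TE__"


@dataclass
class AlignedRead:
    read_id: str
    candidate_loci: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.candidate_loci:
            raise ValueError(f"read {self.read_id} has no candidate loci")

    @property
    def n_hits(self) -> int:
        return len(self.candidate_loci)

    @property
    def unique(self) -> bool:
        return self.n_hits == 1


def _copy_trees(te: TEAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for c in te.copies:
        trees.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end, c
        )
    return trees


def _best_copy(locus: GenomicInterval, trees: dict[str, IntervalTree]):
    """Copy with the largest overlap; ties to the smallest copy_id."""
    tree = trees.get(locus.chrom)
    if tree is None:
        return None
    best = None
    best_key = None
    for hit in tree.overlap(locus.start, locus.end):
        c = hit.data
        ov = c.interval.overlap_length(locus)
        key = (-ov, c.copy_id)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best


def count_te_copies(
    reads: list[AlignedRead],
    te: TEAnnotation,
    known_chroms: set[str] | None = None,
    sample_name: str = "sample",
) -> CountMatrix:
    """Unique-read copy-level counts (multi-mappers contribute nothing)."""
    trees = _copy_trees(te)
    counts = {c.copy_id: 0 for c in te.copies}
    skipped_unknown = 0
    for read in reads:
        if not read.unique:
            continue
        locus = read.candidate_loci[0]
        if known_chroms is not None and locus.chrom not in known_chroms:
            skipped_unknown += 1
            continue
        copy = _best_copy(locus, trees)
        if copy is not None:
            counts[copy.copy_id] += 1
    if skipped_unknown:
        logger.warning(
            "count_te_copies: skipped %d reads on unknown chromosomes", skipped_unknown
        )
    df = pd.DataFrame(
        {sample_name: pd.Series(counts, dtype=np.int64)}
    ).rename_axis("feature_id")
    df = df.loc[[c.copy_id for c in te.copies]]
    return CountMatrix(df, "te_copy", meta={"skipped_unknown_chrom": skipped_unknown})


def count_te_families(
    reads: list[AlignedRead],
    te: TEAnnotation,
    mode: str = "em",
    em_iters: int = 100,
    sample_name: str = "sample",
    tol: float = 1e-8,
) -> CountMatrix:
    """Family-level counts with fractional multi-mapper assignment.

    mode="uniform" splits each ambiguous read equally over its candidate
    families; mode="em" iteratively reassigns ambiguous mass proportional
    to current family abundances (uniform initialization, stopping after
    `em_iters` rounds or when the largest family-weight change < tol).
    Column sums plus the non-TE sink equal the number of assigned reads.
    """
    if mode not in {"uniform", "em"}:
        raise ValueError(f"mode must be 'uniform' or 'em', got {mode!r}")
    if mode == "em" and em_iters < 1:
        raise ValueError("em_iters must be >= 1")
    trees = _copy_trees(te)
    families = te.families
    fam_pos = {f: i for i, f in enumerate(families)}
    n_fam = len(families)
    sink_pos = n_fam  # sink participates in the mixture like a family

    unique_counts = np.zeros(n_fam + 1)
    ambiguous: list[np.ndarray] = []  # candidate indices (deduplicated) per read
    for read in reads:
        cand: set[int] = set()
        for locus in read.candidate_loci:
            copy = _best_copy(locus, trees)
            cand.add(fam_pos[copy.label] if copy is not None else sink_pos)
        if read.unique or len(cand) == 1:
            unique_counts[cand.pop()] += 1
        else:
            ambiguous.append(np.fromiter(cand, dtype=np.int64))

    weights = np.zeros(n_fam + 1)
    if ambiguous:
        if mode == "uniform":
            for cand in ambiguous:
                weights[cand] += 1.0 / len(cand)
        else:
            # uniform initialization of the ambiguous mass
            for cand in ambiguous:
                weights[cand] += 1.0 / len(cand)
            for _ in range(em_iters):
                abundance = unique_counts + weights
                new = np.zeros_like(weights)
                for cand in ambiguous:
                    a = abundance[cand]
                    total = a.sum()
                    if total == 0:
                        new[cand] += 1.0 / len(cand)
                    else:
                        new[cand] += a / total
                if np.max(np.abs(new - weights)) < tol:
                    weights = new
                    break
                weights = new
    totals = unique_counts + weights
    if totals[sink_pos] > 0:
        logger.info(
            "count_te_families: %.2f read mass assigned to the non-TE sink",
            totals[sink_pos],
        )
    df = pd.DataFrame(
        {sample_name: totals[:n_fam]}, index=pd.Index(families, name="feature_id")
    )
    return CountMatrix(
        df,
        "te_family",
        meta={"non_te_sink": float(totals[sink_pos]), "n_reads": len(reads)},
    )


def mixture_log_likelihood(
    reads: list[AlignedRead], te: TEAnnotation, family_weights: dict[str, float]
) -> float:
    """Log-likelihood of ambiguous reads under the simple family mixture.

    pi_f proportional to family_weights; each ambiguous read contributes
    log(sum of pi over its candidate families).  Used to check EM
    monotonicity.
    """
    trees = _copy_trees(te)
    labels = list(family_weights)
    w = np.array([family_weights[f] for f in labels], dtype=float)
    pi = w / w.sum()
    pos = {f: i for i, f in enumerate(labels)}
    ll = 0.0
    for read in reads:
        cand: set[int] = set()
        for locus in read.candidate_loci:
            copy = _best_copy(locus, trees)
            if copy is not None and copy.label in pos:
                cand.add(pos[copy.label])
        if len(cand) > 1:
            ll += float(np.log(pi[list(cand)].sum()))
    return ll
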