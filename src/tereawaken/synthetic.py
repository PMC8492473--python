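"""Ground-truth synthetic data for every pipeline stage.

The generators emulate, at desk scale, the statistical structure of the
sequencing data the pipeline was designed for: NB-distributed counts per
gene/TE family/TE copy with designated fold changes across two
conditions, multi-mapping ambiguity within TE families, accessibility
peaks preferentially placed within a pad of chosen TE families, gene TSS
placed within or beyond a window of chosen TE copies, and per-base
strand-split Tn5 insertion profiles with a tunable footprint depression
over motif spans.  Every generator is deterministic for a fixed seed and
records what it planted in a :class:`SimTruth`, so downstream stages can
be scored against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import Gene, GeneAnnotation, TEAnnotation, TECopy
from .counts import CountMatrix
from .footprint import FootprintProfileSet
from .intervals import GenomeModel, GenomicInterval, StartSpace, merge_segments
from .peaks import Peak, PeakSet

_MAX_PLACEMENT_RETRIES = 1000

# superfamily/class labels cycled over synthetic families; RepeatMasker-style
_TE_HIERARCHY = [
    ("ERV1", "LTR"),
    ("ERVK", "LTR"),
    ("L1", "LINE"),
    ("B1", "SINE"),
    ("ERVL", "LTR"),
]


@dataclass
class SimTruth:
    """What the generators planted; consumed by recovery/power checks."""

    up_families: set[str] = field(default_factory=set)
    down_families: set[str] = field(default_factory=set)
    up_copies: set[str] = field(default_factory=set)
    de_genes: set[str] = field(default_factory=set)
    enriched_families: set[str] = field(default_factory=set)
    proximal_pairs: set[tuple[str, str]] = field(default_factory=set)
    footprint_depth_by_condition: dict[str, float] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)

    def update(self, other: "SimTruth") -> "SimTruth":
        self.up_families |= other.up_families
        self.down_families |= other.down_families
        self.up_copies |= other.up_copies
        self.de_genes |= other.de_genes
        self.enriched_families |= other.enriched_families
        self.proximal_pairs |= other.proximal_pairs
        self.footprint_depth_by_condition.update(other.footprint_depth_by_condition)
        self.fold_changes.update(other.fold_changes)
        return self


def simulate_genome(
    n_chroms: int,
    chrom_len: int,
    excluded_fraction: float = 0.0,
    seed: int = 0,
    n_excluded_regions: int = 10,
) -> GenomeModel:
    """A genome of equal-length chromosomes with random excluded regions.

    Excluded regions stand in for assembly gaps/blacklist intervals; they
    cover approximately `excluded_fraction` of each chromosome, split into
    `n_excluded_regions` non-overlapping pieces.
    """
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")
    if not (0 <= excluded_fraction < 0.5):
        raise ValueError("excluded_fraction must lie in [0, 0.5): shuffle space too small")
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": int(chrom_len) for i in range(n_chroms)}
    excluded: list[GenomicInterval] = []
    if excluded_fraction > 0:
        region_len = max(1, int(round(chrom_len * excluded_fraction / n_excluded_regions)))
        for chrom in chrom_sizes:
            placed: list[tuple[int, int]] = []
            target = int(round(chrom_len * excluded_fraction))
            covered = 0
            tries = 0
            while covered + region_len <= target + region_len // 2:
                tries += 1
                if tries > _MAX_PLACEMENT_RETRIES:
                    raise RuntimeError(f"could not place excluded regions on {chrom}")
                s = int(rng.integers(0, chrom_len - region_len + 1))
                e = s + region_len
                if any(s < pe and ps < e for ps, pe in placed):
                    continue
                placed.append((s, e))
                covered += region_len
                if covered >= target:
                    break
            excluded.extend(GenomicInterval(chrom, s, e) for s, e in merge_segments(placed))
    return GenomeModel(chrom_sizes, excluded)


def simulate_te_annotation(
    genome: GenomeModel,
    n_families: int,
    copies_per_family: int,
    copy_len: tuple[int, int] | int = (100, 500),
    seed: int = 0,
) -> TEAnnotation:
    """Place TE copies uniformly in the allowed (non-excluded) space.

    Copies within one family share the "name:superfamily:class" label.
    Copies may overlap each other (as real nested repeats do) but never
    excluded regions or chromosome bounds.
    """
    if isinstance(copy_len, int):
        copy_len = (copy_len, copy_len)
    lo, hi = copy_len
    if not (0 < lo <= hi):
        raise ValueError("invalid copy length range")
    rng = np.random.default_rng(seed)
    total_bp_budget = n_families * copies_per_family * hi
    if total_bp_budget >= genome.allowed_size():
        raise ValueError("total TE bp exceeds available genome space")
    copies: list[TECopy] = []
    k = 0
    for fam_i in range(n_families):
        superfam, te_class = _TE_HIERARCHY[fam_i % len(_TE_HIERARCHY)]
        fam_name = f"TEfam{fam_i + 1:02d}"
        for _ in range(copies_per_family):
            length = int(rng.integers(lo, hi + 1))
            space = StartSpace.for_length(genome, length)
            if space.total == 0:
                raise RuntimeError(
                    f"no room for a {length} bp TE copy anywhere in the genome"
                )
            chrom, start = space.sample(rng, 1)[0]
            strand = "+" if rng.random() < 0.5 else "-"
            copies.append(
                TECopy(
                    copy_id=f"{fam_name}_c{k:04d}",
                    family=fam_name,
                    superfamily=superfam,
                    te_class=te_class,
                    interval=GenomicInterval(chrom, start, start + length, strand),
                )
            )
            k += 1
    return TEAnnotation(copies)


def simulate_gene_annotation(
    genome: GenomeModel,
    n_genes: int,
    te_annotation: TEAnnotation,
    frac_proximal: float | None = 0.0,
    window: int = 30_000,
    seed: int = 0,
    target_copies: list[str] | None = None,
    gene_len: int = 2_000,
) -> tuple[GeneAnnotation, SimTruth]:
    """Place gene TSS relative to designated TE copies.

    A fraction `frac_proximal` of genes get a TSS within `window` bp of a
    designated copy (default: all copies); the rest are rejection-sampled
    to lie strictly beyond the window of every designated copy.
    `frac_proximal=None` places all genes uniformly, ignoring TEs — the
    TE-independent configuration used for null calibration.  The planted
    (copy_id, gene_id) pairs are recorded in the returned SimTruth.
    """
    if frac_proximal is not None and not (0 <= frac_proximal <= 1):
        raise ValueError("frac_proximal must lie in [0, 1] or be None")
    if window >= max(genome.chrom_sizes.values()):
        raise ValueError("window larger than chromosome")
    rng = np.random.default_rng(seed)
    by_id = te_annotation.by_id()
    if target_copies is None:
        designated = list(te_annotation.copies)
    else:
        designated = [by_id[cid] for cid in target_copies]
    truth = SimTruth()
    genes: list[Gene] = []

    def tss_near(copy: TECopy) -> int:
        lo = max(0, copy.interval.start - window)
        hi = min(genome.chrom_sizes[copy.interval.chrom] - 1, copy.interval.end - 1 + window)
        return int(rng.integers(lo, hi + 1))

    def tss_far() -> tuple[str, int]:
        chroms = sorted(genome.chrom_sizes)
        for _ in range(_MAX_PLACEMENT_RETRIES):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(0, genome.chrom_sizes[chrom]))
            ok = True
            for c in designated:
                if c.interval.chrom != chrom:
                    continue
                d = _point_interval_distance(pos, c.interval)
                if d <= window:
                    ok = False
                    break
            if ok:
                return chrom, pos
        raise RuntimeError(
            "could not place a gene beyond the window of all designated copies; "
            "genome too small or window too large"
        )

    def tss_uniform() -> tuple[str, int]:
        chroms = sorted(genome.chrom_sizes)
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        return chrom, int(rng.integers(0, genome.chrom_sizes[chrom]))

    if frac_proximal is None:
        n_prox = 0
    else:
        n_prox = int(round(frac_proximal * n_genes))
        if n_prox > 0 and not designated:
            raise ValueError("frac_proximal > 0 but no designated copies")
    for g in range(n_genes):
        gid = f"gene_{g:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if g < n_prox:
            copy = designated[int(rng.integers(0, len(designated)))]
            chrom, tss = copy.interval.chrom, tss_near(copy)
            truth.proximal_pairs.add((copy.copy_id, gid))
        elif frac_proximal is None:
            chrom, tss = tss_uniform()
        else:
            chrom, tss = tss_far()
        clen = genome.chrom_sizes[chrom]
        if strand == "+":
            start, end = tss, min(clen, tss + gene_len)
        else:
            start, end = max(0, tss + 1 - gene_len), tss + 1
        genes.append(Gene(gid, GenomicInterval(chrom, start, end, strand)))
    return GeneAnnotation(genes), truth


def _point_interval_distance(pos: int, iv: GenomicInterval) -> int:
    """bp distance from a point to the nearest base of a half-open interval."""
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - (iv.end - 1)
    return 0


def simulate_counts(
    feature_ids: list[str],
    n_reps: int,
    base_mean: float,
    dispersion: float,
    fold_changes: dict[str, float] | None = None,
    lib_size_factors: np.ndarray | None = None,
    seed: int = 0,
    kind: str = "gene",
    base_means: dict[str, float] | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """NB counts for two conditions (A = reference, B carries fold changes).

    counts ~ NB(mean = s_j * mu_i * fc_i(condition), dispersion alpha) with
    Var = mu + alpha * mu^2; dispersion 0 degrades to Poisson.  Samples are
    named A_1..A_n, B_1..B_n.  Truth records every feature with fc != 1.
    """
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    fold_changes = fold_changes or {}
    if any(fc <= 0 for fc in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    samples = [f"A_{j + 1}" for j in range(n_reps)] + [f"B_{j + 1}" for j in range(n_reps)]
    if lib_size_factors is None:
        sf = np.ones(2 * n_reps)
    else:
        sf = np.asarray(lib_size_factors, dtype=float)
        if sf.shape != (2 * n_reps,) or (sf <= 0).any():
            raise ValueError("lib_size_factors must be positive, one per sample")
    mu_base = np.array(
        [base_means.get(f, base_mean) if base_means else base_mean for f in feature_ids]
    )
    fc = np.array([fold_changes.get(f, 1.0) for f in feature_ids])
    mu = np.empty((len(feature_ids), 2 * n_reps))
    mu[:, :n_reps] = mu_base[:, None] * sf[None, :n_reps]
    mu[:, n_reps:] = (mu_base * fc)[:, None] * sf[None, n_reps:]
    if dispersion == 0:
        arr = rng.poisson(mu)
    else:
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + mu)
        arr = rng.negative_binomial(n_param, p_param)
    df = pd.DataFrame(arr, index=pd.Index(feature_ids, name="feature_id"), columns=samples)
    truth = SimTruth(fold_changes={f: v for f, v in fold_changes.items() if v != 1.0})
    for f, v in truth.fold_changes.items():
        target = truth.up_families if kind == "te_family" else (
            truth.up_copies if kind == "te_copy" else truth.de_genes
        )
        if v > 1:
            target.add(f)
        elif kind == "te_family":
            truth.down_families.add(f)
        elif kind == "gene":
            truth.de_genes.add(f)
    return CountMatrix(df, kind), truth


def simulate_peaks(
    genome: GenomeModel,
    te_annotation: TEAnnotation,
    enriched_families: set[str],
    enrichment_factor: float,
    n_peaks: int,
    peak_len: int = 200,
    pad: int = 1_000,
    seed: int = 0,
    label: str = "sim",
) -> tuple[PeakSet, SimTruth]:
    """Peaks placed uniformly except for excess mass near chosen families.

    Under uniform placement a peak overlaps the +/-pad neighbourhood of an
    enriched-family copy with probability q (the fraction of valid start
    positions that yield such an overlap).  Each simulated peak instead
    hits that neighbourhood with probability min(enrichment_factor * q, 1),
    so enrichment_factor = 1 reproduces uniform placement exactly.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    if n_peaks < 0:
        raise ValueError("n_peaks must be >= 0")
    rng = np.random.default_rng(seed)
    truth = SimTruth(enriched_families=set(enriched_families))
    if n_peaks == 0:
        return PeakSet(label, []), truth
    space = StartSpace.for_length(genome, peak_len)
    if space.total < n_peaks:
        raise RuntimeError("n_peaks exceeds placeable start positions")
    # start positions whose peak would overlap a padded enriched-family copy
    target_regions: dict[str, list[tuple[int, int]]] = {}
    for c in te_annotation.copies:
        if c.label in enriched_families:
            clen = genome.chrom_sizes[c.interval.chrom]
            lo = max(0, c.interval.start - pad - peak_len + 1)
            hi = min(clen, c.interval.end + pad)
            target_regions.setdefault(c.interval.chrom, []).append((lo, hi))
    hit_space = space.restrict(target_regions) if target_regions else StartSpace([])
    miss_space = space.subtract(hit_space)
    q = hit_space.total / space.total
    p_hit = min(enrichment_factor * q, 1.0)
    peaks: list[Peak] = []
    for _ in range(n_peaks):
        use_hit = hit_space.total > 0 and rng.random() < p_hit
        pool = hit_space if use_hit else miss_space
        if pool.total == 0:
            pool = hit_space if pool is miss_space else miss_space
        chrom, start = pool.sample(rng, 1)[0]
        score = float(rng.uniform(100, 1000))
        peaks.append(Peak(GenomicInterval(chrom, start, start + peak_len), score))
    return PeakSet(label, peaks), truth


def simulate_reads(
    te: TEAnnotation,
    copy_expression: dict[str, float],
    multimap_frac: float = 0.2,
    read_len: int = 50,
    seed: int = 0,
) -> list:
    """Simplified alignment records over TE copies.

    Each copy emits Poisson(copy_expression[copy_id]) reads placed
    uniformly inside it.  A fraction `multimap_frac` of reads are
    multi-mappers: they additionally report a placement in 1-3 other
    copies of the same family (repeats are homologous within a family),
    so they carry family-level but not copy-level information.
    """
    from .te_quant import AlignedRead

    if not (0 <= multimap_frac <= 1):
        raise ValueError("multimap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fam_copies: dict[str, list[TECopy]] = {}
    for c in te.copies:
        fam_copies.setdefault(c.label, []).append(c)
    reads: list[AlignedRead] = []
    k = 0

    def locus_in(copy: TECopy) -> GenomicInterval:
        span = max(1, len(copy.interval) - read_len)
        s = copy.interval.start + int(rng.integers(0, span))
        return GenomicInterval(copy.interval.chrom, s, min(s + read_len, copy.interval.end))

    for c in te.copies:
        lam = copy_expression.get(c.copy_id, 0.0)
        n = int(rng.poisson(lam)) if lam > 0 else 0
        siblings = [x for x in fam_copies[c.label] if x.copy_id != c.copy_id]
        for _ in range(n):
            loci = [locus_in(c)]
            if siblings and rng.random() < multimap_frac:
                extra = rng.choice(
                    len(siblings), size=min(len(siblings), 1 + int(rng.integers(0, 3))),
                    replace=False,
                )
                loci.extend(locus_in(siblings[j]) for j in extra)
            reads.append(AlignedRead(f"read_{k:06d}", loci))
            k += 1
    return reads


def simulate_insertion_profiles(
    n_sites: int,
    flank: int,
    motif_len: int,
    background_rate: float,
    footprint_depth: float,
    seed: int = 0,
) -> FootprintProfileSet:
    """Poisson insertion counts with a depression over the motif span.

    Outside the motif each strand/position draws Poisson(background_rate);
    inside, Poisson(background_rate * (1 - footprint_depth)).  depth 0 is
    flat in expectation, depth 1 forbids insertions inside the motif.
    """
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    if not (0 <= footprint_depth <= 1):
        raise ValueError("footprint_depth must lie in [0, 1]")
    if n_sites < 1 or flank < 1 or motif_len < 1:
        raise ValueError("n_sites, flank, motif_len must be positive")
    rng = np.random.default_rng(seed)
    width = motif_len + 2 * flank
    rates = np.full(width, background_rate)
    rates[flank : flank + motif_len] *= 1 - footprint_depth
    counts = rng.poisson(rates, size=(n_sites, 2, width))
    spacing = width + 100
    sites = [
        GenomicInterval("chrSim", flank + i * spacing, flank + i * spacing + motif_len)
        for i in range(n_sites)
    ]
    return FootprintProfileSet(sites, counts, flank, motif_len)
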