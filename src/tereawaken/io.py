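"""Plain-text readers and writers for the pipeline's interchange formats.

BED is native (0-based half-open).  TE copies serialize their identity in
the BED name field as "copy_id|family:superfamily:class".  Counts travel
as TSV (feature_id, kind, one column per sample); simulation ground truth
as a flat key-value text file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotations import Gene, GeneAnnotation, TEAnnotation, TECopy, parse_family_label
from .intervals import GenomeModel, GenomicInterval
from .peaks import Peak, PeakSet
from .synthetic import SimTruth
from .te_quant import AlignedRead


def write_chrom_sizes(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.chrom_sizes):
            fh.write(f"{chrom}\t{genome.chrom_sizes[chrom]}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, length = line.split()[:2]
                sizes[chrom] = int(length)
    return sizes


def write_bed(intervals: list[GenomicInterval], path: str | Path,
              names: list[str] | None = None, scores: list[float] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            score = scores[i] if scores else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


def write_te_bed(te: TEAnnotation, path: str | Path) -> None:
    write_bed(
        [c.interval for c in te.copies],
        path,
        names=[f"{c.copy_id}|{c.label}" for c in te.copies],
    )


def read_te_bed(path: str | Path) -> TEAnnotation:
    copies = []
    for iv, name, _ in read_bed(path):
        copy_id, label = name.split("|", 1)
        fam, superfam, te_class = parse_family_label(label)
        copies.append(TECopy(copy_id, fam, superfam, te_class, iv))
    return TEAnnotation(copies)


def write_gene_bed(genes: GeneAnnotation, path: str | Path) -> None:
    write_bed([g.interval for g in genes.genes], path, names=[g.gene_id for g in genes.genes])


def read_gene_bed(path: str | Path) -> GeneAnnotation:
    return GeneAnnotation([Gene(name, iv) for iv, name, _ in read_bed(path)])


def write_peaks(peaks: PeakSet, path: str | Path, narrow: bool = False) -> None:
    """BED6 by default; narrowPeak (BED6+4) when narrow=True."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.peaks):
            iv = p.interval
            base = f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{p.score:g}\t."
            if narrow:
                base += "\t0\t-1\t-1\t-1"
            fh.write(base + "\n")


def read_peaks(path: str | Path, label: str | None = None) -> PeakSet:
    """Read BED or narrowPeak (extra columns ignored)."""
    peaks = [Peak(iv, score) for iv, _, score in read_bed(path)]
    return PeakSet(label or Path(path).stem, peaks)


def write_reads_tsv(reads: list[AlignedRead], path: str | Path) -> None:
    """read_id, chrom, start, end, n_hits, hit_index (one row per locus)."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tn_hits\thit_index\n")
        for r in reads:
            for i, locus in enumerate(r.candidate_loci):
                fh.write(
                    f"{r.read_id}\t{locus.chrom}\t{locus.start}\t{locus.end}"
                    f"\t{r.n_hits}\t{i}\n"
                )


def read_reads_tsv(path: str | Path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t")
    reads = []
    for read_id, grp in df.groupby("read_id", sort=False):
        loci = [
            GenomicInterval(row.chrom, int(row.start), int(row.end))
            for row in grp.sort_values("hit_index").itertuples()
        ]
        reads.append(AlignedRead(str(read_id), loci))
    return reads


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in ("up_families", "down_families", "up_copies", "de_genes",
                    "enriched_families"):
            fh.write(f"{key}\t{','.join(sorted(getattr(truth, key)))}\n")
        fh.write(
            "proximal_pairs\t"
            + ",".join(f"{c}|{g}" for c, g in sorted(truth.proximal_pairs))
            + "\n"
        )
        for cond, depth in sorted(truth.footprint_depth_by_condition.items()):
            fh.write(f"footprint_depth:{cond}\t{depth}\n")
        for feat, fc in sorted(truth.fold_changes.items()):
            fh.write(f"fold_change:{feat}\t{fc}\n")


def read_truth(path: str | Path) -> SimTruth:
    truth = SimTruth()
    with open(path) as fh:
        for line in fh:
            if "\t" not in line:
                continue
            key, value = line.rstrip("\n").split("\t", 1)
            if key in {"up_families", "down_families", "up_copies", "de_genes",
                       "enriched_families"}:
                setattr(truth, key, set(v for v in value.split(",") if v))
            elif key == "proximal_pairs":
                truth.proximal_pairs = {
                    tuple(v.split("|", 1)) for v in value.split(",") if v
                }
            elif key.startswith("footprint_depth:"):
                truth.footprint_depth_by_condition[key.split(":", 1)[1]] = float(value)
            elif key.startswith("fold_change:"):
                truth.fold_changes[key.split(":", 1)[1]] = float(value)
    return truth
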