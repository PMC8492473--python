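#!/usr/bin/env python
"""TE-family enrichment in gained accessibility peaks vs a shuffled null.

Each copy is padded by +/-1 kb; observed peak-copy overlap events per
family are compared with 1,000 uniform same-chromosome relocations of
the padded copies.  Families are then crossed with the differential
expression calls — the interesting result is a family that is both
upregulated and enriched in newly accessible chromatin.
"""

from pathlib import Path

from tereawaken import io as tio
from tereawaken.config import PipelineConfig
from tereawaken.enrichment import cross_with_de, family_enrichment
from tereawaken.intervals import GenomeModel

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "simdata"
SEED = 1


def main() -> None:
    cfg = PipelineConfig()
    sizes = tio.read_chrom_sizes(SIM / "genome.chrom.sizes")
    excluded = [iv for iv, _, _ in tio.read_bed(SIM / "excluded.bed")]
    genome = GenomeModel(sizes, excluded)
    te = tio.read_te_bed(SIM / "te_copies.bed")
    gained = tio.read_peaks(BASE / "peaks_gained.bed", "gained")
    import pandas as pd

    de = pd.read_csv(BASE / "de_genes_families.tsv", sep="\t", index_col=0)
    up_fams = set(de[(de.status == "up") & de.index.isin(te.families)].index)

    results = family_enrichment(
        te, genome, gained, pad=cfg.te_pad, n_shuffles=cfg.n_shuffles_atac,
        alpha=cfg.alpha, seed=SEED,
    )
    table = cross_with_de(results, up_fams)
    table.to_csv(BASE / "te_enrichment.tsv", sep="\t")
    print(table[["observed_hits", "null_mean", "p_binomial",
                 "accessibility", "expression", "flagged"]].to_string())
    flagged = table.index[table.flagged].tolist()
    print(f"\nfamilies both deregulated and peak-enriched: {flagged}")
    print("table -> te_enrichment.tsv")


if __name__ == "__main__":
    main()
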