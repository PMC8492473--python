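#!/usr/bin/env python
"""Are deregulated genes enriched near upregulated TE copies?

Each detected upregulated copy is assigned to its closest gene TSS; the
genes within +/-30 kb form the proximal list.  Its overlap with the
detected deregulated genes is tested with hypergeometric/Fisher tests
and against a background of 10,000 resampled DEG-sized gene sets (the
mean overlap of the resamples feeds an exact binomial test).
"""

from pathlib import Path

import pandas as pd

from tereawaken import io as tio
from tereawaken.config import PipelineConfig
from tereawaken.proximity import proximity_analysis

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "simdata"
SEED = 1


def main() -> None:
    cfg = PipelineConfig()
    te = tio.read_te_bed(SIM / "te_copies.bed")
    genes = tio.read_gene_bed(SIM / "genes.bed")
    copy_de = pd.read_csv(BASE / "de_te_copies.tsv", sep="\t", index_col=0)
    up_ids = set(copy_de[copy_de.status == "up"].index)
    gene_de = pd.read_csv(BASE / "de_genes_families.tsv", sep="\t", index_col=0)
    degs = set(gene_de[gene_de.status.isin(["up", "down"])
                       & gene_de.index.str.startswith("gene_")].index)
    up_copies = [c for c in te.copies if c.copy_id in up_ids]

    res = proximity_analysis(
        up_copies, genes, degs, window=cfg.proximity_window,
        n_resamples=cfg.n_resamples_proximity, seed=SEED,
    )
    row = {
        "n_up_copies": res.n_te_copies,
        "n_proximal_genes": len(res.proximal_genes),
        "observed_overlap": res.n_observed_overlap,
        "universe": res.universe_size,
        "null_mean": res.null_mean_overlap,
        "p_binomial_vs_null": res.p_binomial_vs_null,
        "p_hypergeom": res.p_hypergeom,
        "p_fisher": res.p_fisher,
    }
    pd.DataFrame([row]).to_csv(BASE / "proximity.tsv", sep="\t", index=False)
    print(f"{res.n_te_copies} upregulated copies -> "
          f"{len(res.proximal_genes)} proximal genes (within "
          f"{cfg.proximity_window / 1000:.0f} kb of the closest TSS)")
    print(f"overlap with {row['universe']}-gene universe DEGs: "
          f"{res.n_observed_overlap} observed vs {res.null_mean_overlap:.2f} "
          f"expected from {res.n_resamples} resamples")
    print(f"p (binomial vs resampled null) = {res.p_binomial_vs_null:.3g}; "
          f"p (hypergeometric) = {res.p_hypergeom:.3g}; "
          f"p (Fisher) = {res.p_fisher:.3g}")
    print("table -> proximity.tsv")


if __name__ == "__main__":
    main()
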