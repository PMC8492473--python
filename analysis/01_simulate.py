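#!/usr/bin/env python
"""Generate the default synthetic study and write its inputs + ground truth.

One TE family (TEfam01:ERV1:LTR) is planted as transcriptionally
upregulated (4-fold) with its copies preferentially gaining accessibility
peaks; deregulated genes are preferentially drawn from genes within 30 kb
of the upregulated copies; footprinted motifs are deeper in condition A
than condition B.  Everything downstream (02-07) re-derives these facts
from the data alone.
"""

from pathlib import Path

from tereawaken import io as tio
from tereawaken.pipeline import run_default_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "simdata"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = run_default_pipeline(seed=SEED)
    tio.write_chrom_sizes(res["genome"], OUT / "genome.chrom.sizes")
    tio.write_bed(res["genome"].excluded_regions, OUT / "excluded.bed")
    tio.write_te_bed(res["te"], OUT / "te_copies.bed")
    tio.write_gene_bed(res["genes"], OUT / "genes.bed")
    tio.write_reads_tsv(res["reads"], OUT / "reads.tsv")
    tio.write_peaks(res["peaks_0"], OUT / "peaks_D0.narrowPeak", narrow=True)
    tio.write_peaks(res["peaks_t"], OUT / "peaks_t.narrowPeak", narrow=True)
    tio.write_truth(res["truth"], OUT / "truth.txt")
    truth = res["truth"]
    print(f"genome: {len(res['genome'].chrom_sizes)} chromosomes, "
          f"{sum(res['genome'].chrom_sizes.values()):,} bp "
          f"({len(res['genome'].excluded_regions)} excluded regions)")
    print(f"TE annotation: {len(res['te'])} copies in {len(res['te'].families)} families")
    print(f"genes: {len(res['genes'])}; planted proximal pairs: {len(truth.proximal_pairs)}")
    print(f"planted upregulated family: {sorted(truth.up_families)}")
    print(f"planted deregulated genes: {len(truth.de_genes)}")
    print(f"simulated reads: {len(res['reads'])}")
    print(f"peaks: D0 {len(res['peaks_0'])}, later {len(res['peaks_t'])}")
    print(f"wrote dataset + truth to {OUT}")


if __name__ == "__main__":
    main()
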