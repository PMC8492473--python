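"""End-to-end synthetic study: simulate -> quantify -> test -> peaks ->
enrichment -> proximity -> footprint.

The default scale (2 chromosomes x 1 Mb, 5 TE families x 20 copies, 500
genes, 3 vs 3 replicates) is small enough to run in well under a minute
while leaving every statistical stage enough signal to recover the
planted truth: one TE family is transcriptionally upregulated (4-fold)
and its copies preferentially gain accessibility peaks (5-fold placement
excess); deregulated genes are preferentially drawn from genes near the
upregulated copies; footprinted motifs are deeper in one condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import synthetic
from .config import PipelineConfig
from .counts import CountMatrix
from .differential import classify, nb_test, results_frame
from .enrichment import cross_with_de, family_enrichment
from .footprint import compare_fos, fos
from .peaks import filter_min_length, gained_lost, merge_peaks
from .proximity import proximity_analysis
from .synthetic import SimTruth
from .te_quant import count_te_copies, count_te_families


@dataclass
class DefaultScale:
    """Problem sizes for the default synthetic study."""

    n_chroms: int = 2
    chrom_len: int = 1_000_000
    excluded_fraction: float = 0.05
    n_families: int = 5
    copies_per_family: int = 20
    copy_len: tuple[int, int] = (300, 600)
    n_genes: int = 1_000
    frac_proximal: float = 0.1
    n_reps: int = 3
    gene_base_mean: float = 100.0
    family_base_mean: float = 200.0
    dispersion: float = 0.05
    planted_fc: float = 4.0
    n_de_genes: int = 100
    n_peaks_baseline: int = 120
    n_peaks_later: int = 160
    peak_len: int = 400
    peak_enrichment_factor: float = 5.0
    n_footprint_sites: int = 300
    footprint_flank: int = 100
    footprint_motif_len: int = 20
    footprint_rate: float = 0.5
    footprint_depths: tuple[float, float] = (0.7, 0.2)


def run_default_pipeline(
    seed: int = 0,
    config: PipelineConfig | None = None,
    scale: DefaultScale | None = None,
    n_shuffles: int | None = None,
    n_resamples: int | None = None,
) -> dict[str, Any]:
    """Run every stage on one synthetic dataset; returns results + truth."""
    config = config or PipelineConfig()
    scale = scale or DefaultScale()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=16)
    truth = SimTruth()

    # --- genome and annotations -------------------------------------------
    genome = synthetic.simulate_genome(
        scale.n_chroms, scale.chrom_len, scale.excluded_fraction, seed=int(seeds[0])
    )
    te = synthetic.simulate_te_annotation(
        genome, scale.n_families, scale.copies_per_family, scale.copy_len,
        seed=int(seeds[1]),
    )
    planted_family = te.families[0]
    planted_copies = [c for c in te.copies if c.label == planted_family]
    truth.up_families.add(planted_family)
    truth.up_copies |= {c.copy_id for c in planted_copies}

    genes, gene_truth = synthetic.simulate_gene_annotation(
        genome, scale.n_genes, te, frac_proximal=scale.frac_proximal,
        window=config.proximity_window, seed=int(seeds[2]),
        target_copies=[c.copy_id for c in planted_copies],
    )
    truth.update(gene_truth)

    # --- read-level quantification (single-sample sanity stage) ----------
    expr = {c.copy_id: 30.0 for c in te.copies}
    reads = synthetic.simulate_reads(te, expr, multimap_frac=0.25, seed=int(seeds[3]))
    copy_counts_1s = count_te_copies(reads, te)
    family_counts_1s = count_te_families(reads, te, mode="em")

    # --- expression: genes + TE families normalized together --------------
    planted_prox = sorted({g for _, g in truth.proximal_pairs})
    rng_de = np.random.default_rng(int(seeds[4]))
    n_prox_de = min(len(planted_prox), int(0.6 * scale.n_de_genes))
    de_genes = list(
        rng_de.choice(planted_prox, size=n_prox_de, replace=False)
    )
    others = sorted(set(g.gene_id for g in genes.genes) - set(de_genes))
    de_genes += list(
        rng_de.choice(others, size=scale.n_de_genes - n_prox_de, replace=False)
    )
    gene_fc = {g: scale.planted_fc for g in de_genes}
    fam_fc = {planted_family: scale.planted_fc}
    gene_ids = [g.gene_id for g in genes.genes]
    gene_cm, gene_truth_c = synthetic.simulate_counts(
        gene_ids, scale.n_reps, scale.gene_base_mean, scale.dispersion,
        fold_changes=gene_fc, seed=int(seeds[5]), kind="gene",
    )
    fam_cm, fam_truth_c = synthetic.simulate_counts(
        te.families, scale.n_reps, scale.family_base_mean, scale.dispersion,
        fold_changes=fam_fc, seed=int(seeds[6]), kind="te_family",
    )
    truth.update(gene_truth_c).update(fam_truth_c)
    joint = CountMatrix.concat([gene_cm, fam_cm], kind="element")
    labels = ["A"] * scale.n_reps + ["B"] * scale.n_reps
    joint_results = nb_test(joint, labels, config)
    up_all, down_all = classify(joint_results, config.fc_cutoff, config.alpha)
    up_families = {f for f in up_all if f in set(te.families)}
    detected_degs = (up_all | down_all) - set(te.families)

    # --- TE copies (unique-read counts, pairwise-normalized test) ---------
    copy_fc = {c.copy_id: scale.planted_fc for c in planted_copies}
    copy_cm, _ = synthetic.simulate_counts(
        [c.copy_id for c in te.copies], scale.n_reps, 50.0, scale.dispersion,
        fold_changes=copy_fc, seed=int(seeds[7]), kind="te_copy",
    )
    copy_results = nb_test(copy_cm, labels, config)
    up_copies, _ = classify(copy_results, config.fc_cutoff, config.alpha)

    # --- accessibility peaks ----------------------------------------------
    peaks_0, _ = synthetic.simulate_peaks(
        genome, te, set(), 1.0, scale.n_peaks_baseline, scale.peak_len,
        pad=config.te_pad, seed=int(seeds[8]), label="D0",
    )
    peaks_t, peak_truth = synthetic.simulate_peaks(
        genome, te, {planted_family}, scale.peak_enrichment_factor,
        scale.n_peaks_later, scale.peak_len, pad=config.te_pad,
        seed=int(seeds[9]), label="H16",
    )
    truth.update(peak_truth)
    consensus = merge_peaks(peaks_t, peaks_0)
    gained, lost, common = gained_lost(consensus, peaks_t, peaks_0)
    gained = filter_min_length(gained, config.min_peak_len)

    # --- TE-family enrichment in gained peaks + cross with DE -------------
    enrich = family_enrichment(
        te, genome, gained, pad=config.te_pad,
        n_shuffles=n_shuffles or config.n_shuffles_atac,
        alpha=config.alpha, seed=int(seeds[10]),
    )
    crossed = cross_with_de(enrich, up_families, set())

    # --- proximity of upregulated copies to deregulated genes -------------
    by_id = te.by_id()
    up_copy_objs = [by_id[cid] for cid in sorted(up_copies) if cid in by_id]
    proximity = proximity_analysis(
        up_copy_objs, genes, detected_degs,
        window=config.proximity_window,
        n_resamples=n_resamples or config.n_resamples_proximity,
        seed=int(seeds[11]),
    )

    # --- footprints ---------------------------------------------------------
    d_a, d_b = scale.footprint_depths
    prof_a = synthetic.simulate_insertion_profiles(
        scale.n_footprint_sites, scale.footprint_flank, scale.footprint_motif_len,
        scale.footprint_rate, d_a, seed=int(seeds[12]),
    )
    prof_b = synthetic.simulate_insertion_profiles(
        scale.n_footprint_sites, scale.footprint_flank, scale.footprint_motif_len,
        scale.footprint_rate, d_b, seed=int(seeds[13]),
    )
    truth.footprint_depth_by_condition = {"condA": d_a, "condB": d_b}
    fos_a = fos(prof_a, flank_width=config.fos_flank_width)
    fos_b = fos(prof_b, flank_width=config.fos_flank_width)
    mean_diff, t_stat, p_fos = compare_fos(fos_a, fos_b)

    return {
        "genome": genome,
        "te": te,
        "genes": genes,
        "truth": truth,
        "reads": reads,
        "copy_counts_single_sample": copy_counts_1s,
        "family_counts_single_sample": family_counts_1s,
        "joint_results": results_frame(joint_results),
        "up_families": up_families,
        "detected_degs": detected_degs,
        "copy_results": results_frame(copy_results),
        "up_copies": up_copies,
        "peaks_0": peaks_0,
        "peaks_t": peaks_t,
        "consensus": consensus,
        "gained": gained,
        "lost": lost,
        "common": common,
        "enrichment": enrich,
        "crossed": crossed,
        "proximity": proximity,
        "fos_mean_log2_diff": mean_diff,
        "fos_t": t_stat,
        "fos_p": p_fos,
        "config": config,
        "scale": scale,
    }
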