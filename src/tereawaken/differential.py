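"""Negative-binomial differential testing and threshold classification.

Counts are normalized by median-of-ratios size factors (geometric-mean
reference).  Each feature gets a Wald test on the log fold change between
two conditions under NB(mean mu, Var = mu + alpha * mu^2) with a
method-of-moments dispersion estimate floored at 1e-8; group means are
maximum-likelihood fits with size-factor offsets.  Because the plug-in
dispersion is noisy with few replicates, each per-feature estimate is
additionally floored by a mean-binned trend across features (take the
larger of the two), after which the Wald statistic is referred to a
standard normal.  p values are BH-adjusted across tested features;
features with zero counts everywhere are reported untested and excluded
from the BH denominator.

A feature is called up when its linear fold change is >= fc_cutoff and
p_adj < alpha (down symmetric) — a 1.5-fold cutoff at p_adj < 0.05 by
default.  FLASH-style bait-versus-control binding uses a per-element
Welch unequal-variance t-test on normalized counts with *unadjusted*
p < 0.05 and strict fold change > 1.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .counts import CountMatrix

logger = logging.getLogger(__name__)

_DISPERSION_FLOOR = 1e-8


@dataclass
class DEResult:
    feature_id: str
    base_mean: float
    log2_fc: float
    p_value: float
    p_adj: float
    status: str  # up | down | ns | untested


def size_factors(counts: CountMatrix | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean reference.

    Features with a zero in any sample are excluded from the reference;
    if none remain, falls back to total-count ratios with a warning.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("empty count matrix")
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        logger.warning(
            "size_factors: no feature nonzero in all samples; "
            "falling back to total-count ratios"
        )
        totals = arr.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("a sample has zero total counts")
        return totals / np.exp(np.mean(np.log(totals)))
    pos = arr[all_pos]
    log_geo_mean = np.mean(np.log(pos), axis=1)
    ratios = np.log(pos) - log_geo_mean[:, None]
    return np.exp(np.median(ratios, axis=0))


def _group_mle_mean(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 20
) -> np.ndarray:
    """Per-feature NB MLE of the group mean q with offsets mu_ij = s_j * q_i.

    Solved by IRLS on the log link; with equal size factors this is the
    plain normalized mean, which is also the starting value.
    """
    q = np.maximum((y / s).mean(axis=1), 1e-12)
    if np.allclose(s, s[0]):
        return q
    for _ in range(n_iter):
        mu = q[:, None] * s[None, :]
        w = mu / (1 + alpha[:, None] * mu)  # IRLS weights, log link
        num = (w * (y / np.maximum(mu, 1e-300))).sum(axis=1)
        den = w.sum(axis=1)
        q_new = q * num / np.maximum(den, 1e-300)
        if np.allclose(q_new, q, rtol=1e-10):
            q = q_new
            break
        q = np.maximum(q_new, 1e-12)
    return q


def _dispersion_trend(
    base_mean: np.ndarray, disp: np.ndarray, tested: np.ndarray, n_bins: int = 20
) -> np.ndarray:
    """Median dispersion within quantile bins of the base mean.

    Serves as a per-feature floor on the noisy method-of-moments
    estimates; with few features a single global median is used.
    """
    out = np.zeros_like(disp)
    if tested.sum() < 10:
        out[:] = np.median(disp[tested]) if tested.any() else _DISPERSION_FLOOR
        return out
    bm = base_mean[tested]
    edges = np.quantile(bm, np.linspace(0, 1, min(n_bins, max(2, tested.sum() // 10)) + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, base_mean, side="right") - 1, 0, len(edges) - 2)
    for b in range(len(edges) - 1):
        sel = tested & (idx == b)
        if sel.any():
            out[idx == b] = np.median(disp[sel])
    return out


def nb_test(
    counts: CountMatrix,
    condition_labels: list[str],
    config: PipelineConfig | None = None,
    allow_no_replicates: bool = False,
    sample_size_factors: np.ndarray | None = None,
) -> list[DEResult]:
    """Per-feature NB Wald test of condition B versus condition A.

    `sample_size_factors` overrides the internally estimated
    median-of-ratios factors — used when normalization should come from a
    larger matrix than the one being tested (or, for pairwise-normalized
    copy-level comparisons, from just the two conditions at hand).
    """
    config = config or PipelineConfig()
    df = counts.counts
    labels = np.asarray(condition_labels)
    if len(labels) != df.shape[1]:
        raise ValueError("one condition label per sample required")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two conditions required, got {list(groups)}")
    mask_a = labels == groups[0]
    mask_b = labels == groups[1]
    low_confidence = False
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        if not allow_no_replicates:
            raise ValueError(
                "each condition needs >= 2 replicates "
                "(pass allow_no_replicates=True to force a pooled-dispersion fit)"
            )
        low_confidence = True
        warnings.warn(
            "nb_test without replicates: pooled-dispersion heuristic, "
            "results are low-confidence",
            stacklevel=2,
        )

    arr = df.to_numpy(dtype=float)
    if sample_size_factors is not None:
        sf = np.asarray(sample_size_factors, dtype=float)
        if sf.shape != (arr.shape[1],) or (sf <= 0).any():
            raise ValueError("sample_size_factors must be positive, one per sample")
    else:
        sf = size_factors(counts)
    norm = arr / sf[None, :]
    base_mean = norm.mean(axis=1)
    tested = arr.sum(axis=1) > 0

    ya, yb = arr[:, mask_a], arr[:, mask_b]
    sa, sb = sf[mask_a], sf[mask_b]
    na, nb_ = mask_a.sum(), mask_b.sum()

    # method-of-moments dispersion from pooled within-group moments of
    # normalized counts: Var = mu + alpha mu^2  =>  alpha = (v - mu) / mu^2.
    # Per-feature estimates are noisy with few replicates, so each is
    # floored by a mean-binned trend across features (information sharing
    # in the DESeq tradition: use the larger of the per-feature and
    # fitted values), which keeps the normal Wald reference honest.
    if low_confidence:
        # no within-group variance available: pool across all samples and
        # all features of similar mean (single global estimate)
        v = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros(len(norm))
        pooled = np.nanmedian(
            (v - base_mean) / np.maximum(base_mean, 1e-12) ** 2
        )
        disp = np.full(len(arr), max(pooled, _DISPERSION_FLOOR))
    else:
        var_a = (norm[:, mask_a]).var(axis=1, ddof=1)
        var_b = (norm[:, mask_b]).var(axis=1, ddof=1)
        pooled_var = ((na - 1) * var_a + (nb_ - 1) * var_b) / (na + nb_ - 2)
        disp = (pooled_var - base_mean) / np.maximum(base_mean, 1e-12) ** 2
        disp = np.maximum(disp, _DISPERSION_FLOOR)
        disp = np.maximum(disp, _dispersion_trend(base_mean, disp, tested))

    qa = _group_mle_mean(ya, sa, disp)
    qb = _group_mle_mean(yb, sb, disp)
    # a group with zero total gets a half-count floor so the fold change
    # and its variance stay finite
    qa = np.where(ya.sum(axis=1) == 0, 0.5 / sa.sum(), qa)
    qb = np.where(yb.sum(axis=1) == 0, 0.5 / sb.sum(), qb)

    mu_a = qa[:, None] * sa[None, :]
    mu_b = qb[:, None] * sb[None, :]
    w_a = (mu_a / (1 + disp[:, None] * mu_a)).sum(axis=1)
    w_b = (mu_b / (1 + disp[:, None] * mu_b)).sum(axis=1)
    beta = np.log(qb) - np.log(qa)
    se = np.sqrt(1 / np.maximum(w_a, 1e-300) + 1 / np.maximum(w_b, 1e-300))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))

    log2_fc = beta / np.log(2)
    results: list[DEResult] = []
    p_for_adjust = pvals[tested]
    p_adj_vec = np.full(len(arr), np.nan)
    if tested.any():
        p_adj_vec[tested] = multipletests(p_for_adjust, method="fdr_bh")[1]
    log2_cut = np.log2(config.fc_cutoff)
    for i, fid in enumerate(df.index):
        if not tested[i]:
            results.append(DEResult(fid, 0.0, 0.0, np.nan, np.nan, "untested"))
            continue
        status = "ns"
        if p_adj_vec[i] < config.alpha:
            if log2_fc[i] >= log2_cut:
                status = "up"
            elif log2_fc[i] <= -log2_cut:
                status = "down"
        results.append(
            DEResult(
                fid,
                float(base_mean[i]),
                float(log2_fc[i]),
                float(pvals[i]),
                float(p_adj_vec[i]),
                status,
            )
        )
    return results


def classify(
    results: list[DEResult], fc_cutoff: float = 1.5, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """(up, down) feature sets at |log2 fc| >= log2(fc_cutoff), p_adj < alpha."""
    log2_cut = np.log2(fc_cutoff)
    up, down = set(), set()
    for r in results:
        if r.status == "untested" or not np.isfinite(r.p_adj):
            continue
        if r.p_adj < alpha and r.log2_fc >= log2_cut:
            up.add(r.feature_id)
        elif r.p_adj < alpha and r.log2_fc <= -log2_cut:
            down.add(r.feature_id)
    return up, down


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "base_mean": r.base_mean,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "p_adj": r.p_adj,
                "status": r.status,
            }
            for r in results
        ]
    ).set_index("feature_id")


def welch_enrichment(
    counts_bait: pd.DataFrame,
    counts_control: pd.DataFrame,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    normalize: bool = True,
) -> set[str]:
    """Bait-versus-control bound elements: fold change strictly > fc_cutoff
    and Welch unequal-variance t-test p < p_cutoff (unadjusted).

    Counts are normalized by joint median-of-ratios size factors by
    default (normalization method recorded here because the choice is an
    analysis convention, not a mathematical necessity).
    """
    if counts_bait.shape[1] < 2 or counts_control.shape[1] < 2:
        raise ValueError("need >= 2 replicates per side")
    if not counts_bait.index.equals(counts_control.index):
        raise ValueError("bait and control must share element ids")
    joint = pd.concat([counts_bait, counts_control], axis=1)
    if normalize:
        sf = size_factors(joint)
        joint = joint / sf[None, :]
    bait = joint.iloc[:, : counts_bait.shape[1]].to_numpy(dtype=float)
    ctrl = joint.iloc[:, counts_bait.shape[1] :].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate zero-variance rows are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(bait, ctrl, axis=1, equal_var=False)
    # zero variance on both sides: identical means -> p 1, else p 0
    degenerate = np.isnan(p)
    same = np.isclose(bait.mean(axis=1), ctrl.mean(axis=1))
    p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    mean_ctrl = ctrl.mean(axis=1)
    mean_bait = bait.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ctrl > 0, mean_bait / mean_ctrl, np.inf)
    fc = np.where((mean_ctrl == 0) & (mean_bait == 0), 1.0, fc)
    bound = (fc > fc_cutoff) & (p < p_cutoff)
    return set(counts_bait.index[bound])
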