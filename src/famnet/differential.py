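"""Differential expression and promoter-methylation calling.

Expression calls use a Welch two-sample t-test on log2 values with
Benjamini-Hochberg adjustment; a gene is called up when log2fc > 1 and
adjusted p < 0.05 (strictly), down for log2fc < -1. Methylation calls use
the Wilcoxon rank-sum test on promoter beta-means with the difference of
mean betas (delta_beta) giving the direction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError
from .stats import rank_sum_test

__all__ = ["aggregate_promoter_probes", "de_test", "bh_adjust", "diff_methylation"]

log = logging.getLogger(__name__)


def aggregate_promoter_probes(betas: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe x sample beta matrix to gene x sample beta-means.

    Only probes flagged as promoter probes contribute; a single-probe gene
    passes through unchanged. Genes without any promoter probe are excluded
    (logged). Betas outside [0, 1] are rejected.
    """
    vals = betas.to_numpy(dtype=float)
    if np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0:
        raise InvalidInputError("beta values must lie in [0, 1]")
    pm = probe_map.dropna(subset=["gene"])
    promoter = pm[pm["region"].astype(str).str.lower().isin({"promoter", "tss", "true", "1"})]
    promoter = promoter[promoter["probe"].isin(betas.index)]
    dropped = sorted(set(pm["gene"]) - set(promoter["gene"]))
    if dropped:
        log.info("excluding %d gene(s) with no promoter probe: %s",
                 len(dropped), ", ".join(dropped[:10]))
    if promoter.empty:
        return pd.DataFrame(columns=betas.columns)
    grouped = betas.loc[promoter["probe"].to_numpy()]
    grouped.index = promoter["gene"].to_numpy()
    return grouped.groupby(level=0).mean()


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1, input order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def de_test(cancer: pd.DataFrame, normal: pd.DataFrame, cohort_id: str = "",
            lfc_threshold: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene differential expression between log2 matrices.

    log2fc is the difference of group means; p comes from Welch's t-test and
    is BH-adjusted across all tested genes.
    """
    genes = [g for g in cancer.index if g in set(normal.index)]
    if not genes:
        raise InvalidInputError("matrices share no genes")
    if cancer.shape[1] < 2 or normal.shape[1] < 2:
        raise InvalidInputError("need >= 2 samples per group")
    c = cancer.loc[genes].to_numpy(dtype=float)
    n = normal.loc[genes].to_numpy(dtype=float)
    lfc = c.mean(axis=1) - n.mean(axis=1)
    t, p = sps.ttest_ind(c, n, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    padj = bh_adjust(p)
    call = np.full(len(genes), "ns", dtype=object)
    call[(lfc > lfc_threshold) & (padj < alpha)] = "up"
    call[(lfc < -lfc_threshold) & (padj < alpha)] = "down"
    return pd.DataFrame({
        "gene": genes,
        "cohort": cohort_id,
        "log2fc": lfc,
        "p": p,
        "p_adj": padj,
        "call": call,
    })


def diff_methylation(cancer_betas: pd.DataFrame, normal_betas: pd.DataFrame,
                     cohort_id: str = "", alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene differential promoter methylation.

    delta_beta is mean(cancer beta) - mean(normal beta); p is from the
    Wilcoxon rank-sum test. Calls: hyper (delta_beta > 0, p < alpha),
    hypo (delta_beta < 0, p < alpha), else ns.
    """
    if cancer_betas.shape[1] == 0 or normal_betas.shape[1] == 0:
        raise InvalidInputError("both cohorts must be non-empty")
    for df in (cancer_betas, normal_betas):
        vals = df.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise InvalidInputError("beta values must lie in [0, 1]")
    genes = [g for g in cancer_betas.index if g in set(normal_betas.index)]
    rows = []
    for g in genes:
        c = cancer_betas.loc[g].to_numpy(dtype=float)
        n = normal_betas.loc[g].to_numpy(dtype=float)
        res = rank_sum_test(c, n)
        delta = float(c.mean() - n.mean())
        if res.p < alpha and delta > 0:
            call = "hyper"
        elif res.p < alpha and delta < 0:
            call = "hypo"
        else:
            call = "ns"
        rows.append((g, cohort_id, float(c.mean()), float(n.mean()), delta, res.p, call))
    return pd.DataFrame(rows, columns=[
        "gene", "cohort", "mean_beta_cancer", "mean_beta_normal",
        "delta_beta", "p", "call"])
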