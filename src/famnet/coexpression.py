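"""Empirical-null family co-expression networks and rewiring tests.

The null distribution for edge significance is the set of |Pearson r| values
over randomly chosen background (protein-coding) gene pairs computed in the
same condition; a family pair's empirical p is the fraction of null pairs
whose |r| is at least as large. Networks keep pairs with p strictly below
alpha (default 0.01). Cancer-vs-normal rewiring per cohort is summarized by
an exact two-sided binomial test on the condition-exclusive edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (InconsistentUniverseError, InvalidInputError,
                     UndefinedCorrelationError)

__all__ = [
    "NullDistribution",
    "NetworkComparison",
    "pairwise_correlations",
    "sample_null_distribution",
    "empirical_pvalue",
    "build_network",
    "classify_edges",
    "binomial_shift_test",
    "coexpression_analysis",
]


@dataclass
class NullDistribution:
    """Sorted |r| values over random background-gene pairs in one condition."""

    condition: str
    values: np.ndarray  # sorted ascending
    n_pairs: int
    seed: int | None = None

    def __post_init__(self):
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.values.size != self.n_pairs:
            raise InvalidInputError("null length must equal n_pairs")
        if self.values.size and (self.values[0] < 0 or self.values[-1] > 1):
            raise InvalidInputError("null |r| values must lie in [0, 1]")


@dataclass
class NetworkComparison:
    cohort_id: str
    n_cancer_edges: int
    n_normal_edges: int
    n_shared: int
    n_cancer_only: int
    n_normal_only: int
    p: float
    direction: str  # increase / decrease / none


def _standardized(expr: pd.DataFrame, genes: Sequence[str]) -> np.ndarray:
    x = expr.loc[list(genes)].to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise UndefinedCorrelationError(f"constant gene(s): {bad[:5]}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def pairwise_correlations(expr: pd.DataFrame, pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Pearson r for each (unordered) gene pair over the matrix columns."""
    pairs = list(pairs)
    if expr.shape[1] < 3:
        raise InvalidInputError("need >= 3 samples")
    genes = sorted({g for p in pairs for g in p})
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise InvalidInputError(f"genes absent from matrix: {missing[:5]}")
    z = _standardized(expr, genes)
    idx = {g: k for k, g in enumerate(genes)}
    n = expr.shape[1]
    rs = [float(z[idx[a]] @ z[idx[b]] / n) for a, b in pairs]
    return pd.DataFrame({"gene_a": [p[0] for p in pairs],
                         "gene_b": [p[1] for p in pairs],
                         "r": rs})


def sample_null_distribution(expr: pd.DataFrame, background_genes: Sequence[str],
                             n_pairs: int = 10000, seed=None,
                             condition: str = "") -> NullDistribution:
    """|r| over ``n_pairs`` random background pairs.

    Distinct unordered pairs are sampled without replacement when the pool is
    large enough, with replacement otherwise. Constant background genes are
    silently dropped from the pool.
    """
    if n_pairs < 1:
        raise InvalidInputError("n_pairs must be >= 1")
    pool = [g for g in background_genes if g in expr.index]
    x = expr.loc[pool].to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    pool = [g for g, k in zip(pool, keep) if k]
    if len(pool) < 2:
        raise InvalidInputError("background pool must contain >= 2 usable genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(pool)
    iu, ju = np.triu_indices(m, k=1)
    total = iu.size
    if total >= n_pairs:
        codes = rng.choice(total, size=n_pairs, replace=False)
    else:
        codes = rng.integers(0, total, size=n_pairs)
    z = _standardized(expr, pool)
    n = expr.shape[1]
    r = np.einsum("ij,ij->i", z[iu[codes]], z[ju[codes]]) / n
    return NullDistribution(condition=condition, values=np.abs(np.clip(r, -1, 1)),
                            n_pairs=n_pairs,
                            seed=seed if isinstance(seed, int) else None)


def empirical_pvalue(r_obs: float, null: NullDistribution) -> float:
    """p = (# null |r| >= |r_obs|) / n_pairs, ties counting as >=."""
    if null.n_pairs == 0:
        raise InvalidInputError("empty null distribution")
    k = null.values.size - int(np.searchsorted(null.values, abs(r_obs), side="left"))
    return k / null.n_pairs


def build_network(edges: pd.DataFrame, alpha: float = 0.01,
                  condition: str = "cancer") -> nx.Graph:
    """Graph of pairs whose empirical p in ``condition`` is strictly < alpha.

    ``edges`` needs columns gene_a, gene_b and p_<condition>.
    """
    col = f"p_{condition}"
    g = nx.Graph()
    for _, row in edges.iterrows():
        if row[col] < alpha:
            g.add_edge(row["gene_a"], row["gene_b"])
    return g


def _key(a, b):
    return (a, b) if a <= b else (b, a)


def classify_edges(cancer_net: nx.Graph, normal_net: nx.Graph,
                   universe: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Partition the tested-pair universe into the four edge statuses."""
    uni = [_key(a, b) for a, b in universe]
    uni_set = set(uni)
    for net, name in ((cancer_net, "cancer"), (normal_net, "normal")):
        for a, b in net.edges:
            if _key(a, b) not in uni_set:
                raise InconsistentUniverseError(
                    f"{name} network edge {(a, b)} outside the tested universe")
    c_edges = {_key(a, b) for a, b in cancer_net.edges}
    n_edges = {_key(a, b) for a, b in normal_net.edges}
    status = []
    for pair in uni:
        in_c, in_n = pair in c_edges, pair in n_edges
        if in_c and in_n:
            status.append("shared")
        elif in_c:
            status.append("cancer_only")
        elif in_n:
            status.append("normal_only")
        else:
            status.append("insignificant")
    return pd.DataFrame({"gene_a": [p[0] for p in uni],
                         "gene_b": [p[1] for p in uni],
                         "status": status})


def binomial_shift_test(n_cancer_only: int, n_normal_only: int,
                        alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided exact binomial test of cancer-only vs normal-only edge
    counts at p0 = 0.5; direction requires significance at ``alpha``."""
    n = n_cancer_only + n_normal_only
    if n == 0:
        return float("nan"), "none"
    p = float(sps.binomtest(n_cancer_only, n, 0.5, alternative="two-sided").pvalue)
    if p < alpha and n_cancer_only > n / 2:
        direction = "increase"
    elif p < alpha and n_cancer_only < n / 2:
        direction = "decrease"
    else:
        direction = "none"
    return p, direction


def coexpression_analysis(expr_cancer: pd.DataFrame, expr_normal: pd.DataFrame,
                          family_genes: Sequence[str],
                          background_genes: Sequence[str],
                          n_null_pairs: int = 10000, alpha: float = 0.01,
                          seed=None, cohort_id: str = ""):
    """Full per-cohort rewiring analysis.

    Returns ``(edges, comparison)`` where ``edges`` holds r and empirical p
    in both conditions plus the status of every family pair, and
    ``comparison`` is the binomial rewiring summary. Family genes that are
    constant in either condition are excluded from the pair universe.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    usable = [g for g in family_genes
              if g in expr_cancer.index and g in expr_normal.index
              and expr_cancer.loc[g].std() > 0 and expr_normal.loc[g].std() > 0]
    pairs = [(a, b) for i, a in enumerate(usable) for b in usable[i + 1:]]
    if not pairs:
        raise InvalidInputError("fewer than two usable family genes")
    null_c = sample_null_distribution(expr_cancer, background_genes,
                                      n_null_pairs, rng, condition="cancer")
    null_n = sample_null_distribution(expr_normal, background_genes,
                                      n_null_pairs, rng, condition="normal")
    r_c = pairwise_correlations(expr_cancer, pairs)["r"].to_numpy()
    r_n = pairwise_correlations(expr_normal, pairs)["r"].to_numpy()
    p_c = np.array([empirical_pvalue(r, null_c) for r in r_c])
    p_n = np.array([empirical_pvalue(r, null_n) for r in r_n])
    edges = pd.DataFrame({
        "gene_a": [p[0] for p in pairs],
        "gene_b": [p[1] for p in pairs],
        "r_cancer": r_c, "r_normal": r_n,
        "p_cancer": p_c, "p_normal": p_n,
    })
    cancer_net = build_network(edges, alpha, "cancer")
    normal_net = build_network(edges, alpha, "normal")
    edges["status"] = classify_edges(cancer_net, normal_net, pairs)["status"]
    counts = edges["status"].value_counts()
    n_shared = int(counts.get("shared", 0))
    n_co = int(counts.get("cancer_only", 0))
    n_no = int(counts.get("normal_only", 0))
    p, direction = binomial_shift_test(n_co, n_no)
    comparison = NetworkComparison(
        cohort_id=cohort_id,
        n_cancer_edges=n_co + n_shared,
        n_normal_edges=n_no + n_shared,
        n_shared=n_shared, n_cancer_only=n_co, n_normal_only=n_no,
        p=p, direction=direction)
    return edges, comparison
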