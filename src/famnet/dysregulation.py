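"""Gain/loss rewiring of TF-target correlations between conditions.

The statistic for a TF-target pair (A, B) is

    delta_r = PearsonR(A, B | cancer) - PearsonR(A, B | normal)

and its significance comes from shuffling the cancer/normal labels of the
pooled samples (group sizes preserved) and counting permutations whose
statistic reaches the observed one: p = sum(S_i) / N with no small-sample
correction, so p can be exactly 0. The default comparison is two-sided on
|delta_r|; a signed one-sided variant is available via ``mode="signed"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import NamedTuple

import numpy as np
import pandas as pd

from .differential import bh_adjust
from .errors import InvalidInputError, TableParseError, UndefinedCorrelationError
from .stats import pearson

__all__ = [
    "filter_targets",
    "delta_r",
    "permutation_pvalue",
    "exact_permutation_pvalue",
    "classify_pattern",
    "analyze_target_dysregulation",
    "PermutationResult",
    "ExactPermutationResult",
]

_VAR_EPS = 1e-12
_TIE_TOL = 1e-12


def filter_targets(table: pd.DataFrame, min_score: float = 100.0) -> pd.DataFrame:
    """Keep TF-target rows with significance score strictly above ``min_score``."""
    scores = pd.to_numeric(table["score"], errors="coerce")
    if scores.isna().any():
        bad = table.loc[scores.isna(), "score"].iloc[0]
        raise TableParseError(f"non-numeric significance score: {bad!r}")
    return table.loc[scores > min_score].reset_index(drop=True)


def delta_r(expr_a_cancer, expr_b_cancer, expr_a_normal, expr_b_normal) -> float:
    """Difference of Pearson correlations, cancer minus normal."""
    r_c = pearson(expr_a_cancer, expr_b_cancer).r
    r_n = pearson(expr_a_normal, expr_b_normal).r
    return r_c - r_n


class PermutationResult(NamedTuple):
    p: float
    s_count: int
    n_perm: int
    observed: float
    n_resampled: int


class ExactPermutationResult(NamedTuple):
    p: float
    n_splits: int
    observed: float


def _delta_from_masks(masks: np.ndarray, a: np.ndarray, b: np.ndarray,
                      n_cancer: int):
    """delta_r for each row-mask (True = cancer) via sufficient statistics.

    Returns (delta, degenerate) where degenerate flags masks yielding a
    zero-variance subgroup for either gene.
    """
    n = a.size
    feats = np.column_stack([a, b, a * a, b * b, a * b])
    tot = feats.sum(axis=0)
    sc = masks.astype(float) @ feats
    sn = tot - sc
    out = np.empty(masks.shape[0])
    degenerate = np.zeros(masks.shape[0], dtype=bool)
    for sums, k, sign in ((sc, n_cancer, 1.0), (sn, n - n_cancer, -1.0)):
        ma, mb = sums[:, 0] / k, sums[:, 1] / k
        va = sums[:, 2] / k - ma * ma
        vb = sums[:, 3] / k - mb * mb
        cov = sums[:, 4] / k - ma * mb
        bad = (va <= _VAR_EPS) | (vb <= _VAR_EPS)
        degenerate |= bad
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(va * vb)
        r = np.clip(np.where(bad, 0.0, r), -1.0, 1.0)
        if sign > 0:
            out = r.copy()
        else:
            out -= r
    return out, degenerate


def _exceeds(delta_perm: np.ndarray, observed: float, mode: str) -> np.ndarray:
    if mode == "absolute":
        return np.abs(delta_perm) >= abs(observed) - _TIE_TOL
    if mode == "signed":
        if observed >= 0:
            return delta_perm >= observed - _TIE_TOL
        return delta_perm <= observed + _TIE_TOL
    raise InvalidInputError(f"unknown comparison mode {mode!r}")


def _prepare(expr_a, expr_b, labels):
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == labels.shape):
        raise InvalidInputError("expression vectors and labels must align")
    n_c = int(labels.sum())
    n_n = labels.size - n_c
    if n_c < 3 or n_n < 3:
        raise InvalidInputError("need >= 3 samples in each condition")
    obs, bad = _delta_from_masks(labels[None, :], a, b, n_c)
    if bad[0]:
        raise UndefinedCorrelationError("constant subvector in the observed split")
    return a, b, labels, n_c, float(obs[0])


def permutation_pvalue(expr_a, expr_b, labels, n_perm: int = 1000,
                       seed=None, mode: str = "absolute",
                       exhaustive: bool = False) -> PermutationResult:
    """Label-permutation p-value for the observed delta_r.

    ``labels`` flags cancer samples in the pooled vectors. Each permutation
    reassigns the labels uniformly at random preserving group sizes;
    permutations producing a constant subgroup are redrawn (counted in
    ``n_resampled``). p = s_count / n_perm with ties counting as exceeding.
    With ``exhaustive=True`` (<= 12 samples) every distinct assignment is
    enumerated instead, matching :func:`exact_permutation_pvalue`.
    """
    if exhaustive:
        res = exact_permutation_pvalue(expr_a, expr_b, labels, mode=mode)
        hits = round(res.p * res.n_splits)
        return PermutationResult(res.p, hits, res.n_splits, res.observed, 0)
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    a, b, labels, n_c, observed = _prepare(expr_a, expr_b, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a.size
    masks = rng.random((n_perm, n)).argsort(axis=1) < n_c
    delta, degenerate = _delta_from_masks(masks, a, b, n_c)
    n_resampled = 0
    attempts = 0
    while degenerate.any():
        attempts += 1
        if attempts > 100:
            raise InvalidInputError("could not draw non-degenerate permutations")
        idx = np.flatnonzero(degenerate)
        n_resampled += idx.size
        masks[idx] = rng.random((idx.size, n)).argsort(axis=1) < n_c
        d_new, bad_new = _delta_from_masks(masks[idx], a, b, n_c)
        delta[idx] = d_new
        degenerate[idx] = bad_new
    s_count = int(_exceeds(delta, observed, mode).sum())
    return PermutationResult(s_count / n_perm, s_count, n_perm, observed, n_resampled)


def exact_permutation_pvalue(expr_a, expr_b, labels,
                             mode: str = "absolute") -> ExactPermutationResult:
    """Exhaustive enumeration over all label assignments (<= 12 samples).

    p is the fraction of distinct group-size-preserving assignments whose
    statistic reaches the observed one (ties included); the observed
    assignment is itself enumerated, so p >= 1 / C(n, n_cancer).
    """
    a, b, labels, n_c, observed = _prepare(expr_a, expr_b, labels)
    n = a.size
    if n > 12:
        raise InvalidInputError(f"enumeration limited to 12 samples, got {n}")
    n_splits = comb(n, n_c)
    masks = np.zeros((n_splits, n), dtype=bool)
    for row, idx in enumerate(combinations(range(n), n_c)):
        masks[row, list(idx)] = True
    delta, degenerate = _delta_from_masks(masks, a, b, n_c)
    keep = ~degenerate
    if not keep.any():
        raise InvalidInputError("every label split is degenerate")
    hits = int(_exceeds(delta[keep], observed, mode).sum())
    return ExactPermutationResult(hits / int(keep.sum()), int(keep.sum()), observed)


def classify_pattern(delta: float, p: float, alpha: float = 0.05) -> str:
    """gain (delta_r > 0), loss (delta_r < 0) when significant, else none."""
    if not (np.isfinite(delta) and np.isfinite(p)):
        return "none"
    if p < alpha and delta > 0:
        return "gain"
    if p < alpha and delta < 0:
        return "loss"
    return "none"


def analyze_target_dysregulation(expr_cancer: pd.DataFrame,
                                 expr_normal: pd.DataFrame,
                                 targets: pd.DataFrame,
                                 cohort_id: str = "",
                                 n_perm: int = 1000,
                                 alpha: float = 0.05,
                                 min_score: float = 100.0,
                                 seed=None,
                                 mode: str = "absolute") -> pd.DataFrame:
    """delta_r + permutation p for every scored TF-target pair of a cohort.

    Pairs are score-filtered first; BH adjustment is applied within each TF
    family and the gain/loss pattern uses the adjusted p at ``alpha``.
    Pairs whose genes are absent or constant in either condition are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept = filter_targets(targets, min_score)
    n_c, n_n = expr_cancer.shape[1], expr_normal.shape[1]
    labels = np.concatenate([np.ones(n_c, dtype=bool), np.zeros(n_n, dtype=bool)])
    rows = []
    for _, row in kept.iterrows():
        tf, target = row["tf"], row["target"]
        ok = all(g in expr_cancer.index and g in expr_normal.index
                 for g in (tf, target))
        if not ok:
            continue
        ac = expr_cancer.loc[tf].to_numpy(dtype=float)
        bc = expr_cancer.loc[target].to_numpy(dtype=float)
        an = expr_normal.loc[tf].to_numpy(dtype=float)
        bn = expr_normal.loc[target].to_numpy(dtype=float)
        try:
            r_c = pearson(ac, bc).r
            r_n = pearson(an, bn).r
            res = permutation_pvalue(np.concatenate([ac, an]),
                                     np.concatenate([bc, bn]),
                                     labels, n_perm=n_perm, seed=rng, mode=mode)
        except UndefinedCorrelationError:
            continue
        rows.append((tf, target, cohort_id, r_c, r_n, r_c - r_n,
                     res.s_count, res.n_perm, res.p))
    out = pd.DataFrame(rows, columns=["tf", "target", "cohort", "r_cancer",
                                      "r_normal", "delta_r", "s_count",
                                      "n_perm", "p_perm"])
    if out.empty:
        out["fdr"] = pd.Series(dtype=float)
        out["pattern"] = pd.Series(dtype=object)
        return out
    out["fdr"] = np.nan
    for _, idx in out.groupby("tf").groups.items():
        out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_perm"].to_numpy())
    out["pattern"] = [classify_pattern(d, f, alpha)
                      for d, f in zip(out["delta_r"], out["fdr"])]
    return out
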