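"""Survival stratification and drug-sensitivity association.

Patients are dichotomized at the cohort median of a gene's expression
(ties to "low"), compared by Kaplan-Meier / log-rank, and summarized by a
univariate Cox model on the binary group (Breslow ties by default, Efron
optional; a continuous-covariate mode exists for sensitivity checks).
Drug screening keeps gene-drug pairs with |Pearson r| > 0.2 and p < 0.05
(both strict), then joins drug-target annotations into an axis table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSplitError, InvalidInputError
from .stats import pearson

__all__ = [
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "cox_score_test",
    "drug_correlation",
    "build_drug_axis",
    "CoxResult",
    "DrugAssociation",
    "LogrankResult",
]

log = logging.getLogger(__name__)


def median_split(values) -> np.ndarray:
    """Assign "high" to samples strictly above the median, "low" otherwise.

    Ties at the median go to "low". Raises when fewer than 4 samples are
    given or when either group would be empty.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InvalidInputError(f"need >= 4 samples for a median split, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateSplitError("all expression values identical")
    med = np.median(v)
    groups = np.where(v > med, "high", "low")
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise DegenerateSplitError("median split produced an empty group")
    return groups


def _check_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise InvalidInputError("times and events must align")
    if t.size == 0:
        raise InvalidInputError("need at least one record")
    if np.any(t <= 0):
        raise InvalidInputError("follow-up times must be > 0")
    if not np.isin(e, (0, 1)).all():
        raise InvalidInputError("event flags must be 0 or 1")
    return t, e


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with the risk set, event count
    and the post-step survival probability; the curve starts at S = 1, so an
    all-censored input yields an empty frame (S identically 1).
    """
    t, e = _check_surv(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    for ut in np.unique(t[e == 1]):
        at_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(ut), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


class LogrankResult(NamedTuple):
    chi_square: float
    p: float
    n_events: int


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test (hypergeometric variance, chi2 with 1 df).

    Zero events in total is a no-test result (NaN statistic and p).
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, dtype=bool), np.ones(tb.size, dtype=bool)])
    n_events = int(e.sum())
    if n_events == 0:
        return LogrankResult(float("nan"), float("nan"), 0)
    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = int(at_risk.sum())
        n1 = int((at_risk & ~grp).sum())
        d = int(((t == ut) & (e == 1)).sum())
        d1 = int(((t == ut) & (e == 1) & ~grp).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogrankResult(float("nan"), float("nan"), n_events)
    chi2 = o_minus_e**2 / var
    return LogrankResult(float(chi2), float(sps.chi2.sf(chi2, df=1)), n_events)


# ----------------------------------------------------------------------
@dataclass
class CoxResult:
    log_hr: float
    hr: float
    se: float
    ci_low: float  # on the hazard-ratio scale
    ci_high: float
    p: float
    direction: str  # risk / protective / ns
    n: int
    n_events: int
    converged: bool
    separation: bool


def _cox_derivatives(beta: float, t, x, e, ties: str):
    """Score and information of the Cox partial likelihood at ``beta``."""
    w = np.exp(beta * x)
    # suffix sums over samples still at risk (times sorted ascending)
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum((w * x)[::-1])[::-1]
    c2 = np.cumsum((w * x * x)[::-1])[::-1]
    score = 0.0
    info = 0.0
    for ut in np.unique(t[e == 1]):
        f = int(np.searchsorted(t, ut, side="left"))
        mask = (t == ut) & (e == 1)
        d = int(mask.sum())
        sum_x_d = float(x[mask].sum())
        if ties == "breslow" or d == 1:
            s0, s1, s2 = c0[f], c1[f], c2[f]
            score += sum_x_d - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        elif ties == "efron":
            wd = w[mask]
            d0, d1_, d2 = float(wd.sum()), float((wd * x[mask]).sum()), float((wd * x[mask] ** 2).sum())
            for ell in range(d):
                frac = ell / d
                s0 = c0[f] - frac * d0
                s1 = c1[f] - frac * d1_
                s2 = c2[f] - frac * d2
                score += sum_x_d / d - s1 / s0
                info += s2 / s0 - (s1 / s0) ** 2
        else:
            raise InvalidInputError(f"unknown tie method {ties!r}")
    return score, info


def cox_score_test(covariate, times, events) -> tuple[float, float]:
    """Score (Rao) test of the Cox model at beta = 0; chi2 with 1 df."""
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    order = np.argsort(t, kind="stable")
    t, x, e = t[order], x[order], e[order]
    u, i = _cox_derivatives(0.0, t, x, e, "breslow")
    if i == 0:
        return float("nan"), float("nan")
    chi2 = u * u / i
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def cox_univariate(covariate, times, events, ties: str = "breslow",
                   alpha: float = 0.05, max_iter: int = 100,
                   tol: float = 1e-10) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton-Raphson.

    ``covariate`` is typically the binary median-split group (0/1) but any
    numeric vector works. Monotone likelihood (complete separation) is
    flagged with an unbounded confidence interval instead of failing.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise InvalidInputError("covariate and times must align")
    if np.ptp(x) == 0:
        raise InvalidInputError("covariate is constant")
    if e.sum() == 0:
        raise InvalidInputError("no events observed")
    order = np.argsort(t, kind="stable")
    t, x, e = t[order], x[order], e[order]
    scale = float(np.std(x)) or 1.0
    xs = x / scale
    beta = 0.0
    converged = False
    separation = False
    for _ in range(max_iter):
        u, i = _cox_derivatives(beta, t, xs, e, ties)
        if i <= 0:
            separation = True
            break
        step = u / i
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 30.0:
            separation = True
            break
        if abs(step) < tol:
            converged = True
            break
    _, info = _cox_derivatives(beta, t, xs, e, ties)
    log_hr = beta / scale
    if separation or info <= 0:
        se = float("inf")
        p = float("nan")
        ci_low, ci_high = 0.0, float("inf")
    else:
        se = 1.0 / np.sqrt(info) / scale
        z = log_hr / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        q = sps.norm.ppf(1 - alpha / 2)
        ci_low = float(np.exp(log_hr - q * se))
        ci_high = float(np.exp(log_hr + q * se))
    hr = float(np.exp(log_hr))
    if np.isfinite(p) and p < alpha:
        direction = "risk" if hr > 1 else "protective"
    else:
        direction = "ns"
    return CoxResult(float(log_hr), hr, float(se), ci_low, ci_high, p,
                     direction, int(t.size), int(e.sum()), converged, separation)


# ----------------------------------------------------------------------
@dataclass
class DrugAssociation:
    gene_id: str
    drug_id: str
    pcc: float
    p: float
    retained: bool
    n: int


def drug_correlation(expr, ic50, gene_id: str = "", drug_id: str = "",
                     pcc_threshold: float = 0.2, alpha: float = 0.05) -> DrugAssociation:
    """Pearson association between expression and IC50 across cell lines.

    Series inputs are aligned on their shared index; retention requires
    |r| > ``pcc_threshold`` AND p < ``alpha`` (both strict).
    """
    if isinstance(expr, pd.Series) and isinstance(ic50, pd.Series):
        shared = expr.index.intersection(ic50.index)
        expr = expr.loc[shared].to_numpy(dtype=float)
        ic50 = ic50.loc[shared].to_numpy(dtype=float)
    else:
        expr = np.asarray(expr, dtype=float)
        ic50 = np.asarray(ic50, dtype=float)
    if expr.size < 3:
        raise InvalidInputError(f"need >= 3 shared cell lines, got {expr.size}")
    res = pearson(expr, ic50)
    retained = abs(res.r) > pcc_threshold and res.p < alpha
    return DrugAssociation(gene_id, drug_id, res.r, res.p, retained, int(expr.size))


def build_drug_axis(gene_drug: pd.DataFrame, gene_target: pd.DataFrame,
                    drug_annotation: pd.DataFrame) -> pd.DataFrame:
    """(pathway, drug, gene, drug_target) rows where both screens pass.

    ``gene_drug`` and ``gene_target`` carry retained flags from
    :func:`drug_correlation`; drugs without an annotation row are dropped
    (logged). Output rows are deduplicated and sorted.
    """
    gd = gene_drug[gene_drug["retained"].astype(bool)]
    gt = gene_target[gene_target["retained"].astype(bool)]
    anno = drug_annotation.drop_duplicates()
    unannotated = sorted(set(gd["drug"]) - set(anno["drug"]))
    if unannotated:
        log.info("dropping %d retained drug(s) without annotation: %s",
                 len(unannotated), ", ".join(unannotated[:10]))
    merged = gd.merge(anno, on="drug")
    merged = merged.merge(gt[["gene", "target"]].rename(columns={"target": "target_gene"}),
                          on=["gene", "target_gene"])
    out = (merged[["pathway", "drug", "gene", "target_gene"]]
           .rename(columns={"target_gene": "drug_target"})
           .drop_duplicates()
           .sort_values(["pathway", "drug", "gene", "drug_target"])
           .reset_index(drop=True))
    return out
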