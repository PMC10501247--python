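"""Gene-level alteration frequencies and alteration-vs-expression tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError, MissingSampleError
from .stats import PearsonResult, RankSumResult, pearson, rank_sum_test

__all__ = [
    "AlterationFrequency",
    "mutation_frequency",
    "cnv_frequency",
    "alteration_expression_test",
    "omic_expression_correlation",
]


@dataclass(frozen=True)
class AlterationFrequency:
    gene_id: str
    cohort_id: str
    mutation_freq: float
    amp_freq: float
    del_freq: float
    n_samples: int


def mutation_frequency(muts: pd.DataFrame, cohort_samples: Sequence[str],
                       genes: Sequence[str], cohort_id: str = "",
                       variant_classes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene fraction of cohort samples carrying at least one mutation.

    Samples with multiple variant rows in one gene count once. When
    ``variant_classes`` is given, only rows of those classes qualify.
    """
    if len(cohort_samples) == 0:
        raise InvalidInputError("cohort sample list is empty")
    cohort = set(cohort_samples)
    sub = muts
    if variant_classes is not None:
        sub = sub[sub["variant_class"].isin(set(variant_classes))]
    sub = sub[sub["sample"].isin(cohort)]
    counts = sub.groupby("gene")["sample"].nunique()
    n = len(cohort)
    rows = [(g, cohort_id, counts.get(g, 0) / n, n) for g in genes]
    return pd.DataFrame(rows, columns=["gene", "cohort", "mutation_freq", "n_samples"])


def cnv_frequency(cnv: pd.DataFrame, cohort_samples: Sequence[str],
                  amp_ge: float = 1.0, del_le: float = -1.0,
                  cohort_id: str = "") -> pd.DataFrame:
    """Amplification/deletion frequency per gene at value thresholds.

    A sample is amplified when its value is >= ``amp_ge`` and deleted when
    <= ``del_le``; the thresholds make the calls mutually exclusive.
    """
    if not del_le < amp_ge:
        raise InvalidParameterError(
            f"del_le ({del_le}) must be strictly below amp_ge ({amp_ge})")
    missing = [s for s in cohort_samples if s not in cnv.columns]
    if missing:
        raise MissingSampleError(f"samples absent from CNV matrix: {missing[:5]}")
    sub = cnv[list(cohort_samples)]
    n = sub.shape[1]
    amp = (sub >= amp_ge).sum(axis=1) / n
    dele = (sub <= del_le).sum(axis=1) / n
    return pd.DataFrame({
        "gene": sub.index,
        "cohort": cohort_id,
        "amp_freq": amp.to_numpy(),
        "del_freq": dele.to_numpy(),
        "n_samples": n,
    })


def alteration_expression_test(expr, status) -> RankSumResult:
    """Wilcoxon rank-sum comparison of expression between altered and
    unaltered samples (altered first)."""
    expr = np.asarray(expr, dtype=float)
    status = np.asarray(status, dtype=bool)
    if expr.shape != status.shape:
        raise InvalidInputError("expression and status must align")
    altered = expr[status]
    unaltered = expr[~status]
    if altered.size == 0 or unaltered.size == 0:
        raise InvalidInputError("both altered and unaltered groups must be non-empty")
    return rank_sum_test(altered, unaltered)


def omic_expression_correlation(expr, other) -> PearsonResult:
    """Pearson correlation between expression and another per-sample omic
    value (CNV dosage, promoter beta, ...)."""
    return pearson(expr, other)
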