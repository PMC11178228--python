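"""Simplified differential-expression surrogate.

Size factors follow the median-of-ratios scheme: for each sample, the
median over all-positive gene rows of ``count / geometric-mean-row``.
Testing is a two-sided Welch t-test on ``log2(normalized + pseudocount)``
per gene, with the volcano significance rule: a gene is significant
when ``|log2fc| >= 1`` (inclusive) *and* ``p < 0.05`` (exclusive).

This module is deliberately a simplified, fully documented surrogate
for a shrinkage-based DE framework; it makes no claim of numerical
agreement with one, and every output table carries
``method=simplified-surrogate``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["size_factors", "differential_expression", "replicate_qc"]


def size_factors(matrix: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    Only gene rows positive in every sample enter the median.  When no
    such row exists, an error suggests the ``pseudocount`` option
    (which is added to all counts before the computation).
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    m = matrix.astype(float) + pseudocount
    positive = (m > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene row is positive in every sample; pass pseudocount > 0 "
            "to compute size factors on shifted counts"
        )
    sub = m.loc[positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = sub.div(geomean, axis=0).median(axis=0)
    factors.name = "size_factor"
    return factors


def differential_expression(
    matrix: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series | dict[str, str],
    reference: str = "WT",
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene log2 fold change, Welch t-test and volcano significance.

    ``groups`` maps sample name to group label; exactly two groups are
    required and ``reference`` names the denominator group.  With fewer
    than two replicates in either group p-values are NA and nothing is
    significant (a warning is logged for n=2, where the t-test is
    underpowered).
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2 or reference not in labels:
        raise ValueError(f"need exactly two groups including {reference!r}, got {labels}")
    other = next(g for g in labels if g != reference)
    ref_samples = groups.index[groups == reference].tolist()
    mut_samples = groups.index[groups == other].tolist()
    if min(len(ref_samples), len(mut_samples)) == 2:
        logger.warning(
            "differential_expression: only two replicates per group; "
            "the Welch t-test is underpowered at n=2"
        )

    norm = matrix.astype(float).div(factors, axis=1)
    mean_ref = norm[ref_samples].mean(axis=1)
    mean_mut = norm[mut_samples].mean(axis=1)
    log2fc = np.log2((mean_mut + pseudocount) / (mean_ref + pseudocount))

    if min(len(ref_samples), len(mut_samples)) >= 2:
        la = np.log2(norm[mut_samples].to_numpy() + pseudocount)
        lb = np.log2(norm[ref_samples].to_numpy() + pseudocount)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = res.pvalue
    else:
        p = np.full(len(matrix), np.nan)

    out = pd.DataFrame(
        {
            "base_mean": (mean_ref + mean_mut) / 2.0,
            "log2fc": log2fc,
            "p_value": p,
        },
        index=matrix.index,
    )
    out["significant"] = (
        (out["log2fc"].abs() >= lfc_threshold) & (out["p_value"] < p_threshold)
    ).fillna(False)
    out.attrs["method"] = "simplified-surrogate"
    return out


def replicate_qc(
    sample_a: np.ndarray | pd.Series,
    sample_b: np.ndarray | pd.Series,
    threshold: float = 0.98,
    log_transform: bool = True,
) -> tuple[float, bool]:
    """Pearson correlation between replicate count vectors.

    Computed on ``log2(count + 1)`` by default; passes when
    ``r > threshold``.  Zero variance in either vector yields NA and a
    failing flag.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("replicate_qc needs two equal-length vectors with n >= 3")
    if log_transform:
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), False
    r = float(stats.pearsonr(a, b).statistic)
    return r, r > threshold
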