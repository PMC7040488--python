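"""Differential-expression screening between two condition groups.

Abundances (FPKM/TPM) are log2(x + pseudocount)-transformed; each feature
gets a Welch two-sample t-test plus a log2 fold-change of group means,
and Benjamini-Hochberg q-values over all features of the class.  A
feature is flagged significant when p < p_thr and |log2FC| > lfc_thr
(both inequalities strict, matching the printed thresholds p < 0.05 and
|FC| > 1 on the log2 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclass
class DERecord:
    feature_id: str
    feature_class: str
    comparison: tuple[str, str]
    log2fc: float
    p: float
    q: float
    direction: str
    significant: bool


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_screen(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    p_thr: float = 0.05,
    lfc_thr: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Screen every feature for differential expression in B vs A.

    Returns a DataFrame with one row per feature: log2fc (B relative to
    A, computed from group means of log2(x + pseudocount)), Welch p,
    BH q, direction and the significance flag.
    """
    if expr.unit not in ("FPKM", "TPM"):
        raise ValueError(f"DE screening expects normalized input, got unit {expr.unit!r}")
    for g in (group_a, group_b):
        if g not in set(expr.groups):
            raise ValueError(f"group {g!r} not present in matrix")
    sa = expr.samples_in_groups([group_a])
    sb = expr.samples_in_groups([group_b])
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least 2 replicates")

    log_a = np.log2(expr.values[sa].to_numpy() + pseudocount)
    log_b = np.log2(expr.values[sb].to_numpy() + pseudocount)
    log2fc = log_b.mean(axis=1) - log_a.mean(axis=1)

    # Welch's t accommodates unequal group variances; with zero variance in
    # both groups (identical values) the statistic is undefined and p := 1
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)

    significant = (p < p_thr) & (np.abs(log2fc) > lfc_thr)
    return pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "feature_class": expr.feature_class,
            "comparison": f"{group_a}-{group_b}",
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
            "significant": significant,
        }
    )
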