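"""Negative co-expression screening of miRNA-target candidate pairs.

A miRNA that represses a target leaves a negative Pearson correlation
between the two expression profiles across samples.  Candidate pairs
(from seed-match prediction) are screened with the printed thresholds
r < -0.7 and p < 0.05, both strict.  With the full nine samples those
thresholds are jointly satisfiable (r = -0.7 at n = 9 gives p ~ 0.036);
restricted to one comparison's six samples they are not (p ~ 0.121 at
the boundary), which is why the default scope is all samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .targets import TargetPair


@dataclass
class CoexprPair:
    mirna_id: str
    target_id: str
    target_class: str
    r: float
    p: float
    n: int


def correlation_with_p(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value.

    p comes from t = r * sqrt((n-2) / (1-r^2)) referred to a t
    distribution with n-2 degrees of freedom; |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("vectors must have equal length")
    if n < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance vector")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-14:  # collinear up to rounding
        return math.copysign(1.0, r), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def screen_negative_pairs(
    mirna_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    candidates: list[TargetPair],
    r_thr: float = -0.7,
    p_thr: float = 0.05,
    sample_scope: list[str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Correlate each candidate pair and keep those with r < r_thr and p < p_thr.

    ``sample_scope`` restricts the correlation to a subset of shared
    sample labels (default: all shared samples).  Expression is
    log2(x + 1)-transformed unless ``log_transform`` is off.  Returns one
    row per candidate with a ``retained`` flag.
    """
    shared = [s for s in mirna_expr.samples if s in set(target_expr.samples)]
    if sample_scope is not None:
        missing = [s for s in sample_scope if s not in shared]
        if missing:
            raise ValueError(f"sample_scope labels not shared by both matrices: {missing}")
        shared = [s for s in shared if s in set(sample_scope)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")

    mx = mirna_expr.values[shared]
    tx = target_expr.values[shared]
    if log_transform:
        mx = np.log2(mx + 1.0)
        tx = np.log2(tx + 1.0)

    rows = []
    for pair in candidates:
        if pair.mirna_id not in mx.index:
            raise ValueError(f"candidate references unknown miRNA {pair.mirna_id!r}")
        if pair.transcript_id not in tx.index:
            raise ValueError(f"candidate references unknown target {pair.transcript_id!r}")
        r, p = correlation_with_p(mx.loc[pair.mirna_id], tx.loc[pair.transcript_id])
        rows.append(
            {
                "mirna_id": pair.mirna_id,
                "target_id": pair.transcript_id,
                "target_class": pair.transcript_class,
                "r": r,
                "p": p,
                "n": len(shared),
                "retained": (r < r_thr) and (p < p_thr),
            }
        )
    return pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "target_class", "r", "p", "n", "retained"]
    )


def retained_pairs(screen: pd.DataFrame) -> list[CoexprPair]:
    return [
        CoexprPair(r.mirna_id, r.target_id, r.target_class, r.r, r.p, int(r.n))
        for r in screen.itertuples(index=False)
        if r.retained
    ]
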