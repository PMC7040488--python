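"""Hypergeometric gene-set enrichment with BH q-values and rich factors.

For a term with K annotated genes in a background of N, and n DE genes
of which x fall in the term, the enrichment p-value is the upper
(inclusive) hypergeometric tail P(X >= x).  Terms are significant at
q < 0.05 after BH adjustment over the collection.  The rich factor
x / K mirrors the usual pathway-enrichment dot-plot axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    members: set[str]
    category: str = "GO-like"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")


def hypergeom_pvalue(x: int, K: int, n: int, N: int) -> float:
    """Upper-tail (inclusive) hypergeometric p-value.

    p = sum_{k=x}^{min(n,K)} C(K,k) C(N-K,n-k) / C(N,n).
    """
    if not (0 <= x <= min(n, K)):
        raise ValueError(f"x must lie in [0, min(n, K)]: x={x}, n={n}, K={K}")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"need n <= N and K <= N: n={n}, K={K}, N={N}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich_genesets(
    de_genes: set[str],
    background: set[str],
    genesets: list[GeneSet],
    q_thr: float = 0.05,
) -> pd.DataFrame:
    """One enrichment record per term, sorted by ascending q.

    Term members are intersected with the background before counting.
    Ties in q are broken by descending rich factor, then term id.
    """
    stray = de_genes - background
    if stray:
        raise ValueError(f"DE gene(s) absent from background: {sorted(stray)[:5]}")
    N = len(background)
    n = len(de_genes)
    rows = []
    for gs in genesets:
        members = gs.members & background
        K = len(members)
        x = len(members & de_genes)
        p = hypergeom_pvalue(x, K, n, N) if K else 1.0
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "category": gs.category,
                "x": x,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "rich_factor": (x / K) if K else 0.0,
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "category", "x", "K", "n", "N", "p", "rich_factor"]
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    df["significant"] = df["q"] < q_thr
    df = df.sort_values(
        ["q", "rich_factor", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df


def top_terms(enrichment: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """The top-n report: a prefix of the q-sorted record list."""
    return enrichment.head(n).copy()


def select_development_genes(
    de_genes: set[str],
    genesets: list[GeneSet],
    name_patterns: list[str] | None = None,
) -> set[str]:
    """DE genes annotated to any term whose name matches a pattern.

    Matching is case-insensitive substring containment; the default
    pattern list is ``["development"]``.
    """
    patterns = [p.lower() for p in (name_patterns if name_patterns is not None else ["development"])]
    if not patterns:
        raise ValueError("name_patterns must be non-empty")
    selected: set[str] = set()
    for gs in genesets:
        name = gs.term_name.lower()
        if any(p in name for p in patterns):
            selected |= gs.members
    return selected & de_genes
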