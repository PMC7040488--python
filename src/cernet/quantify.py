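"""Expression normalization (FPKM, TPM) and the 2^-ddCt qPCR calculator.

FPKM (fragments per kilobase per million) is used for mRNA and lncRNA;
TPM for miRNA.  Small-RNA TPM conventionally ignores tag length
(every mature miRNA is ~22 nt), so ``tpm_matrix`` defaults to the
per-million-tags form; the length-normalized form is available for
completeness and is feature-wise proportional to FPKM within a sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


def _library_sizes(matrix: ExpressionMatrix) -> pd.Series:
    sizes = matrix.values.sum(axis=0)
    empty = sizes[sizes == 0]
    if len(empty):
        raise ValueError(f"empty library (all-zero column): {list(empty.index)}")
    return sizes


def fpkm_matrix(counts: ExpressionMatrix) -> ExpressionMatrix:
    """FPKM_ij = c_ij * 1e9 / (L_i * C_j), with C_j the column sum.

    Doubling every count in a sample leaves its FPKM column unchanged.
    """
    if counts.unit != "count":
        raise ValueError(f"expected count unit, got {counts.unit!r}")
    if counts.lengths is None:
        raise ValueError("FPKM requires feature lengths")
    missing = counts.lengths[counts.lengths.isna()]
    if len(missing):
        raise ValueError(f"missing length for feature(s): {list(missing.index)}")
    sizes = _library_sizes(counts)
    fpkm = counts.values * 1e9
    fpkm = fpkm.div(counts.lengths, axis=0).div(sizes, axis=1)
    return counts.copy_with(fpkm, "FPKM")


def tpm_matrix(counts: ExpressionMatrix, mode: str = "per_million_tags") -> ExpressionMatrix:
    """TPM with per-sample columns summing to 1e6.

    ``per_million_tags`` (default, the small-RNA convention):
    TPM_ij = c_ij * 1e6 / C_j.  ``length_normalized``: counts are first
    divided by feature length, then scaled to a column sum of 1e6.
    """
    if counts.unit != "count":
        raise ValueError(f"expected count unit, got {counts.unit!r}")
    if mode == "per_million_tags":
        rates = counts.values
    elif mode == "length_normalized":
        if counts.lengths is None:
            raise ValueError("length_normalized TPM requires feature lengths")
        rates = counts.values.div(counts.lengths, axis=0)
    else:
        raise ValueError(f"unknown TPM mode {mode!r}")
    sizes = rates.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError(
            f"empty library (all-zero column): {list(sizes.index[sizes == 0])}"
        )
    tpm = rates.mul(1e6, axis=0).div(sizes, axis=1)
    return counts.copy_with(tpm, "TPM")


def ddct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
    sample_col: str = "sample",
    gene_col: str = "gene",
    ct_col: str = "Ct",
    group_col: str = "group",
) -> pd.Series:
    """Relative expression by the 2^-ddCt method.

    dCt_s = Ct(target, s) - Ct(reference, s); ddCt_s = dCt_s minus the mean
    dCt over calibrator-group samples; returns 2^-ddCt per sample.  The
    geometric mean of the returned values over the calibrator group is 1.
    """
    wide = ct.pivot_table(index=sample_col, columns=gene_col, values=ct_col)
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"no Ct values for gene {gene!r}")
        na = wide.index[wide[gene].isna()]
        if len(na):
            raise ValueError(f"missing Ct for gene {gene!r} in sample(s) {list(na)}")
    groups = ct[[sample_col, group_col]].drop_duplicates().set_index(sample_col)[group_col]
    calibrators = groups.index[groups == calibrator_group]
    if len(calibrators) == 0:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    dct = wide[target_gene] - wide[reference_gene]
    dddct = dct - dct.loc[calibrators].mean()
    return np.power(2.0, -dddct).rename("relative_expression")
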