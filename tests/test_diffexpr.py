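"""DE screening and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cernet import ExpressionMatrix, bh_adjust, de_screen


def bh_bruteforce(p):
    """Step-up from the definition: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_bh_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_trivial_cases():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([0.07] * 5), 0.07)
    assert list(bh_adjust([])) == []


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
)
def test_bh_matches_step_up_definition(pvals):
    assert np.allclose(bh_adjust(pvals), bh_bruteforce(pvals), atol=1e-12)


def test_bh_monotone_in_p():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=200)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def _expr(a_vals, b_vals, unit="FPKM"):
    """Two 3-replicate groups as one matrix."""
    df = pd.DataFrame(
        np.hstack([np.atleast_2d(a_vals), np.atleast_2d(b_vals)]),
        columns=[f"30d_r{j}" for j in range(1, 4)] + [f"60d_r{j}" for j in range(1, 4)],
    )
    df.index = [f"g{i}" for i in range(df.shape[0])]
    return ExpressionMatrix(df, "mRNA", unit)


def test_identical_groups_are_null():
    em = _expr([[5.0, 5.0, 5.0]], [[5.0, 5.0, 5.0]])
    rec = de_screen(em, "30d", "60d").iloc[0]
    assert rec.log2fc == 0.0
    assert not rec.significant
    assert rec.direction == "none"


def test_clear_shift_is_significant_with_welch_oracle():
    # log2(x+1) of 3 vs 15 (+ tiny jitter) is ~2 vs ~4 -> log2fc = 2
    a = [3.0, 3.01, 2.99]
    b = [15.0, 15.05, 14.95]
    rec = de_screen(_expr([a], [b]), "30d", "60d").iloc[0]
    assert rec.log2fc == pytest.approx(2.0, abs=0.01)
    assert rec.direction == "up"
    assert rec.significant
    t_or, p_or = stats.ttest_ind(np.log2(np.array(b) + 1), np.log2(np.array(a) + 1), equal_var=False)
    assert rec.p == pytest.approx(p_or)


def test_lfc_threshold_is_strict():
    # symmetric jitter keeps the log2 group means exactly 1 and 2: |lfc| == 1
    d = 0.01
    a = [2 ** (1 - d) - 1, 2**1 - 1, 2 ** (1 + d) - 1]
    b = [2 ** (2 - d) - 1, 2**2 - 1, 2 ** (2 + d) - 1]
    rec = de_screen(_expr([a], [b]), "30d", "60d").iloc[0]
    assert rec.log2fc == pytest.approx(1.0, abs=1e-12)
    assert rec.p < 0.05
    assert not rec.significant  # |log2fc| > 1 must be strict


def test_q_dominates_p_and_flag_recomputes(pipeline_result):
    de = pipeline_result.per_comparison["30d-90d"].de["mRNA"]
    assert (de.q >= de.p - 1e-12).all()
    flag = (de.p < 0.05) & (de.log2fc.abs() > 1.0)
    assert (flag == de.significant).all()


def test_group_errors():
    em = _expr([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
    with pytest.raises(ValueError, match="group"):
        de_screen(em, "30d", "99d")
    with pytest.raises(ValueError, match="normalized"):
        de_screen(
            ExpressionMatrix(em.values.copy(), "mRNA", "count"), "30d", "60d"
        )


def test_planted_de_sensitivity_and_direction(default_dataset):
    """Planted features at the full effect size are recovered with matching sign."""
    from cernet import fpkm_matrix, tpm_matrix

    ds = default_dataset
    mats = {
        "mRNA": fpkm_matrix(ds.mrna),
        "lncRNA": fpkm_matrix(ds.lncrna),
        "miRNA": tpm_matrix(ds.mirna),
    }
    truth = ds.truth.planted_de.query("comparison == '30d-90d'")
    found = total = 0
    for cls, mat in mats.items():
        de = de_screen(mat, "30d", "90d").set_index("feature_id")
        for row in truth[truth.feature_class == cls].itertuples():
            total += 1
            rec = de.loc[row.feature_id]
            if rec.significant:
                found += 1
                assert rec.direction == row.direction
    assert found / total >= 0.9
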