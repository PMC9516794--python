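"""Kruskal-Wallis statistic against independent oracles, plus the
similarity-matrix contract.

The primary oracle is the variance-ratio form of the statistic computed
directly on midranks, K = (N-1) * sum n_i (rbar_i - rbar)^2 /
sum (r_ij - rbar)^2, which is algebraically equivalent to the tie-corrected
rank-sum form the implementation uses; scipy.stats.kruskal is a second,
fully independent cross-check.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from degnet.io import ExpressionMatrix
from degnet.similarity import kruskal_wallis, similarity_matrix

import pandas as pd


def variance_form_oracle(groups):
    """Eq.-style definition: ANOVA on midranks, computed from scratch."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    rbar = (n + 1) / 2.0
    num = 0.0
    offset = 0
    for size in sizes:
        ri = ranks[offset : offset + size]
        num += size * (ri.mean() - rbar) ** 2
        offset += size
    den = ((ranks - rbar) ** 2).sum()
    if den == 0:
        return 0.0
    return (n - 1) * num / den


class TestKruskalWallis:
    def test_worked_two_group_example(self):
        """Ranks 1-3 vs 4-6 give H = 27/7 = 3.857 and p ~ 0.0495."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(27 / 7, abs=1e-12)
        assert round(res.statistic, 3) == 3.857
        assert res.p_value == pytest.approx(0.0495, abs=5e-4)
        assert res.df == 1

    def test_identical_groups_give_zero_statistic(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_data_gives_p_one(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_df_is_groups_minus_one(self):
        assert kruskal_wallis([[1], [2], [3]]).df == 2

    @pytest.mark.parametrize("groups", [[[1, 2], []], [[1], [2]]])
    def test_degenerate_inputs_rejected(self, groups):
        with pytest.raises(ValueError):
            kruskal_wallis(groups)

    def test_matches_variance_form_oracle_all_two_group_sizes_upto_8(self):
        """For every 2-group size split with N <= 8, H equals the
        variance-ratio oracle on random data with and without ties."""
        rng = np.random.default_rng(7)
        for n1, n2 in itertools.product(range(1, 8), repeat=2):
            if not 3 <= n1 + n2 <= 8:
                continue
            for tied in (False, True):
                if tied:
                    data = rng.integers(0, 3, size=n1 + n2).astype(float)
                else:
                    data = rng.permutation(np.arange(n1 + n2, dtype=float))
                groups = [data[:n1], data[n1:]]
                if np.all(data == data[0]):
                    continue
                ours = kruskal_wallis(groups).statistic
                assert ours == pytest.approx(variance_form_oracle(groups), abs=1e-10)

    def test_matches_scipy_on_random_multigroup_data(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            g = rng.integers(2, 5)
            groups = [rng.integers(0, 6, size=rng.integers(2, 7)) for _ in range(g)]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            ours = kruskal_wallis(groups)
            ref = stats.kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_two_group_no_ties_equals_mann_whitney_chi_square(self):
        """With g = 2 and no ties, H is the square of the large-sample
        Mann-Whitney z statistic."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            n1, n2 = rng.integers(3, 10, size=2)
            data = rng.permutation(np.arange(n1 + n2, dtype=float))
            a, b = data[:n1], data[n1:]
            u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
            n = n1 + n2
            z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n + 1) / 12.0)
            assert kruskal_wallis([a, b]).statistic == pytest.approx(z**2, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.lists(st.integers(-50, 50), min_size=2, max_size=8),
        b=st.lists(st.integers(-50, 50), min_size=2, max_size=8),
        shift=st.integers(-100, 100),
        perm_seed=st.integers(0, 2**16),
    )
    def test_rank_and_shift_invariance(self, a, b, shift, perm_seed):
        base = kruskal_wallis([a, b]).statistic
        rng = np.random.default_rng(perm_seed)
        permuted = [rng.permutation(a), rng.permutation(b)]
        assert kruskal_wallis(permuted).statistic == pytest.approx(base, abs=1e-9)
        shifted = [[x + shift for x in a], [x + shift for x in b]]
        assert kruskal_wallis(shifted).statistic == pytest.approx(base, abs=1e-9)


def _expr(values: pd.DataFrame, n_case=3, n_control=2):
    values = values.copy()
    values.columns = [f"s{i}" for i in range(n_case + n_control)]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=list(values.columns)
    )
    return ExpressionMatrix(values=values, groups=groups)


class TestSimilarityMatrix:
    def test_identical_rows_have_similarity_one(self):
        expr = _expr(pd.DataFrame([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]],
                                  index=["A", "B"]))
        sm = similarity_matrix(expr, ["A", "B"], sample_scope="all")
        assert sm.values[0, 1] == 1.0

    def test_below_threshold_cells_are_zeroed(self):
        rows = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6, 7, 8], [101, 102, 103, 104, 105, 106, 107, 108]],
            index=["A", "B"],
        )
        expr = _expr(rows, n_case=8, n_control=0)
        # disjoint value ranges -> tiny KW p -> zeroed cell
        p = kruskal_wallis([rows.loc["A"], rows.loc["B"]]).p_value
        assert p < 0.005
        sm = similarity_matrix(expr, ["A", "B"], sample_scope="cases")
        assert sm.values[0, 1] == 0.0

    def test_cells_are_zero_or_at_least_threshold(self, default_inputs):
        expr = default_inputs["expr"]
        genes = expr.genes[:12]
        sm = similarity_matrix(expr, genes)
        off = sm.values[~np.eye(len(genes), dtype=bool)]
        assert np.all((off == 0) | (off >= sm.threshold))
        assert np.all(np.diag(sm.values) == 0)
        assert np.allclose(sm.values, sm.values.T)

    def test_gene_order_invariance(self, default_inputs):
        expr = default_inputs["expr"]
        genes = expr.genes[:8]
        sm1 = similarity_matrix(expr, genes)
        sm2 = similarity_matrix(expr, genes[::-1])
        lookup = {g: i for i, g in enumerate(sm2.genes)}
        for i, gi in enumerate(sm1.genes):
            for j, gj in enumerate(sm1.genes):
                assert sm1.values[i, j] == sm2.values[lookup[gi], lookup[gj]]

    def test_missing_genes_reported_and_too_few_rejected(self, default_inputs):
        expr = default_inputs["expr"]
        sm = similarity_matrix(expr, [expr.genes[0], expr.genes[1], "NOSUCH"])
        assert sm.missing == ("NOSUCH",)
        with pytest.raises(ValueError, match="at least 2"):
            similarity_matrix(expr, [expr.genes[0], "NOSUCH"])
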