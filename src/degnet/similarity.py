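"""Kruskal-Wallis rank test and thresholded gene-gene similarity matrices.

The Kruskal-Wallis H statistic tests whether k independent samples come
from populations with the same location.  Here it is run pairwise on the
per-sample expression vectors of two genes (g = 2 groups), and its p value
is repurposed as a similarity score: a high p means the two genes' values
are statistically indistinguishable, i.e. the genes behave alike.  Cells
below the similarity threshold (default 0.005) are zeroed, so nonzero cells
are exactly the edges of the similarity network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix

__all__ = ["KWResult", "SimilarityMatrix", "kruskal_wallis", "similarity_matrix"]


@dataclass(frozen=True)
class KWResult:
    """Outcome of one Kruskal-Wallis test."""

    statistic: float
    df: int
    p_value: float
    n_total: int
    group_sizes: tuple

    def __post_init__(self) -> None:
        if self.statistic < -1e-12:
            raise ValueError("H must be nonnegative")


def kruskal_wallis(groups) -> KWResult:
    """Kruskal-Wallis H test on two or more samples.

    H is computed on midranks with the standard tie correction
    (H divided by 1 - sum(t^3 - t)/(N^3 - N) over tie groups of size t);
    the p value comes from the chi-square survival function with
    g - 1 degrees of freedom.  All observations identical gives H = 0,
    p = 1.

    Raises
    ------
    ValueError
        If fewer than two groups, any group is empty, or N < 3.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    sizes = tuple(len(a) for a in arrays)
    if any(s == 0 for s in sizes):
        raise ValueError("every group must be non-empty")
    n_total = int(sum(sizes))
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    g = len(arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, g - 1, 1.0, n_total, sizes)
    ranks = stats.rankdata(pooled)
    # rank-sum form: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)
    h = 0.0
    offset = 0
    for size in sizes:
        r_i = ranks[offset : offset + size].sum()
        h += r_i * r_i / size
        offset += size
    n = n_total
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction <= 0:
        return KWResult(0.0, g - 1, 1.0, n_total, sizes)
    h = max(h / correction, 0.0)
    p = float(min(stats.chi2.sf(h, g - 1), 1.0))
    return KWResult(float(h), g - 1, p, n_total, sizes)


@dataclass
class SimilarityMatrix:
    """Symmetric thresholded matrix of pairwise Kruskal-Wallis p values.

    ``values[i, j]`` is the KW p value for genes i and j when it is at
    least ``threshold``, else 0; the diagonal is fixed at 0 (no self
    edges).  ``missing`` lists requested genes absent from the expression
    matrix.
    """

    genes: tuple
    values: np.ndarray
    threshold: float
    missing: tuple = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.genes), len(self.genes)):
            raise ValueError("matrix shape does not match gene list")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")


def similarity_matrix(
    expr: ExpressionMatrix,
    genes,
    sample_scope: str = "cases",
    threshold: float = 0.005,
) -> SimilarityMatrix:
    """Pairwise KW similarity among ``genes`` over a sample scope.

    ``sample_scope`` selects which samples' values form the two compared
    populations: ``cases`` (default), ``controls`` or ``all``.  Genes not
    present in the expression matrix are dropped and reported on the
    result; fewer than two remaining genes is an error.
    """
    present = [g for g in genes if g in expr.values.index]
    missing = tuple(g for g in genes if g not in expr.values.index)
    if len(present) < 2:
        raise ValueError(
            f"need at least 2 genes with expression data, got {len(present)}"
        )
    samples = expr.samples_in(sample_scope)
    if len(samples) < 2:
        raise ValueError(f"sample scope {sample_scope!r} has fewer than 2 samples")
    data = expr.values.loc[present, samples].to_numpy(dtype=float)
    n = len(present)
    cells = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            p = kruskal_wallis([data[i], data[j]]).p_value
            if p >= threshold:
                cells[i, j] = cells[j, i] = p
    return SimilarityMatrix(
        genes=tuple(present), values=cells, threshold=threshold, missing=missing
    )
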