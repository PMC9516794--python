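"""Hypergeometric over-representation analysis with FDR and Bonferroni.

Given a gene list of size n drawn from a universe of N annotated genes, a
pathway with K members and overlap k with the list is scored with the
upper-tail hypergeometric probability P[X >= k].  Raw p values are
corrected per tested pathway by Benjamini-Hochberg (FDR) and Bonferroni,
and rows are ranked by ascending raw p, ties by descending overlap then
pathway id.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PathwayDB

__all__ = ["hypergeom_pvalue", "enrich"]

ENRICHMENT_COLUMNS = [
    "pathway_id",
    "pathway_name",
    "overlap_k",
    "pathway_size_K",
    "list_size_n",
    "universe_N",
    "p_value",
    "fdr",
    "bonferroni",
]


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the pathway size, n the query-list size and
    k the observed overlap.  k = 0 returns 1 (the whole support).
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}")
    if n > N or K > N:
        raise ValueError(f"n={n} and K={K} must not exceed N={N}")
    if k == 0:
        return 1.0
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def enrich(
    genes,
    db: PathwayDB,
    background=None,
    min_pathway_size: int = 1,
    max_pathway_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` against ``db``.

    The universe defaults to all genes annotated to at least one pathway;
    an optional ``background`` (e.g. all genes on the array) is
    intersected with that universe first.  Pathways with no member in the
    universe are not tested, so they do not enter the correction.

    Returns a ranked DataFrame with one row per tested pathway; raises
    ``ValueError`` when the query has no gene in the universe.
    """
    genes = {str(g).strip().upper() for g in genes}
    universe = set(db.universe)
    if background is not None:
        universe &= {str(g).strip().upper() for g in background}
        if not universe:
            raise ValueError("background does not intersect the pathway universe")
    query = genes & universe
    if not query:
        raise ValueError(
            "no query gene lies in the pathway universe "
            f"({len(genes)} genes given, universe size {len(universe)})"
        )
    n = len(query)
    N = len(universe)
    rows = []
    for pid in sorted(db.pathways):
        name, members = db.pathways[pid]
        restricted = members & universe
        K = len(restricted)
        if K < max(min_pathway_size, 1):
            continue
        if max_pathway_size is not None and K > max_pathway_size:
            continue
        k = len(query & restricted)
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": name,
                "overlap_k": k,
                "pathway_size_K": K,
                "list_size_n": n,
                "universe_N": N,
                "p_value": hypergeom_pvalue(k, n, K, N),
            }
        )
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-2])
    m = len(table)
    if m:
        table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["bonferroni"] = (table["p_value"] * m).clip(upper=1.0)
    else:
        table["fdr"] = []
        table["bonferroni"] = []
    table = table.sort_values(
        ["p_value", "overlap_k", "pathway_id"],
        ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return table
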