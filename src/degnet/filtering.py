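"""DEG selection: threshold filtering, deduplication and up/down partition.

A gene qualifies as differentially expressed when its (adjusted) p value is
at most ``p_threshold`` and |log2 fold change| is at least ``lfc_threshold``
(defaults 0.005 and 1.5, both boundaries inclusive).  Genes with negative
logFC are down-regulated, the rest up-regulated; after deduplication the two
sets are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["GeneSetPartition", "filter_degs", "deduplicate", "partition_by_regulation"]


@dataclass(frozen=True)
class GeneSetPartition:
    """Disjoint ordered up- and down-regulated gene symbol lists."""

    up: tuple
    down: tuple

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up- and down-regulated sets overlap")

    @property
    def all_genes(self) -> tuple:
        return self.up + self.down


def filter_degs(
    table: pd.DataFrame,
    p_threshold: float = 0.005,
    lfc_threshold: float = 1.5,
    use_adjusted_p: bool = True,
) -> pd.DataFrame:
    """Keep rows with chosen p <= p_threshold and |logFC| >= lfc_threshold."""
    if p_threshold <= 0 or lfc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    pcol = "adj_p_value" if use_adjusted_p else "p_value"
    mask = (table[pcol] <= p_threshold) & (table["log_fc"].abs() >= lfc_threshold)
    return table.loc[mask].reset_index(drop=True)


def deduplicate(
    table: pd.DataFrame,
    policy: str = "min_p",
    use_adjusted_p: bool = True,
) -> pd.DataFrame:
    """Retain one record per gene symbol.

    ``min_p``: keep the record with the smallest chosen p, ties broken by
    larger |logFC|, then lexicographically smallest probe_id.
    ``max_abs_lfc``: keep the largest |logFC|, ties by smaller chosen p,
    then probe_id.
    """
    if policy not in {"min_p", "max_abs_lfc"}:
        raise ValueError(f"unknown deduplication policy {policy!r}")
    if table.empty:
        return table.reset_index(drop=True)
    pcol = "adj_p_value" if use_adjusted_p else "p_value"
    work = table.assign(_abs_lfc=table["log_fc"].abs())
    if policy == "min_p":
        keys = [pcol, "_abs_lfc", "probe_id"]
        ascending = [True, False, True]
    else:
        keys = ["_abs_lfc", pcol, "probe_id"]
        ascending = [False, True, True]
    work = work.sort_values(keys, ascending=ascending, kind="stable")
    work = work[~work["gene_symbol"].duplicated(keep="first")]
    # restore the original row order of the survivors
    work = work.sort_index().drop(columns="_abs_lfc")
    return work.reset_index(drop=True)


def partition_by_regulation(table: pd.DataFrame) -> GeneSetPartition:
    """Split a deduplicated DEG table into up (logFC >= 0) and down (< 0)."""
    if table["gene_symbol"].duplicated().any():
        dups = sorted(table.loc[table["gene_symbol"].duplicated(), "gene_symbol"])
        raise ValueError(f"table contains duplicate symbols (deduplicate first): {dups}")
    down = tuple(table.loc[table["log_fc"] < 0, "gene_symbol"])
    up = tuple(table.loc[table["log_fc"] >= 0, "gene_symbol"])
    return GeneSetPartition(up=up, down=down)
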