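"""Readers and writers for the external formats the pipeline touches.

Four inputs: a GEO2R-style differential-expression table, a log2 expression
matrix with case/control sample annotation, a tab-delimited PPI edge list
(IID-style), and pathway gene sets in GMT format.  One output: a ranked
enrichment table as TSV.

All gene identifiers are uppercase-trimmed symbols; every cross-file join in
the pipeline happens on that normalized key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "LoadReport",
    "ExpressionMatrix",
    "PathwayDB",
    "DEG_COLUMNS",
    "normalize_symbol",
    "read_deg_table",
    "write_deg_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ppi_edgelist",
    "write_edgelist",
    "read_gmt",
    "write_gmt",
    "write_enrichment",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to its expected format."""


#: canonical column name -> default header in a GEO2R export
DEG_COLUMNS = {
    "probe_id": "ID",
    "gene_symbol": "Gene.symbol",
    "p_value": "P.Value",
    "adj_p_value": "adj.P.Val",
    "log_fc": "logFC",
}


def normalize_symbol(symbol: object) -> str:
    """Uppercase-trim a gene symbol; empty string for missing values."""
    if symbol is None or (isinstance(symbol, float) and math.isnan(symbol)):
        return ""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping for rows dropped while parsing a DEG table."""

    n_input: int
    n_kept: int
    dropped: int
    reasons: dict = field(default_factory=dict)


def read_deg_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a GEO2R-style DEG export into the canonical DEG table.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional overrides mapping canonical names (``gene_symbol``,
        ``p_value``, ``adj_p_value``, ``log_fc``, ``probe_id``) to the
        actual headers in the file.

    Returns
    -------
    pandas.DataFrame
        Columns ``probe_id, gene_symbol, p_value, adj_p_value, log_fc``.
        Rows with a missing symbol or unparseable/out-of-range numerics are
        dropped and counted in ``df.attrs["load_report"]``.
    """
    colmap = dict(DEG_COLUMNS)
    if column_map:
        colmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty DEG table: {path}") from exc
    if raw.empty and raw.columns.empty:
        raise FormatError(f"empty DEG table: {path}")
    for canonical in ("gene_symbol", "p_value", "adj_p_value", "log_fc"):
        if colmap[canonical] not in raw.columns:
            raise FormatError(
                f"DEG table {path} lacks required column "
                f"{colmap[canonical]!r} ({canonical})"
            )
    n_input = len(raw)
    if colmap["probe_id"] in raw.columns:
        probe = raw[colmap["probe_id"]].astype(str)
    else:
        probe = pd.Series([str(i) for i in range(n_input)], index=raw.index)
    df = pd.DataFrame(
        {
            "probe_id": probe,
            "gene_symbol": raw[colmap["gene_symbol"]].map(normalize_symbol),
            "p_value": pd.to_numeric(raw[colmap["p_value"]], errors="coerce"),
            "adj_p_value": pd.to_numeric(raw[colmap["adj_p_value"]], errors="coerce"),
            "log_fc": pd.to_numeric(raw[colmap["log_fc"]], errors="coerce"),
        }
    )
    bad_symbol = df["gene_symbol"] == ""
    bad_p = ~df["p_value"].between(0, 1, inclusive="right")
    bad_adj = ~df["adj_p_value"].between(0, 1, inclusive="right")
    bad_lfc = ~np.isfinite(df["log_fc"].to_numpy(dtype=float, na_value=np.nan))
    drop = bad_symbol | bad_p | bad_adj | bad_lfc
    kept = df.loc[~drop].reset_index(drop=True)
    kept.attrs["load_report"] = LoadReport(
        n_input=n_input,
        n_kept=len(kept),
        dropped=int(drop.sum()),
        reasons={
            "missing_symbol": int(bad_symbol.sum()),
            "bad_p_value": int((bad_p & ~bad_symbol).sum()),
            "bad_adj_p_value": int((bad_adj & ~bad_symbol & ~bad_p).sum()),
            "bad_log_fc": int((bad_lfc & ~bad_symbol & ~bad_p & ~bad_adj).sum()),
        },
    )
    return kept


def write_deg_table(df: pd.DataFrame, path) -> None:
    """Write a canonical DEG table back out with GEO2R-style headers."""
    out = pd.DataFrame(
        {
            "ID": df["probe_id"],
            "adj.P.Val": df["adj_p_value"],
            "P.Value": df["p_value"],
            "logFC": df["log_fc"],
            "Gene.symbol": df["gene_symbol"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """A genes x samples log2 expression matrix with case/control labels.

    ``values`` is indexed by normalized gene symbol (unique); ``groups``
    maps every sample id (the matrix columns) to ``"case"`` or
    ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"group labels must be case/control, got {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, scope: str) -> list[str]:
        """Sample ids for a scope in {cases, controls, all}."""
        if scope == "all":
            return self.samples
        label = {"cases": "case", "controls": "control"}.get(scope)
        if label is None:
            raise ValueError(f"unknown sample scope {scope!r}")
        return [s for s in self.samples if self.groups[s] == label]


def read_expression_matrix(path, groups_path) -> ExpressionMatrix:
    """Read an expression TSV (header = sample ids, first column = gene)
    plus a two-column sample-to-group TSV.

    Duplicate gene rows are collapsed to the row with maximal variance
    across samples (the most informative probe).  Every sample in the
    matrix must appear in the groups file.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = [normalize_symbol(g) for g in values.index]
    groups_df = pd.read_csv(groups_path, sep="\t")
    if groups_df.shape[1] < 2:
        raise FormatError(f"groups file {groups_path} needs two columns")
    groups = pd.Series(
        groups_df.iloc[:, 1].astype(str).str.strip().str.lower().values,
        index=groups_df.iloc[:, 0].astype(str).values,
    )
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise FormatError(f"samples missing from groups file: {missing}")
    n_dup = 0
    if pd.Index(values.index).has_duplicates:
        variances = values.var(axis=1)
        order = np.argsort(-variances.to_numpy(), kind="stable")
        dedup = values.iloc[order]
        dedup = dedup[~dedup.index.duplicated(keep="first")]
        n_dup = len(values) - len(dedup)
        values = dedup.loc[[g for g in dict.fromkeys(values.index)]]
    em = ExpressionMatrix(values=values, groups=groups.loc[list(values.columns)])
    em.values.attrs["n_duplicates_collapsed"] = n_dup
    return em


def write_expression_matrix(em: ExpressionMatrix, path, groups_path) -> None:
    em.values.to_csv(path, sep="\t", index_label="Gene.symbol")
    pd.DataFrame({"sample": em.samples, "group": [em.groups[s] for s in em.samples]}).to_csv(
        groups_path, sep="\t", index=False
    )


def read_ppi_edgelist(path, min_confidence: float | None = None) -> nx.Graph:
    """Read a tab-delimited protein-protein interaction edge list.

    Each data line holds two gene symbols and, optionally, a numeric
    confidence in the third column.  Self-loops and duplicate (reversed)
    pairs are removed; with ``min_confidence`` set, weighted edges below it
    are dropped.  Lines starting with ``#`` are skipped.
    """
    graph = nx.Graph()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"{path}: malformed edge at line {lineno}")
            a, b = normalize_symbol(fields[0]), normalize_symbol(fields[1])
            if a == b:
                continue
            weight = None
            if len(fields) >= 3 and fields[2].strip():
                try:
                    weight = float(fields[2])
                except ValueError:
                    weight = None
            if min_confidence is not None and weight is not None and weight < min_confidence:
                continue
            if weight is None:
                graph.add_edge(a, b)
            else:
                graph.add_edge(a, b, weight=weight)
    return graph


def write_edgelist(graph: nx.Graph, path) -> None:
    """Write a network as a tab-delimited edge list (canonical sorted pairs)."""
    with open(path, "w", encoding="utf-8") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            data = graph.get_edge_data(a, b) or {}
            if "weight" in data:
                handle.write(f"{a}\t{b}\t{data['weight']:.6g}\n")
            else:
                handle.write(f"{a}\t{b}\n")


@dataclass
class PathwayDB:
    """Pathway gene sets keyed by pathway id.

    ``pathways`` maps id -> (display name, frozenset of member symbols);
    the universe is the union of all member sets.
    """

    pathways: dict

    def __post_init__(self) -> None:
        for pid, (name, members) in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid} has no members")
            self.pathways[pid] = (name, frozenset(members))

    @property
    def universe(self) -> frozenset:
        out: set[str] = set()
        for _, members in self.pathways.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)


def read_gmt(path) -> PathwayDB:
    """Read a Broad-dialect GMT file: name TAB description TAB gene...

    Gene symbols are uppercase-normalized; a line with fewer than three
    fields (i.e. no members) is a format error.
    """
    pathways: dict = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            pid = fields[0].strip()
            name = fields[1].strip() or pid
            members = {normalize_symbol(g) for g in fields[2:] if g.strip()}
            if not members:
                raise FormatError(f"{path}: GMT line {lineno} has no member genes")
            pathways[pid] = (name, frozenset(members))
    return PathwayDB(pathways=pathways)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for pid in sorted(db.pathways):
            name, members = db.pathways[pid]
            handle.write("\t".join([pid, name, *sorted(members)]) + "\n")


def _abs_log2(p: float) -> float:
    if p <= 0:
        return float("inf")
    return abs(math.log2(p))


def write_enrichment(table: pd.DataFrame, path) -> None:
    """Write a ranked enrichment table as TSV.

    Adds the presentation columns ``abs_log2_p``, ``abs_log2_fdr`` and
    ``abs_log2_bonf`` (|log2| of the corresponding p value) at write time;
    internal tables keep full precision.
    """
    cols = [
        "pathway_id",
        "pathway_name",
        "p_value",
        "fdr",
        "bonferroni",
        "overlap_k",
        "pathway_size_K",
        "list_size_n",
        "universe_N",
    ]
    out = table[cols].copy() if len(table) else pd.DataFrame(columns=cols)
    out["abs_log2_p"] = [_abs_log2(p) for p in out["p_value"]]
    out["abs_log2_fdr"] = [_abs_log2(p) for p in out["fdr"]]
    out["abs_log2_bonf"] = [_abs_log2(p) for p in out["bonferroni"]]
    out.to_csv(path, sep="\t", index=False)


def read_enrichment(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
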