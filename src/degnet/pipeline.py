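"""End-to-end orchestration of the DEG pre-processing method.

The pipeline runs the up- and down-regulated branches independently:

    filter -> deduplicate -> partition
    per branch: KW similarity matrix -> network -> closeness ->
                essential genes -> PPI mapping -> radius-1 community ->
                Bottleneck-relevant genes -> hypergeometric enrichment

and optionally a combined enrichment over the union of both branches'
relevant genes, for the grouped-vs-ungrouped contrast.  Everything after
input parsing is deterministic, so the same inputs and configuration
produce byte-identical reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import io as dio
from .enrichment import enrich
from .filtering import deduplicate, filter_degs, partition_by_regulation
from .network import closeness_centrality, select_essential, to_network
from .ppi import map_to_ppi, neighborhood, select_relevant
from .similarity import similarity_matrix

__all__ = [
    "PipelineParams",
    "PipelineConfig",
    "BranchResult",
    "PipelineResult",
    "run",
    "run_pipeline",
    "compare_enrichments",
]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds and flags for one pipeline run."""

    p_threshold: float = 0.005
    lfc_threshold: float = 1.5
    use_adjusted_p: bool = True
    dedup_policy: str = "min_p"
    similarity_threshold: float = 0.005
    sample_scope: str = "cases"
    invert_cc_rule: bool = False
    radius: int = 1
    min_pathway_size: int = 1
    max_pathway_size: int | None = None
    run_combined: bool = True


@dataclass
class BranchResult:
    """All intermediate artifacts of one regulation branch."""

    regulation: str
    genes: tuple = ()
    similarity: object = None
    network: object = None
    essential: frozenset = frozenset()
    mapped: frozenset = frozenset()
    unmapped: frozenset = frozenset()
    community_members: frozenset = frozenset()
    relevant: frozenset = frozenset()
    bottleneck_fallback: bool = False
    enrichment: pd.DataFrame | None = None
    empty_reason: str | None = None

    def counts(self) -> dict:
        return {
            "input_genes": len(self.genes),
            "essential": len(self.essential),
            "mapped": len(self.mapped),
            "unmapped": len(self.unmapped),
            "community": len(self.community_members),
            "relevant": len(self.relevant),
            "enriched_pathways": 0 if self.enrichment is None else len(self.enrichment),
        }


@dataclass
class PipelineResult:
    """Filtered table, partition, per-branch artifacts and the report."""

    filtered: pd.DataFrame
    partition: object
    up: BranchResult
    down: BranchResult
    combined_enrichment: pd.DataFrame | None
    report: dict


def _run_branch(
    regulation: str,
    genes,
    expr: dio.ExpressionMatrix,
    ppi: nx.Graph,
    pathways: dio.PathwayDB,
    params: PipelineParams,
    background=None,
) -> BranchResult:
    result = BranchResult(regulation=regulation, genes=tuple(genes))
    present = [g for g in genes if g in expr.values.index]
    if len(present) < 2:
        result.empty_reason = f"fewer than 2 {regulation} genes with expression data"
        return result
    sm = similarity_matrix(
        expr, present, sample_scope=params.sample_scope,
        threshold=params.similarity_threshold,
    )
    net = to_network(sm)
    scores = closeness_centrality(net)
    essential = select_essential(net, scores, regulation, params.invert_cc_rule)
    result.similarity = sm
    result.network = net
    result.essential = essential.genes
    mapped, unmapped = map_to_ppi(essential.genes, ppi)
    result.mapped, result.unmapped = mapped, unmapped
    if not mapped:
        result.empty_reason = "no essential gene mapped onto the PPI network"
        return result
    community = neighborhood(ppi, mapped, radius=params.radius, regulation=regulation)
    result.community_members = community.members
    relevant = select_relevant(community)
    result.relevant = relevant.genes
    result.bottleneck_fallback = relevant.used_fallback
    try:
        result.enrichment = enrich(
            relevant.genes,
            pathways,
            background=background,
            min_pathway_size=params.min_pathway_size,
            max_pathway_size=params.max_pathway_size,
        )
    except ValueError as exc:
        result.empty_reason = f"enrichment skipped: {exc}"
    return result


def run(
    deg_table: pd.DataFrame,
    expr: dio.ExpressionMatrix,
    ppi: nx.Graph,
    pathways: dio.PathwayDB,
    params: PipelineParams = PipelineParams(),
    background=None,
) -> PipelineResult:
    """Run the full method on in-memory inputs.

    Branches with too few genes are recorded as empty instead of failing,
    so one degenerate branch never blocks the other.
    """
    filtered = filter_degs(
        deg_table,
        p_threshold=params.p_threshold,
        lfc_threshold=params.lfc_threshold,
        use_adjusted_p=params.use_adjusted_p,
    )
    dedup = deduplicate(filtered, policy=params.dedup_policy,
                        use_adjusted_p=params.use_adjusted_p)
    partition = partition_by_regulation(dedup)
    up = _run_branch("up", partition.up, expr, ppi, pathways, params, background)
    down = _run_branch("down", partition.down, expr, ppi, pathways, params, background)
    combined = None
    if params.run_combined:
        union = up.relevant | down.relevant
        if union:
            try:
                combined = enrich(
                    union, pathways, background=background,
                    min_pathway_size=params.min_pathway_size,
                    max_pathway_size=params.max_pathway_size,
                )
            except ValueError:
                combined = None
    report = {
        "counts": {
            "input_records": int(len(deg_table)),
            "filtered": int(len(filtered)),
            "deduplicated": int(len(dedup)),
            "up": len(partition.up),
            "down": len(partition.down),
        },
        "branches": {
            "up": up.counts(),
            "down": down.counts(),
        },
        "branch_notes": {
            "up": up.empty_reason,
            "down": down.empty_reason,
        },
        "top_pathways": {
            "up": _top_ids(up.enrichment),
            "down": _top_ids(down.enrichment),
            "combined": _top_ids(combined),
        },
    }
    return PipelineResult(
        filtered=dedup, partition=partition, up=up, down=down,
        combined_enrichment=combined, report=report,
    )


def _top_ids(table: pd.DataFrame | None, n: int = 10) -> list:
    if table is None or table.empty:
        return []
    return list(table["pathway_id"].head(n))


@dataclass
class PipelineConfig:
    """File-level configuration; see :class:`PipelineParams` for knobs."""

    deg_table: str
    expression: str
    groups: str
    ppi: str
    gmt: str
    output_dir: str
    params: PipelineParams = field(default_factory=PipelineParams)
    background_path: str | None = None
    deg_column_map: dict | None = None
    min_ppi_confidence: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate(self) -> None:
        for name in ("deg_table", "expression", "groups", "ppi", "gmt"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Read inputs per ``config``, run the method, write all artifacts.

    Writes per-branch networks, community member lists, enrichment TSVs
    and a ``report.json`` (sorted keys) into the output directory, and
    returns the report dict.  Reruns with identical inputs produce
    byte-identical reports.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    deg = dio.read_deg_table(config.deg_table, column_map=config.deg_column_map)
    expr = dio.read_expression_matrix(config.expression, config.groups)
    ppi = dio.read_ppi_edgelist(config.ppi, min_confidence=config.min_ppi_confidence)
    pathways = dio.read_gmt(config.gmt)
    background = None
    if config.background_path:
        with open(config.background_path, encoding="utf-8") as handle:
            background = {line.strip().upper() for line in handle if line.strip()}
    result = run(deg, expr, ppi, pathways, config.params, background)
    dio.write_deg_table(result.filtered, outdir / "filtered_degs.tsv")
    for branch in (result.up, result.down):
        tag = branch.regulation
        if branch.network is not None:
            dio.write_edgelist(branch.network, outdir / f"similarity_network_{tag}.tsv")
        _write_members(branch, outdir / f"community_{tag}.tsv")
        if branch.enrichment is not None:
            dio.write_enrichment(branch.enrichment, outdir / f"enrichment_{tag}.tsv")
    if result.combined_enrichment is not None:
        dio.write_enrichment(result.combined_enrichment, outdir / "enrichment_combined.tsv")
    with open(outdir / "report.json", "w", encoding="utf-8") as handle:
        json.dump(result.report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return result.report


def _write_members(branch: BranchResult, path) -> None:
    rows = []
    for gene in sorted(branch.community_members):
        rows.append(
            {
                "gene": gene,
                "seed": gene in branch.mapped,
                "selected": gene in branch.relevant,
            }
        )
    pd.DataFrame(rows, columns=["gene", "seed", "selected"]).to_csv(
        path, sep="\t", index=False
    )


def compare_enrichments(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Compare two ranked enrichment tables.

    Reports the shared pathway set, the absolute rank displacement of
    every shared pathway (1-based positions), the mean displacement, and
    per-pathway |log2 p| deltas.  Both tables must be non-empty.
    """
    if table_a is None or table_b is None or table_a.empty or table_b.empty:
        raise ValueError("both enrichment tables must be non-empty")
    rank_a = {pid: i + 1 for i, pid in enumerate(table_a["pathway_id"])}
    rank_b = {pid: i + 1 for i, pid in enumerate(table_b["pathway_id"])}
    pa = dict(zip(table_a["pathway_id"], table_a["p_value"]))
    pb = dict(zip(table_b["pathway_id"], table_b["p_value"]))
    shared = sorted(set(rank_a) & set(rank_b))
    displacement = {pid: abs(rank_a[pid] - rank_b[pid]) for pid in shared}

    def _lg(p):
        return abs(math.log2(p)) if p > 0 else float("inf")

    deltas = {pid: _lg(pa[pid]) - _lg(pb[pid]) for pid in shared}
    return {
        "overlap": len(shared),
        "only_a": len(set(rank_a) - set(rank_b)),
        "only_b": len(set(rank_b) - set(rank_a)),
        "displacement": displacement,
        "mean_displacement": (
            sum(displacement.values()) / len(shared) if shared else 0.0
        ),
        "abs_log2_p_delta": deltas,
    }
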