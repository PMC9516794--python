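"""Deterministic synthetic inputs with planted structure.

The generator emulates the four pipeline inputs at once: a log2 expression
matrix with one planted up-regulated and one planted down-regulated
co-expression module, a differential-expression table computed from that
matrix, a scale-free PPI graph containing the planted genes, and a GMT
pathway collection with one planted pathway holding the module genes.

Every generator is a pure function of its seed and parameters, so fixtures
never need to be stored: tests and the acceptance script rebuild them on
the fly.  Default sizes (300 genes, 25+25 module genes, 10 cases + 10
controls, effect size 3.0 log2 units, noise sd 0.2, 50 pathways) define
the reference study conditions used by the recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import (
    ExpressionMatrix,
    PathwayDB,
    write_deg_table,
    write_edgelist,
    write_expression_matrix,
    write_gmt,
)

__all__ = [
    "PlantedTruth",
    "gene_symbols",
    "make_truth",
    "simulate_expression",
    "simulate_deg_table",
    "simulate_ppi",
    "simulate_pathways",
    "simulate_inputs",
]

PLANTED_PATHWAY_ID = "PW_PLANTED"


def gene_symbols(n: int) -> list[str]:
    """Deterministic synthetic gene symbols G0001..Gnnnn."""
    return [f"G{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth shared by all four generators."""

    up_module: tuple
    down_module: tuple
    planted_pathway_id: str = PLANTED_PATHWAY_ID
    seed: int = 0
    effect_size: float = 3.0
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if set(self.up_module) & set(self.down_module):
            raise ValueError("planted modules must be disjoint")

    @property
    def module_genes(self) -> frozenset:
        return frozenset(self.up_module) | frozenset(self.down_module)


def make_truth(
    n_genes: int = 300,
    module_size: int = 25,
    seed: int = 0,
    effect_size: float = 3.0,
    noise_sd: float = 0.2,
) -> PlantedTruth:
    """Plant the first ``module_size`` genes up and the next block down."""
    if 2 * module_size > n_genes:
        raise ValueError("modules larger than the gene universe")
    genes = gene_symbols(n_genes)
    return PlantedTruth(
        up_module=tuple(genes[:module_size]),
        down_module=tuple(genes[module_size : 2 * module_size]),
        seed=seed,
        effect_size=effect_size,
        noise_sd=noise_sd,
    )


def simulate_expression(
    n_genes: int,
    n_case: int,
    n_control: int,
    truth: PlantedTruth,
    baseline: float = 8.0,
    latent_sd: float = 0.3,
) -> ExpressionMatrix:
    """Log2 expression with planted differential co-expression modules.

    Background genes are i.i.d. Normal(baseline, noise_sd) in every sample.
    Each module shares one per-sample latent factor (sd ``latent_sd``) so
    that module members co-vary; module genes additionally gain
    +effect_size (up module) or -effect_size (down module) in case
    samples.  Deterministic under ``truth.seed``.
    """
    genes = gene_symbols(n_genes)
    if not truth.module_genes <= set(genes):
        raise ValueError("planted module genes exceed the gene universe")
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(truth.seed)
    samples = [f"CASE{i:02d}" for i in range(1, n_case + 1)] + [
        f"CTRL{i:02d}" for i in range(1, n_control + 1)
    ]
    is_case = np.array([1.0] * n_case + [0.0] * n_control)
    values = baseline + rng.normal(0.0, truth.noise_sd, size=(n_genes, len(samples)))
    for module, sign in ((truth.up_module, 1.0), (truth.down_module, -1.0)):
        latent = rng.normal(0.0, latent_sd, size=len(samples))
        for gene in module:
            row = genes.index(gene)
            values[row] = (
                baseline
                + latent
                + sign * truth.effect_size * is_case
                + rng.normal(0.0, truth.noise_sd, size=len(samples))
            )
    frame = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples
    )
    return ExpressionMatrix(values=frame, groups=groups)


def simulate_deg_table(expr: ExpressionMatrix, truth: PlantedTruth) -> pd.DataFrame:
    """GEO2R-style DEG table computed from a simulated matrix.

    Per gene: two-sample t test case vs control, Benjamini-Hochberg
    adjusted p, and logFC = mean(case) - mean(control).  The canonical
    columns of :func:`degnet.io.read_deg_table` are returned; write with
    :func:`degnet.io.write_deg_table` for the GEO2R header layout.
    """
    cases = expr.values[expr.samples_in("cases")].to_numpy(dtype=float)
    controls = expr.values[expr.samples_in("controls")].to_numpy(dtype=float)
    tstat, p = stats.ttest_ind(cases, controls, axis=1)
    p = np.nan_to_num(p, nan=1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    lfc = cases.mean(axis=1) - controls.mean(axis=1)
    return pd.DataFrame(
        {
            "probe_id": expr.genes,
            "gene_symbol": expr.genes,
            "p_value": np.clip(p, np.nextafter(0, 1), 1.0),
            "adj_p_value": np.clip(adj, np.nextafter(0, 1), 1.0),
            "log_fc": lfc,
        }
    )


def simulate_ppi(
    n_nodes: int,
    attach_m: int,
    truth: PlantedTruth,
    seed: int | None = None,
) -> nx.Graph:
    """Scale-free PPI over the synthetic gene symbols.

    A Barabasi-Albert preferential-attachment graph supplies the hub
    structure; each planted module is then wired into a connected chain
    and its first gene attached to the highest-degree hub outside the
    modules, so the modules sit inside the network's dense core the way
    disease modules do in curated PPIs.
    """
    if not 1 <= attach_m < n_nodes:
        raise ValueError("need n_nodes > attach_m >= 1")
    if seed is None:
        seed = truth.seed
    genes = gene_symbols(n_nodes)
    if not truth.module_genes <= set(genes):
        raise ValueError("planted module genes exceed the PPI node set")
    base = nx.barabasi_albert_graph(n_nodes, attach_m, seed=seed)
    graph = nx.relabel_nodes(base, dict(enumerate(genes)))
    hub = max(
        (g for g in graph.nodes() if g not in truth.module_genes),
        key=lambda g: (graph.degree(g), g),
    )
    for module in (truth.up_module, truth.down_module):
        for a, b in zip(module, module[1:]):
            graph.add_edge(a, b)
        if module:
            graph.add_edge(module[0], hub)
    return graph


def simulate_pathways(
    n_pathways: int,
    size_range: tuple = (10, 40),
    truth: PlantedTruth | None = None,
    seed: int | None = None,
    n_genes: int = 300,
    n_decoy_members: int = 5,
) -> PathwayDB:
    """Pathway collection with one planted pathway covering the modules.

    The planted pathway holds every module gene plus ``n_decoy_members``
    random non-module genes; the remaining pathways are uniform draws
    from the non-module genes with sizes in ``size_range``.
    """
    if n_pathways < 2:
        raise ValueError("need at least 2 pathways")
    if truth is None:
        raise ValueError("truth is required")
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    genes = gene_symbols(n_genes)
    pool = [g for g in genes if g not in truth.module_genes]
    lo, hi = size_range
    planted_members = set(truth.module_genes) | set(
        rng.choice(pool, size=min(n_decoy_members, len(pool)), replace=False)
    )
    pathways = {
        truth.planted_pathway_id: ("Planted module pathway", frozenset(planted_members))
    }
    for i in range(1, n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        pid = f"PW_{i:04d}"
        pathways[pid] = (f"Decoy pathway {i}", frozenset(members))
    return PathwayDB(pathways=pathways)


def simulate_inputs(
    outdir,
    n_genes: int = 300,
    module_size: int = 25,
    n_case: int = 10,
    n_control: int = 10,
    effect_size: float = 3.0,
    noise_sd: float = 0.2,
    n_pathways: int = 50,
    attach_m: int = 2,
    seed: int = 0,
) -> dict:
    """Write the full synthetic input bundle to ``outdir``.

    Produces expression.tsv, groups.tsv, deg_table.tsv, ppi.tsv,
    pathways.gmt and truth.json; returns the file paths and the truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_truth(n_genes, module_size, seed, effect_size, noise_sd)
    expr = simulate_expression(n_genes, n_case, n_control, truth)
    deg = simulate_deg_table(expr, truth)
    ppi = simulate_ppi(n_genes, attach_m, truth)
    db = simulate_pathways(n_pathways, truth=truth, n_genes=n_genes)
    paths = {
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "deg_table": outdir / "deg_table.tsv",
        "ppi": outdir / "ppi.tsv",
        "gmt": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression_matrix(expr, paths["expression"], paths["groups"])
    write_deg_table(deg, paths["deg_table"])
    write_edgelist(ppi, paths["ppi"])
    write_gmt(db, paths["gmt"])
    with open(paths["truth"], "w", encoding="utf-8") as handle:
        json.dump(asdict(truth), handle, indent=2, default=list)
    return {"truth": truth, "paths": {k: str(v) for k, v in paths.items()}}
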