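"""PPI mapping, radius-1 community expansion and Bottleneck selection.

Essential genes are intersected with the protein-protein interaction
network, expanded to their radius-1 neighborhood (seeds plus direct
interactors), and the community members are then ranked by Bottleneck
centrality: a node scores one point for every shortest-path tree root from
which more than a quarter of the nodes route through (or end at) it.  The
trees are breadth-first with lexicographic neighbor expansion, which pins
the score deterministically.  Members whose score strictly exceeds the
community average form the relevant gene set; if the strict rule selects
nothing (all scores equal), the comparison falls back to >= and the
fallback is logged.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx

from .network import EssentialGeneSet

__all__ = [
    "GeneCommunity",
    "RelevantGeneSet",
    "map_to_ppi",
    "neighborhood",
    "bottleneck_centrality",
    "select_relevant",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneCommunity:
    """Radius-r PPI neighborhood of a set of seed genes."""

    seeds: frozenset
    members: frozenset
    subgraph: nx.Graph
    regulation: str

    def __post_init__(self) -> None:
        if not self.seeds <= self.members:
            raise ValueError("seeds must be members of their community")


@dataclass(frozen=True)
class RelevantGeneSet:
    """Community members passing the Bottleneck-vs-average rule."""

    genes: frozenset
    regulation: str
    bottleneck_scores: dict
    average_bottleneck: float
    used_fallback: bool = False


def map_to_ppi(genes, ppi: nx.Graph):
    """Intersect a gene set with the PPI node set.

    Accepts a plain iterable of symbols or an :class:`EssentialGeneSet`.
    Returns ``(mapped, unmapped)`` frozensets; an empty mapped set is
    allowed (and logged).
    """
    if isinstance(genes, EssentialGeneSet):
        genes = genes.genes
    genes = frozenset(genes)
    mapped = frozenset(g for g in genes if ppi.has_node(g))
    unmapped = genes - mapped
    if not mapped and genes:
        logger.warning("no genes mapped onto the PPI network (%d unmapped)", len(unmapped))
    return mapped, unmapped


def neighborhood(
    ppi: nx.Graph, seeds, radius: int = 1, regulation: str = "up"
) -> GeneCommunity:
    """All nodes within hop distance <= radius of any seed, seeds included.

    Seeds must already lie on the PPI (run :func:`map_to_ppi` first).
    Radius 0 returns the seeds themselves.
    """
    if isinstance(seeds, EssentialGeneSet):
        seeds = seeds.genes
    seeds = frozenset(seeds)
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    outside = [s for s in seeds if not ppi.has_node(s)]
    if outside:
        raise ValueError(f"seeds not in PPI network: {sorted(outside)}")
    members: set = set()
    for seed in seeds:
        members.update(nx.single_source_shortest_path_length(ppi, seed, cutoff=radius))
    subgraph = nx.Graph(ppi.subgraph(members))
    return GeneCommunity(
        seeds=seeds, members=frozenset(members), subgraph=subgraph, regulation=regulation
    )


def bottleneck_centrality(graph: nx.Graph) -> dict:
    """Bottleneck centrality: shortest-path-tree load with the n/4 rule.

    For every root s, a BFS tree T_s is grown expanding neighbors in
    lexicographic order.  A node v != s earns a point from s when the
    number of nodes whose tree path from s passes through or ends at v
    (its subtree size) exceeds n/4, n the number of graph nodes.
    BN(v) is the total over roots.  A graph with no edges scores all 0.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    scores = dict.fromkeys(nodes, 0)
    quarter = n / 4.0
    for root in nodes:
        parent = {root: None}
        order = [root]
        queue = deque([root])
        while queue:
            u = queue.popleft()
            for w in sorted(graph.neighbors(u)):
                if w not in parent:
                    parent[w] = u
                    order.append(w)
                    queue.append(w)
        subtree = dict.fromkeys(order, 1)
        for v in reversed(order):
            p = parent[v]
            if p is not None:
                subtree[p] += subtree[v]
        for v in order:
            if v != root and subtree[v] > quarter:
                scores[v] += 1
    return scores


def select_relevant(community: GeneCommunity) -> RelevantGeneSet:
    """Members whose Bottleneck score strictly exceeds the community average.

    Scores are computed on the induced community subgraph and averaged
    over all members.  When every member has the same score the strict
    rule selects nothing; the selection then falls back to >= (keeping
    all members) and the fallback is logged.
    """
    if not community.members:
        raise ValueError("community has no members")
    scores = bottleneck_centrality(community.subgraph)
    average = sum(scores.values()) / len(scores)
    selected = {v for v, s in scores.items() if s > average}
    used_fallback = False
    if not selected:
        selected = {v for v, s in scores.items() if s >= average}
        used_fallback = True
        logger.warning(
            "all Bottleneck scores equal in %s community; falling back to >= rule",
            community.regulation,
        )
    return RelevantGeneSet(
        genes=frozenset(selected),
        regulation=community.regulation,
        bottleneck_scores=scores,
        average_bottleneck=average,
        used_fallback=used_fallback,
    )
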