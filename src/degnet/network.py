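"""Similarity-network construction and closeness-based essential-gene selection.

The thresholded similarity matrix maps directly to an undirected network:
genes are nodes, and an edge joins two genes whenever their cell is nonzero
(i.e. the KW p value reached the similarity threshold).  Closeness
centrality is then computed on unweighted hop distances, using the
Wasserman-Faust component scaling so that scores remain comparable on the
frequently disconnected similarity networks, and genes whose closeness is
at most the network-wide average are kept as the essential set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .similarity import SimilarityMatrix

__all__ = [
    "CentralityScores",
    "EssentialGeneSet",
    "to_network",
    "closeness_centrality",
    "select_essential",
]


@dataclass(frozen=True)
class CentralityScores:
    """Per-node centrality values plus their arithmetic mean."""

    scores: dict
    average: float


@dataclass(frozen=True)
class EssentialGeneSet:
    """Genes surviving the closeness-vs-average rule for one branch."""

    genes: frozenset
    regulation: str
    provenance: str


def to_network(sm: SimilarityMatrix) -> nx.Graph:
    """Convert a similarity matrix to a network.

    Every gene becomes a node (isolated genes included); an edge connects
    genes i and j iff their cell is nonzero, carrying the KW p value as
    ``weight``.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sm.genes)
    n = len(sm.genes)
    for i in range(n):
        for j in range(i + 1, n):
            if sm.values[i, j] > 0:
                graph.add_edge(sm.genes[i], sm.genes[j], weight=float(sm.values[i, j]))
    return graph


def closeness_centrality(net: nx.Graph) -> CentralityScores:
    """Component-scaled closeness on unweighted hop distances.

    For a node v in a component of size n_v within a graph of n nodes:
    CC(v) = ((n_v - 1) / sum_u d(v, u)) * ((n_v - 1) / (n - 1)).
    Isolated nodes score 0.  The average is the arithmetic mean over all
    nodes (0 for an empty graph).
    """
    if net.number_of_nodes() == 0:
        return CentralityScores(scores={}, average=0.0)
    scores = nx.closeness_centrality(net, wf_improved=True)
    scores = {v: float(c) for v, c in scores.items()}
    average = math.fsum(scores.values()) / len(scores)
    return CentralityScores(scores=scores, average=average)


def select_essential(
    net: nx.Graph,
    scores: CentralityScores,
    regulation: str = "up",
    invert_cc_rule: bool = False,
) -> EssentialGeneSet:
    """Select genes by the closeness-vs-average rule.

    Default keeps nodes with CC(v) <= average CC; ``invert_cc_rule``
    flips to >= for sensitivity analysis.  An empty network yields an
    empty set.
    """
    missing = set(net.nodes()) - set(scores.scores)
    if missing:
        raise ValueError(f"scores missing for nodes: {sorted(missing)}")
    # relative tolerance so all-equal scores compare equal to their mean
    tol = 1e-12 * max(1.0, abs(scores.average))
    if invert_cc_rule:
        selected = {v for v in net.nodes() if scores.scores[v] >= scores.average - tol}
        rule = "CC >= average (inverted)"
    else:
        selected = {v for v in net.nodes() if scores.scores[v] <= scores.average + tol}
        rule = "CC <= average"
    return EssentialGeneSet(
        genes=frozenset(selected), regulation=regulation, provenance=rule
    )
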