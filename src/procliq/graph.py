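"""Thresholded weighted similarity graph over action patterns.

Vertices are pattern identifiers; an edge {i, j} with weight s_ij is kept
iff s_ij ≥ κ.  κ encodes the minimum similarity two patterns must share
to be allowed into the same clique downstream, since cluster edge
deletion never connects vertices that are not input-graph neighbours.
"""

from __future__ import annotations

from collections.abc import Sequence
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["SimilarityGraph", "build_graph", "write_graphml", "read_graphml"]


class SimilarityGraph:
    """Weighted undirected graph with the construction threshold attached."""

    def __init__(self, graph: nx.Graph, kappa: float):
        self.g = graph
        self.kappa = float(kappa)

    @property
    def vertices(self) -> list:
        return list(self.g.nodes)

    @property
    def edges(self) -> list[tuple]:
        return list(self.g.edges)

    def weight(self, i, j) -> float:
        return self.g.edges[i, j]["weight"]

    def total_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.g.edges(data=True))

    def number_of_edges(self) -> int:
        return self.g.number_of_edges()

    def number_of_vertices(self) -> int:
        return self.g.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SimilarityGraph(|V|={self.g.number_of_nodes()}, "
            f"|E|={self.g.number_of_edges()}, kappa={self.kappa})"
        )


def build_graph(
    edge_list: pd.DataFrame,
    kappa: float = 0.5,
    vertices: Sequence | None = None,
) -> SimilarityGraph:
    """Build the similarity graph, keeping edges with s_ij ≥ κ (inclusive).

    ``edge_list`` has columns ``i``, ``j``, ``s`` with each unordered pair
    at most once.  ``vertices`` fixes the vertex set (so patterns whose
    every similarity falls below κ survive as isolated vertices); when
    omitted it is inferred from the edge list's endpoints.
    """
    if not (0.0 < kappa <= 1.0):
        raise ValueError(f"kappa must lie in (0, 1], got {kappa}")
    g = nx.Graph()
    if vertices is not None:
        g.add_nodes_from(vertices)
    seen: set[frozenset] = set()
    for i, j, s in edge_list[["i", "j", "s"]].itertuples(index=False):
        if i == j:
            raise ValueError(f"self-loop on vertex {i!r} in edge list")
        key = frozenset((i, j))
        if key in seen:
            raise ValueError(f"duplicate pair {{{i!r}, {j!r}}} in edge list")
        seen.add(key)
        if vertices is None:
            g.add_node(i)
            g.add_node(j)
        if s >= kappa:
            g.add_edge(i, j, weight=float(s))
    return SimilarityGraph(g, kappa)


def write_graphml(graph: SimilarityGraph, path: str | Path) -> None:
    g = graph.g.copy()
    g.graph["kappa"] = graph.kappa
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> SimilarityGraph:
    g = nx.read_graphml(path)
    kappa = float(g.graph.get("kappa", 0.5))
    return SimilarityGraph(g, kappa)
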