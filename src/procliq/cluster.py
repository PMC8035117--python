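"""Exact weighted cluster edge deletion.

A *cluster graph* is a disjoint union of cliques — equivalently, a graph
with no induced P3 (three vertices carrying exactly two edges).  Cluster
edge deletion turns the input similarity graph into a cluster graph by
deleting a minimum-weight edge set; no edges may be inserted, so two
patterns end up in the same clique only if every pair inside the clique
was already connected in the input graph.

The problem is NP-hard; it is solved exactly here as a 0/1 integer linear
program.  A binary variable x_ij marks each input edge as retained; the
objective maximises the total retained weight (equivalently, minimises
deleted weight) subject to the transitivity constraints

    x_ij + x_jk − x_ik ≤ 1   for every ordered triple,

which forbid P3s in the retained graph.  Variables for non-edges are
fixed to zero, so only triples holding at least two input edges generate
non-vacuous constraints: for a triple with both {i,j} and {j,k} present
but {i,k} absent the constraint degenerates to x_ij + x_jk ≤ 1, and
triples with fewer than two edges impose nothing.  The MILP is handed to
HiGHS via :func:`scipy.optimize.milp`.

A Bell-number brute-force enumeration over set partitions serves as an
independent exact oracle on small instances.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import SimilarityGraph

__all__ = [
    "Clustering",
    "SolverError",
    "solve_cluster_deletion",
    "solve_cluster_editing",
    "brute_force_cluster_deletion",
    "verify_cluster_graph",
]


class SolverError(RuntimeError):
    """The MILP backend failed or timed out without an incumbent."""


@dataclass
class Clustering:
    """A partition of the graph's vertices into cliques.

    ``objective`` is the total retained edge weight; ``status`` is
    ``optimal`` (proved), ``feasible`` (incumbent at the time limit) or
    ``exact`` (brute-force oracle).
    """

    cliques: list[frozenset]
    deleted_edges: set[frozenset]
    objective: float
    status: str
    solver: str = ""
    wall_time: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def membership(self) -> dict:
        """vertex → clique index (cliques sorted by size desc, then repr)."""
        order = sorted(
            self.cliques, key=lambda c: (-len(c), sorted(map(str, c)))
        )
        return {v: k for k, cl in enumerate(order) for v in cl}

    @property
    def n_cliques(self) -> int:
        return len(self.cliques)

    def singletons(self) -> list:
        return [next(iter(c)) for c in self.cliques if len(c) == 1]


def _edge_key(i, j) -> frozenset:
    return frozenset((i, j))


def solve_cluster_deletion(
    graph: SimilarityGraph, time_limit: float = 3600.0
) -> Clustering:
    """Maximum-retained-weight cluster edge deletion via the HiGHS MILP solver.

    Raises :class:`SolverError` if the solver hits ``time_limit`` without
    any incumbent; with an incumbent the result is returned with
    ``status='feasible'``.
    """
    import time

    g = graph.g
    edges = list(g.edges)
    t0 = time.perf_counter()
    if not edges:
        cliques = [frozenset((v,)) for v in g.nodes]
        return Clustering(cliques, set(), 0.0, "optimal", "trivial",
                          time.perf_counter() - t0)

    idx = {_edge_key(i, j): k for k, (i, j) in enumerate(edges)}
    weights = np.array([g.edges[e]["weight"] for e in edges], float)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    nrow = 0
    for j in g.nodes:
        nbrs = sorted(g.neighbors(j), key=str)
        for i, k in itertools.combinations(nbrs, 2):
            e_ij = idx[_edge_key(i, j)]
            e_jk = idx[_edge_key(j, k)]
            rows += [nrow, nrow]
            cols += [e_ij, e_jk]
            vals += [1.0, 1.0]
            if g.has_edge(i, k):
                rows.append(nrow)
                cols.append(idx[_edge_key(i, k)])
                vals.append(-1.0)
            nrow += 1

    constraints = []
    if nrow:
        a = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(nrow, len(edges))
        )
        constraints = [LinearConstraint(a, -np.inf, 1.0)]

    res = milp(
        c=-weights,
        constraints=constraints,
        integrality=np.ones(len(edges)),
        bounds=Bounds(0, 1),
        options={"time_limit": float(time_limit)},
    )
    wall = time.perf_counter() - t0
    if res.status == 0:
        status = "optimal"
    elif res.status == 1 and res.x is not None:
        status = "feasible"
    else:
        raise SolverError(
            f"MILP backend failed (status {res.status}: {res.message})"
        )

    keep = res.x > 0.5
    retained = [e for e, k in zip(edges, keep) if k]
    deleted = {_edge_key(i, j) for (i, j), k in zip(edges, keep) if not k}
    objective = float(weights[keep].sum())

    import networkx as nx

    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(retained)
    cliques = [frozenset(c) for c in nx.connected_components(h)]
    return Clustering(
        cliques, deleted, objective, status, "scipy-highs", wall,
        meta={"n_constraints": nrow, "n_variables": len(edges)},
    )


def solve_cluster_editing(
    graph: SimilarityGraph,
    insertion_cost: float = 1.0,
    time_limit: float = 3600.0,
) -> Clustering:
    """Full cluster editing (insertions allowed), as a flagged variant.

    The non-edge fixing is dropped: every vertex pair gets a variable, and
    retaining a non-edge (i.e. inserting it) costs ``insertion_cost``.
    Off the default path — deletion-only keeps cliques interpretable — and
    intended for small graphs only.
    """
    import time

    import networkx as nx

    g = graph.g
    nodes = sorted(g.nodes, key=str)
    pairs = list(itertools.combinations(nodes, 2))
    t0 = time.perf_counter()
    if not pairs:
        return Clustering([frozenset(nodes)] if nodes else [], set(), 0.0,
                          "optimal", "trivial", time.perf_counter() - t0)
    idx = {_edge_key(i, j): k for k, (i, j) in enumerate(pairs)}
    c = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        c[k] = g.edges[i, j]["weight"] if g.has_edge(i, j) else -insertion_cost

    rows, cols, vals = [], [], []
    nrow = 0
    for i, j, k in itertools.combinations(nodes, 3):
        for mid, (x, y) in (
            (j, (i, k)),  # x_ij + x_jk - x_ik <= 1
            (i, (j, k)),
            (k, (i, j)),
        ):
            a, b = [v for v in (i, j, k) if v != mid]
            rows += [nrow] * 3
            cols += [
                idx[_edge_key(a, mid)],
                idx[_edge_key(mid, b)],
                idx[_edge_key(x, y)],
            ]
            vals += [1.0, 1.0, -1.0]
            nrow += 1
    a_mat = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, len(pairs)))
    res = milp(
        c=-c,
        constraints=[LinearConstraint(a_mat, -np.inf, 1.0)],
        integrality=np.ones(len(pairs)),
        bounds=Bounds(0, 1),
        options={"time_limit": float(time_limit)},
    )
    wall = time.perf_counter() - t0
    if res.status == 0:
        status = "optimal"
    elif res.status == 1 and res.x is not None:
        status = "feasible"
    else:
        raise SolverError(
            f"MILP backend failed (status {res.status}: {res.message})"
        )
    keep = res.x > 0.5
    h = nx.Graph()
    h.add_nodes_from(nodes)
    h.add_edges_from(p for p, k in zip(pairs, keep) if k)
    deleted = {
        _edge_key(i, j)
        for (i, j), k in zip(pairs, keep)
        if not k and g.has_edge(i, j)
    }
    objective = float(c[keep].sum())
    cliques = [frozenset(cc) for cc in nx.connected_components(h)]
    return Clustering(cliques, deleted, objective, status, "scipy-highs",
                      wall, meta={"variant": "editing"})


def _partitions(items: Sequence) -> Iterator[list[list]]:
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


def brute_force_cluster_deletion(graph: SimilarityGraph) -> Clustering:
    """Exhaustive exact solution by enumerating all set partitions.

    A partition is admissible iff every block induces a clique in the
    input graph; among admissible partitions the one retaining maximum
    within-block edge weight is optimal.  Capped at 12 vertices.
    """
    g = graph.g
    nodes = sorted(g.nodes, key=str)
    if len(nodes) > 12:
        raise ValueError(
            f"brute force capped at 12 vertices, got {len(nodes)}"
        )
    best_obj = -1.0
    best_part: list[list] | None = None
    for part in _partitions(nodes):
        obj = 0.0
        ok = True
        for block in part:
            for i, j in itertools.combinations(block, 2):
                if not g.has_edge(i, j):
                    ok = False
                    break
                obj += g.edges[i, j]["weight"]
            if not ok:
                break
        if ok and obj > best_obj:
            best_obj = obj
            best_part = part
    assert best_part is not None  # singletons always admissible
    cliques = [frozenset(b) for b in best_part]
    within = {
        _edge_key(i, j)
        for b in best_part
        for i, j in itertools.combinations(b, 2)
    }
    deleted = {
        _edge_key(i, j) for i, j in g.edges if _edge_key(i, j) not in within
    }
    return Clustering(cliques, deleted, best_obj, "exact", "brute-force")


def verify_cluster_graph(
    graph: SimilarityGraph, clustering: Clustering
) -> bool:
    """Check the deletion-only cluster-graph contract.

    True iff the cliques partition the vertex set, every within-clique
    pair is an input edge, deleted edges are input edges, and the
    retained graph (input minus deleted) is exactly the union of complete
    graphs on the cliques — hence P3-free.
    """
    g = graph.g
    all_vertices = set(g.nodes)
    seen: set = set()
    for c in clustering.cliques:
        if seen & c:
            return False
        seen |= c
    if seen != all_vertices:
        return False

    input_edges = {_edge_key(i, j) for i, j in g.edges}
    if not clustering.deleted_edges <= input_edges:
        return False
    within = {
        _edge_key(i, j)
        for c in clustering.cliques
        for i, j in itertools.combinations(c, 2)
    }
    if not within <= input_edges:
        return False  # a clique pair was never an input edge
    retained = input_edges - clustering.deleted_edges
    return retained == within
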