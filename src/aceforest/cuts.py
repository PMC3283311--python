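"""Min-cut / min-UnCut machinery for green-only and red-only instances.

A green-only instance (every table of the form (0, a, a, 0)) maps to a
minimum cut: one graph vertex per forest node, one edge of weight a per
forest edge; labelings of total weight W correspond exactly to cuts of
weight W.  A red-only instance ((a, 0, 0, a) tables) maps the same way to
min-UnCut: the cost is the weight of the edges *not* cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np

from .errors import ReductionDomainError, SizeCapError
from .forest import CoEvolvingForest, FullLabeling, ace_score
from .result import SolveResult

__all__ = [
    "CutInstance",
    "to_cut_instance",
    "solve_green_cut",
    "solve_green_forest",
    "verify_min_uncut_reduction",
]

Node = tuple[int, int]  # (family index, node id)


@dataclass
class CutInstance:
    """An undirected weighted graph plus terminal sides from observed leaves."""

    nodes: list[Node]
    edges: list[tuple[Node, Node, float]]
    side1: set[Node] = field(default_factory=set)
    side0: set[Node] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.side1 & self.side0:
            raise ReductionDomainError("terminal sets must be disjoint")
        if any(w < 0 for _, _, w in self.edges):
            raise ReductionDomainError("edge weights must be non-negative")


def _forest_edges(forest: CoEvolvingForest):
    """All forest edges with their tables: tree edges then co-evolution edges."""
    for f in range(forest.n_families):
        for p, c in forest.topology.edges():
            yield (f, p), (f, c), forest.tree_table(f, c)
    for (i, j), t in forest.coevo_tables.items():
        for v in range(forest.n_nodes):
            yield (i, v), (j, v), t


def to_cut_instance(forest: CoEvolvingForest) -> CutInstance:
    """Reduce a green-only forest to a minimum-cut instance.

    Every table must be exactly of the form (0, a, a, 0); the cut edge
    weight is a.  Observed-1 leaves become side-1 terminals and observed-0
    leaves side-0 terminals.
    """
    edges = []
    for u, v, t in _forest_edges(forest):
        if not t.is_green_form:
            raise ReductionDomainError(
                f"table {t.as_tuple()} on edge {u}-{v} is not of green form (0,a,a,0)"
            )
        edges.append((u, v, t.w01))
    nodes = [(f, v) for f in range(forest.n_families) for v in range(forest.n_nodes)]
    side1 = {(f, v) for f, v, lab in forest.fixed_slots() if lab == 1}
    side0 = {(f, v) for f, v, lab in forest.fixed_slots() if lab == 0}
    return CutInstance(nodes=nodes, edges=edges, side1=side1, side0=side0)


def solve_green_cut(
    nodes: list[Node],
    edges: list[tuple[Node, Node, float]],
    fixed: dict[Node, int],
) -> tuple[float, dict[Node, int]]:
    """Minimum-weight label assignment for symmetric-difference edge costs.

    Each edge (u, v, a) costs a when its endpoints get different labels and
    0 otherwise; ``fixed`` pins node labels.  With terminals on both sides
    this is an s-t min-cut (super-source = fixed 1s, super-sink = fixed 0s)
    solved by max-flow; with terminals on at most one side the constant
    labeling is optimal (cost 0) and returned directly.

    Returns (cut weight, labels for every node).  The returned partition is
    the max-flow residual-reachability cut, which is deterministic.
    """
    side1 = [u for u, lab in fixed.items() if lab == 1]
    side0 = [u for u, lab in fixed.items() if lab == 0]
    if not side1 or not side0:
        const = 1 if side1 else 0
        return 0.0, {u: fixed.get(u, const) for u in nodes}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        if g.has_edge(u, v):
            g[u][v]["capacity"] += w
        else:
            g.add_edge(u, v, capacity=w)
    src, snk = ("__s__",), ("__t__",)
    for u in side1:
        g.add_edge(src, u, capacity=np.inf)
    for u in side0:
        g.add_edge(snk, u, capacity=np.inf)
    cut_value, (reach, _) = nx.minimum_cut(g, src, snk)
    labels = {u: (1 if u in reach else 0) for u in nodes}
    labels.update(fixed)
    return float(cut_value), labels


def solve_green_forest(forest: CoEvolvingForest) -> SolveResult:
    """Optimal labeling of a green-only forest via the min-cut reduction."""
    inst = to_cut_instance(forest)
    fixed = {u: 1 for u in inst.side1}
    fixed.update({u: 0 for u in inst.side0})
    cut_value, labels = solve_green_cut(inst.nodes, inst.edges, fixed)
    arr = np.zeros((forest.n_families, forest.n_nodes), dtype=np.int8)
    for (f, v), lab in labels.items():
        arr[f, v] = lab
    labeling = FullLabeling(arr)
    cost = ace_score(forest, labeling)
    return SolveResult(
        labeling=labeling,
        cost=cost,
        optimal=True,
        method="mincut",
        info={"cut_weight": cut_value},
    )


def global_min_cut(forest: CoEvolvingForest) -> tuple[float, set[Node]]:
    """Stoer-Wagner global minimum cut of a green-only forest's graph.

    Returns (cut weight, one side of the best nontrivial bipartition).
    Note the unconstrained labeling optimum is the constant labeling (cost
    0); this solves the classical both-sides-non-empty cut instead.
    """
    inst = to_cut_instance(forest)
    g = nx.Graph()
    g.add_nodes_from(inst.nodes)
    for u, v, w in inst.edges:
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    value, (side_a, _) = nx.stoer_wagner(g)
    return float(value), set(side_a)


def verify_min_uncut_reduction(forest: CoEvolvingForest, cap: int = 14) -> bool:
    """Check the red-only ACE / min-UnCut correspondence by enumeration.

    Requires every table to be exactly of the form (a, 0, 0, a).  Enumerates
    all bipartitions consistent with observed leaves (side S = label 1),
    computes the minimum UnCut weight (total weight of uncut edges)
    directly, and compares it with the brute-force optimum.
    """
    from .exact import brute_force_optimum

    edges = []
    for u, v, t in _forest_edges(forest):
        if not t.is_red_form:
            raise ReductionDomainError(
                f"table {t.as_tuple()} on edge {u}-{v} is not of red form (a,0,0,a)"
            )
        edges.append((u, v, t.w00))
    nodes = [(f, v) for f in range(forest.n_families) for v in range(forest.n_nodes)]
    fixed = {(f, v): lab for f, v, lab in forest.fixed_slots()}
    free = [u for u in nodes if u not in fixed]
    if len(free) > cap:
        raise SizeCapError(f"{len(free)} free nodes exceeds enumeration cap {cap}")
    best = np.inf
    for assignment in product((0, 1), repeat=len(free)):
        side = dict(fixed)
        side.update(zip(free, assignment))
        uncut = sum(w for u, v, w in edges if side[u] == side[v])
        best = min(best, uncut)
    ace_opt = brute_force_optimum(forest).cost
    return abs(best - ace_opt) <= 1e-9
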