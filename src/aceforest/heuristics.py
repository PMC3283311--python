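"""Scalable approximate solvers: greedy flips, cluster/DP/greedy, min-cut seeding."""

from __future__ import annotations

import warnings

import numpy as np

from .cuts import solve_green_cut
from .errors import ContractError
from .exact import component_dp
from .forest import CoEvolvingForest, FullLabeling, ace_score, build_coevolutionary_graph
from .result import SolveResult
from .tables import WeightTable, classify_edge

__all__ = [
    "greedy_improve",
    "cluster_forest",
    "fpt_heuristic",
    "mincut_heuristic",
    "round_green",
]


class _ScoreCache:
    """Precomputed table arrays and co-evolution partner lists for fast flips."""

    def __init__(self, forest: CoEvolvingForest) -> None:
        self.forest = forest
        self.tree_arr = {
            (f, c): forest.tree_table(f, c).as_array()
            for f in range(forest.n_families)
            for _, c in forest.topology.edges()
        }
        # partners[f] = [(other family, table array, f is the table's first index)]
        self.partners: list[list] = [[] for _ in range(forest.n_families)]
        for (i, j), t in forest.coevo_tables.items():
            arr = t.as_array()
            self.partners[i].append((j, arr, True))
            self.partners[j].append((i, arr, False))

    def flip_delta(self, labels: np.ndarray, f: int, v: int) -> float:
        """Score change from flipping node v of family f, in O(degree)."""
        forest = self.forest
        old = int(labels[f, v])
        new = 1 - old
        delta = 0.0
        p = int(forest.topology.parent[v])
        if p >= 0:
            t = self.tree_arr[(f, v)]
            delta += t[labels[f, p], new] - t[labels[f, p], old]
        for c in forest.topology.children[v]:
            t = self.tree_arr[(f, c)]
            delta += t[new, labels[f, c]] - t[old, labels[f, c]]
        for g, t, first in self.partners[f]:
            if first:
                delta += t[new, labels[g, v]] - t[old, labels[g, v]]
            else:
                delta += t[labels[g, v], new] - t[labels[g, v], old]
        return float(delta)


def greedy_improve(forest: CoEvolvingForest, labeling: FullLabeling) -> SolveResult:
    """Steepest-descent single-node flips until no flip improves the score.

    Only free nodes (internal nodes and missing leaves) may flip.  Ties
    between equally improving flips go to the lowest (family, preorder
    node) index, making the procedure deterministic and idempotent.
    """
    labeling.validate(forest)
    labels = labeling.labels.copy()
    free = forest.free_slots()
    cache = _ScoreCache(forest)
    start_cost = ace_score(forest, FullLabeling(labels))
    cost = start_cost
    while True:
        best_delta = -1e-12
        best_slot = None
        for f, v in free:
            d = cache.flip_delta(labels, f, v)
            if d < best_delta:
                best_delta = d
                best_slot = (f, v)
        if best_slot is None:
            break
        f, v = best_slot
        labels[f, v] = 1 - labels[f, v]
        cost += best_delta
    result_labeling = FullLabeling(labels)
    cost = ace_score(forest, result_labeling)
    return SolveResult(
        labeling=result_labeling,
        cost=cost,
        optimal=False,
        method="greedy",
        info={"start_cost": start_cost},
    )


def round_green(table: WeightTable) -> WeightTable:
    """Round a green-classified table to (0, A, A, 0) with A = mean(w01, w10)."""
    a = (table.w01 + table.w10) / 2.0
    return WeightTable(0.0, a, a, 0.0)


def _pair_weight(table: WeightTable) -> float:
    """Coupling strength proxy for clustering: total mass of the table's pull."""
    return float(abs(table.w01 + table.w10 - table.w00 - table.w11))


def cluster_forest(forest: CoEvolvingForest, max_component: int) -> list[list[int]]:
    """Partition the trees into parts of at most ``max_component`` trees.

    Components of the co-evolutionary graph that already fit stay whole.
    Oversized components are split by greedily growing parts that keep the
    maximum within-part co-evolution edge weight: each part is seeded with
    the remaining tree of largest incident weight and extended one tree at
    a time by the largest weight gain.  Returns parts as sorted lists of
    family indices, in ascending order of their smallest member.
    """
    if max_component < 1:
        raise ContractError("max_component must be >= 1")
    graph = build_coevolutionary_graph(forest)
    weight = {pair: _pair_weight(t) for pair, t in forest.coevo_tables.items()}
    parts: list[list[int]] = []
    import networkx as nx

    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) <= max_component:
            parts.append(comp)
            continue
        remaining = set(comp)
        while remaining:
            if len(remaining) <= max_component:
                parts.append(sorted(remaining))
                break
            seed = max(
                sorted(remaining),
                key=lambda f: sum(
                    w
                    for (i, j), w in weight.items()
                    if (i == f and j in remaining) or (j == f and i in remaining)
                ),
            )
            part = {seed}
            while len(part) < max_component:
                candidates = remaining - part
                gains = {
                    f: sum(
                        w
                        for (i, j), w in weight.items()
                        if (i == f and j in part) or (j == f and i in part)
                    )
                    for f in sorted(candidates)
                }
                nxt = max(sorted(candidates), key=lambda f: gains[f])
                part.add(nxt)
            parts.append(sorted(part))
            remaining -= part
    return sorted(parts)


def _restrict(forest: CoEvolvingForest, part: list[int]) -> CoEvolvingForest:
    """Sub-forest over the families in ``part``; cross-part co-evolution dropped."""
    pos = {f: i for i, f in enumerate(part)}
    return CoEvolvingForest(
        topology=forest.topology,
        families=[forest.families[f] for f in part],
        leaf_labels=forest.leaf_labels[part],
        tree_tables={
            (pos[f], c): t for (f, c), t in forest.tree_tables.items() if f in pos
        },
        coevo_tables={
            (pos[i], pos[j]): t
            for (i, j), t in forest.coevo_tables.items()
            if i in pos and j in pos
        },
        default_tree_table=forest.default_tree_table,
    )


def fpt_heuristic(
    forest: CoEvolvingForest, max_component: int = 10, state_cap: int = 1 << 12
) -> SolveResult:
    """Cluster the forest, solve each part exactly by DP, then improve greedily.

    Exact (and equal to the global optimum) whenever clustering drops no
    co-evolution edge; otherwise an upper bound on the optimum.
    """
    parts = cluster_forest(forest, max_component)
    labels = np.zeros((forest.n_families, forest.n_nodes), dtype=np.int8)
    for part in parts:
        sub = _restrict(forest, part)
        res = component_dp(sub, state_cap=state_cap)
        labels[part] = res.labeling.labels
    merged = FullLabeling(labels)
    pre_cost = ace_score(forest, merged)
    dropped = sum(
        _pair_weight(t)
        for (i, j), t in forest.coevo_tables.items()
        if not any(i in p and j in p for p in parts)
    )
    improved = greedy_improve(forest, merged)
    return SolveResult(
        labeling=improved.labeling,
        cost=improved.cost,
        optimal=False,
        method="fpt-heuristic",
        info={
            "parts": parts,
            "dropped_coevo_weight": dropped,
            "pre_greedy_cost": pre_cost,
        },
    )


def mincut_heuristic(forest: CoEvolvingForest) -> SolveResult:
    """Min-cut seed on rounded green edges, then greedy on the full table set.

    Step 1 keeps only green-classified edges, rounds each to
    (0, A, A, 0) with A = (w01 + w10) / 2, and solves the resulting cut
    problem.  Step 2 runs the greedy improver under the original tables.
    """
    green_edges = []
    any_green = False
    from .cuts import _forest_edges

    for u, v, t in _forest_edges(forest):
        if classify_edge(t) == "green":
            any_green = True
            green_edges.append((u, v, round_green(t).w01))
    nodes = [(f, v) for f in range(forest.n_families) for v in range(forest.n_nodes)]
    fixed = {(f, v): lab for f, v, lab in forest.fixed_slots()}
    if not any_green:
        warnings.warn("no green edges; starting greedy from all-zeros", stacklevel=2)
        labels = np.zeros((forest.n_families, forest.n_nodes), dtype=np.int8)
        for (f, v), lab in fixed.items():
            labels[f, v] = lab
        seed = FullLabeling(labels)
    else:
        _, cut_labels = solve_green_cut(nodes, green_edges, fixed)
        labels = np.zeros((forest.n_families, forest.n_nodes), dtype=np.int8)
        for (f, v), lab in cut_labels.items():
            labels[f, v] = lab
        seed = FullLabeling(labels)
    seed_cost = ace_score(forest, seed)
    improved = greedy_improve(forest, seed)
    return SolveResult(
        labeling=improved.labeling,
        cost=improved.cost,
        optimal=False,
        method="mincut-heuristic",
        info={"seed_cost": seed_cost},
    )
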