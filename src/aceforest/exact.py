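"""Provably optimal solvers: brute force, product-alphabet DP, red-edge FPT.

The DP runs independently on each connected component of the co-evolutionary
graph, over the product alphabet {0,1}^k of the component's k trees; its
state space therefore grows with the largest component, as does the exact
method's running time.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .errors import SizeCapError
from .forest import MISSING, CoEvolvingForest, FullLabeling, ace_score, build_coevolutionary_graph
from .result import SolveResult

__all__ = ["brute_force_optimum", "component_dp", "fpt_red_edges"]

_CHUNK = 1 << 14


def brute_force_optimum(forest: CoEvolvingForest, cap: int = 24) -> SolveResult:
    """Enumerate all assignments of the free nodes and return a minimizer.

    Free nodes are internal nodes plus missing leaves.  Ties are broken by
    the lexicographically smallest assignment in (family, preorder node)
    order.  Raises :class:`SizeCapError` when there are more than ``cap``
    free nodes.
    """
    free = forest.free_slots()
    k = len(free)
    if k > cap:
        raise SizeCapError(f"{k} free nodes exceeds brute-force cap {cap}")
    F, N = forest.n_families, forest.n_nodes
    base = np.zeros((F, N), dtype=np.int8)
    for f, v, lab in forest.fixed_slots():
        base[f, v] = lab

    tree_edges = [
        (f, p, c, forest.tree_table(f, c).as_array())
        for f in range(F)
        for p, c in forest.topology.edges()
    ]
    coevo = [(i, j, t.as_array()) for (i, j), t in forest.coevo_tables.items()]

    best_cost = np.inf
    best_idx = -1
    best_labels = None
    total = 1 << k
    # most-significant bit = first free slot, so enumeration order is the
    # lexicographic order used for tie-breaking and argmin picks the winner
    shifts = np.arange(k - 1, -1, -1, dtype=np.int64)
    for start in range(0, total, _CHUNK):
        idx = np.arange(start, min(start + _CHUNK, total), dtype=np.int64)
        m = len(idx)
        L = np.broadcast_to(base, (m, F, N)).copy()
        if k:
            bits = ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int8)
            for s, (f, v) in enumerate(free):
                L[:, f, v] = bits[:, s]
        score = np.zeros(m)
        for f, p, c, w in tree_edges:
            score += w[L[:, f, p], L[:, f, c]]
        for i, j, w in coevo:
            score += w[L[:, i, :], L[:, j, :]].sum(axis=1)
        a = int(np.argmin(score))
        if score[a] < best_cost - 1e-15:
            best_cost = float(score[a])
            best_idx = int(idx[a])
            best_labels = L[a].copy()
    labeling = FullLabeling(best_labels)
    return SolveResult(
        labeling=labeling,
        cost=best_cost,
        optimal=True,
        method="brute",
        info={"enumerated": total, "best_index": best_idx},
    )


def _component_bits(k: int) -> np.ndarray:
    s = np.arange(1 << k, dtype=np.int64)
    return ((s[:, None] >> np.arange(k)[None, :]) & 1).astype(np.int8)


def component_dp(forest: CoEvolvingForest, state_cap: int = 1 << 12) -> SolveResult:
    """Weighted-parsimony DP over the product alphabet, per component.

    For each connected component of the co-evolutionary graph the shared
    topology is swept bottom-up over joint states of the component's trees.
    Co-evolution costs attach once per node at that node's joint state
    (child side of its parent edge; the root pays its own).  Missing leaves
    are unconstrained; observed leaves force their coordinate.
    """
    graph = build_coevolutionary_graph(forest)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort()
    N = forest.n_nodes
    labels = np.zeros((forest.n_families, N), dtype=np.int8)
    total_cost = 0.0
    for comp in components:
        k = len(comp)
        S = 1 << k
        if S > state_cap:
            raise SizeCapError(
                f"component of {k} trees needs {S} DP states (> cap {state_cap}); "
                "use the clustering heuristic instead"
            )
        bits = _component_bits(k)
        # co-evolution cost of a joint state, paid once per node
        nc = np.zeros(S)
        for (i, j), table in forest.coevo_tables.items():
            if i in comp:
                w = table.as_array()
                nc += w[bits[:, comp.index(i)], bits[:, comp.index(j)]]
        C = np.full((N, S), np.inf)
        choice = np.zeros((N, S), dtype=np.int64)
        for v in range(N - 1, -1, -1):
            if forest.topology.is_leaf(v):
                cost = nc.copy()
                for fl, f in enumerate(comp):
                    lab = forest.observed_leaf(f, v)
                    if lab != MISSING:
                        cost[bits[:, fl] != lab] = np.inf
                C[v] = cost
            else:
                cost = nc.copy()
                for c in forest.topology.children[v]:
                    T = np.zeros((S, S))
                    for fl, f in enumerate(comp):
                        w = forest.tree_table(f, c).as_array()
                        T += w[bits[:, fl][:, None], bits[:, fl][None, :]]
                    M = T + C[c][None, :]
                    best_t = np.argmin(M, axis=1)
                    cost += M[np.arange(S), best_t]
                    choice[c] = best_t
                C[v] = cost
        root_state = int(np.argmin(C[0]))
        total_cost += float(C[0, root_state])
        state = np.zeros(N, dtype=np.int64)
        state[0] = root_state
        for v in range(1, N):
            state[v] = choice[v, state[int(forest.topology.parent[v])]]
        for fl, f in enumerate(comp):
            labels[f] = bits[state, fl]
    labeling = FullLabeling(labels)
    return SolveResult(labeling=labeling, cost=total_cost, optimal=True, method="dp")


def fpt_red_edges(forest: CoEvolvingForest, cap: int = 20) -> SolveResult:
    """Exact solve by enumerating labels at nodes incident to red edges.

    Edges whose table is exactly of the form (0, a, a, 0) are green; every
    other edge is treated as red.  All 0/1 assignments to the free nodes
    touching a red edge are enumerated (observed leaves stay fixed); for
    each assignment the red-edge cost is paid directly and the residual
    green problem is solved by min-cut with the assigned nodes as extra
    terminals.  Runs 2^(free red-incident nodes) min-cut calls.
    """
    from .cuts import solve_green_cut

    F = forest.n_families
    green_edges: list[tuple[tuple[int, int], tuple[int, int], float]] = []
    red_edges: list[tuple[tuple[int, int], tuple[int, int], np.ndarray]] = []
    for f in range(F):
        for p, c in forest.topology.edges():
            t = forest.tree_table(f, c)
            if t.is_green_form:
                green_edges.append(((f, p), (f, c), t.w01))
            else:
                red_edges.append(((f, p), (f, c), t.as_array()))
    for (i, j), t in forest.coevo_tables.items():
        for v in range(forest.n_nodes):
            if t.is_green_form:
                green_edges.append(((i, v), (j, v), t.w01))
            else:
                red_edges.append(((i, v), (j, v), t.as_array()))

    fixed = {(f, v): lab for f, v, lab in forest.fixed_slots()}
    red_nodes = sorted(
        {u for e in red_edges for u in e[:2] if u not in fixed}
    )
    r = len(red_nodes)
    if r > cap:
        raise SizeCapError(f"{r} free red-incident nodes exceeds FPT cap {cap}")

    all_nodes = [(f, v) for f in range(F) for v in range(forest.n_nodes)]
    best_cost = np.inf
    best_labels: dict[tuple[int, int], int] | None = None
    enumerated = 0
    for mask in range(1 << r):
        enumerated += 1
        assign = dict(fixed)
        for s, node in enumerate(red_nodes):
            assign[node] = (mask >> (r - 1 - s)) & 1
        red_cost = sum(w[assign[u], assign[v]] for u, v, w in red_edges)
        if red_cost >= best_cost:
            continue
        cut_cost, cut_labels = solve_green_cut(all_nodes, green_edges, assign)
        if red_cost + cut_cost < best_cost - 1e-12:
            best_cost = red_cost + cut_cost
            best_labels = cut_labels
    labels = np.zeros((F, forest.n_nodes), dtype=np.int8)
    for (f, v), lab in best_labels.items():
        labels[f, v] = lab
    labeling = FullLabeling(labels)
    cost = ace_score(forest, labeling)
    return SolveResult(
        labeling=labeling,
        cost=cost,
        optimal=True,
        method="fpt",
        info={"enumerated": enumerated, "red_incident_free_nodes": r},
    )
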