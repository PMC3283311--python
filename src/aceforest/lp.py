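"""Linear/integer programming formulation and a quadratic objective for ACE.

Variables: one node variable y per forest node, plus four edge variables per
forest edge (one per ordered label pair).  Constraints per edge (i, j):

    e00 + e01 + e10 + e11 = 1          (exactly one assignment)
    e10 + e11 = y_i                    (consistency at the first endpoint)
    e01 + e11 = y_j                    (consistency at the second endpoint)

giving 4|E| + |V| variables and 3|E| constraints; all variables live in
[0, 1], observed leaves pin their y by equal bounds.  The relaxed optimum is
a lower bound on the integer optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .errors import ContractError
from .forest import CoEvolvingForest, FullLabeling, ace_score
from .result import SolveResult

__all__ = ["AceLinearProgram", "build_lp", "solve_lp", "qp_objective", "local_qp_descent"]

_INT_TOL = 1e-6

Node = tuple[int, int]


@dataclass
class AceLinearProgram:
    """An assembled LP/IP for one forest."""

    forest: CoEvolvingForest
    c: np.ndarray
    a_eq: sp.csr_matrix
    b_eq: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    relaxed: bool
    node_vars: dict[Node, int]
    edge_vars: list[tuple[Node, Node, int]] = field(repr=False)  # (u, v, first var index)

    @property
    def n_variables(self) -> int:
        return len(self.c)

    @property
    def n_constraints(self) -> int:
        return self.a_eq.shape[0]


def _forest_edges(forest: CoEvolvingForest):
    for f in range(forest.n_families):
        for p, c in forest.topology.edges():
            yield (f, p), (f, c), forest.tree_table(f, c)
    for (i, j), t in forest.coevo_tables.items():
        for v in range(forest.n_nodes):
            yield (i, v), (j, v), t


def build_lp(forest: CoEvolvingForest, relaxed: bool = True) -> AceLinearProgram:
    """Assemble the (relaxed or integer) program for a forest."""
    nodes = [(f, v) for f in range(forest.n_families) for v in range(forest.n_nodes)]
    node_vars = {u: i for i, u in enumerate(nodes)}
    n_nodes = len(nodes)
    edges = list(_forest_edges(forest))
    n_vars = n_nodes + 4 * len(edges)
    c = np.zeros(n_vars)
    lower = np.zeros(n_vars)
    upper = np.ones(n_vars)
    for f, v, lab in forest.fixed_slots():
        i = node_vars[(f, v)]
        lower[i] = upper[i] = float(lab)

    rows, cols, vals = [], [], []
    b_eq = []
    edge_vars = []
    row = 0
    for k, (u, v, table) in enumerate(edges):
        base = n_nodes + 4 * k  # e00, e01, e10, e11
        edge_vars.append((u, v, base))
        w = table.as_tuple()
        c[base : base + 4] = w
        # one assignment per edge
        rows += [row] * 4
        cols += [base, base + 1, base + 2, base + 3]
        vals += [1.0] * 4
        b_eq.append(1.0)
        row += 1
        # e10 + e11 = y_u
        rows += [row, row, row]
        cols += [base + 2, base + 3, node_vars[u]]
        vals += [1.0, 1.0, -1.0]
        b_eq.append(0.0)
        row += 1
        # e01 + e11 = y_v
        rows += [row, row, row]
        cols += [base + 1, base + 3, node_vars[v]]
        vals += [1.0, 1.0, -1.0]
        b_eq.append(0.0)
        row += 1
    a_eq = sp.csr_matrix(
        (vals, (rows, cols)), shape=(row, n_vars)
    )
    return AceLinearProgram(
        forest=forest,
        c=c,
        a_eq=a_eq,
        b_eq=np.asarray(b_eq),
        lower=lower,
        upper=upper,
        relaxed=relaxed,
        node_vars=node_vars,
        edge_vars=edge_vars,
    )


def _labeling_from_y(program: AceLinearProgram, y: np.ndarray) -> FullLabeling:
    forest = program.forest
    arr = np.zeros((forest.n_families, forest.n_nodes), dtype=np.int8)
    for (f, v), i in program.node_vars.items():
        arr[f, v] = int(round(y[i]))
    return FullLabeling(arr)


def solve_lp(program: AceLinearProgram) -> SolveResult:
    """Solve the program with HiGHS.

    Relaxed: returns the LP optimum as ``lower_bound``; a labeling is
    attached only when the solution is integral (within 1e-6), in which
    case it is also optimal.  Integer: returns the exact optimal labeling.
    """
    if program.relaxed:
        res = linprog(
            program.c,
            A_eq=program.a_eq,
            b_eq=program.b_eq,
            bounds=np.column_stack([program.lower, program.upper]),
            method="highs",
        )
        if not res.success:  # pragma: no cover - valid programs are feasible
            raise RuntimeError(f"LP solver failed: {res.message}")
        x = res.x
        integral = bool(np.all(np.minimum(np.abs(x), np.abs(x - 1.0)) <= _INT_TOL))
        if integral:
            labeling = _labeling_from_y(program, x)
            cost = ace_score(program.forest, labeling)
            return SolveResult(
                labeling=labeling,
                cost=cost,
                optimal=True,
                method="lp",
                lower_bound=float(res.fun),
                info={"integral": True},
            )
        return SolveResult(
            labeling=None,
            cost=float(res.fun),
            optimal=False,
            method="lp",
            lower_bound=float(res.fun),
            info={"integral": False},
        )
    res = milp(
        c=program.c,
        constraints=LinearConstraint(program.a_eq, program.b_eq, program.b_eq),
        bounds=Bounds(program.lower, program.upper),
        integrality=np.ones_like(program.c),
    )
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"MILP solver failed: {res.message}")
    labeling = _labeling_from_y(program, res.x)
    cost = ace_score(program.forest, labeling)
    return SolveResult(
        labeling=labeling,
        cost=cost,
        optimal=True,
        method="ip",
        lower_bound=float(res.fun),
        info={"integral": True},
    )


def qp_objective(forest: CoEvolvingForest, y) -> float:
    """Quadratic relaxation objective at a point y in [0, 1]^|V|.

    Per edge (i, j) with table (w00, w01, w10, w11):

        w00 (1-y_i)(1-y_j) + w01 (1-y_i) y_j + w10 y_i (1-y_j) + w11 y_i y_j

    On integer y this equals the labeling's total weight exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (forest.n_forest_nodes(),):
        raise ContractError(
            f"y must have one entry per forest node ({forest.n_forest_nodes()})"
        )
    if ((y < 0) | (y > 1)).any():
        raise ContractError("entries of y must lie in [0, 1]")
    idx = {
        (f, v): f * forest.n_nodes + v
        for f in range(forest.n_families)
        for v in range(forest.n_nodes)
    }
    total = 0.0
    for u, v, t in _forest_edges(forest):
        yi, yj = y[idx[u]], y[idx[v]]
        total += (
            t.w00 * (1 - yi) * (1 - yj)
            + t.w01 * (1 - yi) * yj
            + t.w10 * yi * (1 - yj)
            + t.w11 * yi * yj
        )
    return float(total)


def local_qp_descent(
    forest: CoEvolvingForest, y0, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Coordinate descent on the quadratic objective over [0, 1]^|V|.

    The objective is multilinear, hence linear in each coordinate: each pass
    moves every free coordinate to the better endpoint {0, 1} (observed
    leaves stay pinned).  The objective is monotone non-increasing and the
    method stops at a coordinate-wise minimum or after ``max_iter`` passes.
    """
    y = np.asarray(y0, dtype=float).copy()
    n = forest.n_forest_nodes()
    if y.shape != (n,):
        raise ContractError("y0 has wrong length")
    N = forest.n_nodes
    fixed_idx = {f * N + v: lab for f, v, lab in forest.fixed_slots()}
    for i, lab in fixed_idx.items():
        y[i] = float(lab)
    # incident edge list per coordinate, for O(deg) coordinate updates
    incident: list[list[tuple[int, int, object, bool]]] = [[] for _ in range(n)]
    for u, v, t in _forest_edges(forest):
        iu, iv = u[0] * N + u[1], v[0] * N + v[1]
        incident[iu].append((iu, iv, t, True))
        incident[iv].append((iu, iv, t, False))
    value = qp_objective(forest, y)
    for _ in range(max_iter):
        changed = False
        for i in range(n):
            if i in fixed_idx:
                continue
            # d(objective)/d(y_i) given the other coordinates
            slope = 0.0
            for iu, iv, t, is_first in incident[i]:
                other = y[iv] if is_first else y[iu]
                if is_first:
                    slope += (t.w10 - t.w00) * (1 - other) + (t.w11 - t.w01) * other
                else:
                    slope += (t.w01 - t.w00) * (1 - other) + (t.w11 - t.w10) * other
            target = 0.0 if slope > 0 else (1.0 if slope < 0 else y[i])
            if target != y[i]:
                y[i] = target
                changed = True
        if not changed:
            break
    value = qp_objective(forest, y)
    return y, value
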