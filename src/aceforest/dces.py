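"""Dominant co-evolutionary set selection and target-genome imputation.

A family outside the selected set must be *covered*: either its residual
uncertainty given the set, approximated as H(F_i) - sum of MI to set
members, falls below W1, or its own tree carries enough signal about the
target leaf (tree weight above W2).  Selection is greedy removal from the
full set; imputation alternates ancestral inference with local flips of
the imputed leaf values until the total score stabilizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, InputError
from .forest import MISSING, CoEvolvingForest, FullLabeling, ace_score
from .heuristics import fpt_heuristic

__all__ = [
    "entropy",
    "mutual_information",
    "tree_signal",
    "DcesGraph",
    "DominantSetResult",
    "build_dces_graph",
    "select_dominant_set",
    "default_w1",
    "sweep_w2_for_size",
    "impute_target",
]


def entropy(profile) -> float:
    """Empirical Shannon entropy (nats) of a 0/1 profile, ignoring missing entries."""
    x = np.asarray(profile)
    x = x[x != MISSING]
    if x.size == 0:
        raise ContractError("profile has no observed entries")
    p1 = float(np.mean(x == 1))
    h = 0.0
    for p in (p1, 1.0 - p1):
        if p > 0.0:
            h -= p * math.log(p)
    return h


def mutual_information(a, b) -> float:
    """Empirical mutual information (nats) over jointly observed organisms.

    I(x, y) = sum_{x,y} p(x, y) log( p(x, y) / (p(x) p(y)) ), with marginals
    taken from the joint support; always in [0, min(H(a), H(b))].
    """
    x = np.asarray(a)
    y = np.asarray(b)
    if x.shape != y.shape:
        raise ContractError("profiles must have equal length")
    ok = (x != MISSING) & (y != MISSING)
    if not ok.any():
        raise ContractError("profiles share no jointly observed organism")
    x, y = x[ok], y[ok]
    n = x.size
    mi = 0.0
    for xv in (0, 1):
        px = float(np.mean(x == xv))
        for yv in (0, 1):
            pxy = float(np.mean((x == xv) & (y == yv)))
            py = float(np.mean(y == yv))
            if pxy > 0.0:
                mi += pxy * math.log(pxy / (px * py))
    return max(mi, 0.0)


def _single_tree_mp(
    forest: CoEvolvingForest, fam: int, forced: dict[int, int] | None = None
) -> float:
    """Weighted-parsimony optimum of one family's tree, ignoring co-evolution.

    ``forced`` overrides leaf labels by node id (values 0/1, or MISSING to
    free a leaf).
    """
    forced = forced or {}
    topo = forest.topology
    N = topo.n_nodes
    C = np.zeros((N, 2))
    for v in range(N - 1, -1, -1):
        if topo.is_leaf(v):
            lab = forced.get(v, forest.observed_leaf(fam, v))
            if lab != MISSING:
                C[v, 1 - lab] = np.inf
        else:
            cost = np.zeros(2)
            for c in topo.children[v]:
                w = forest.tree_table(fam, c).as_array()
                cost += np.min(w + C[c][None, :], axis=1)
            C[v] = cost
    return float(C[0].min())


def tree_signal(forest: CoEvolvingForest, fam: int, target_organism: int) -> float:
    """How strongly one family's tree determines its target-leaf value.

    Computes the tree's parsimony optimum with the target leaf forced to 0
    (MP0) and to 1 (MP1) and returns |MP0 - MP1| / min(MP0, MP1).  When the
    minimum is 0: returns inf if MP0 != MP1 (the tree decides the leaf for
    free) and 0 if MP0 == MP1 (no signal).
    """
    leaf = forest.topology.leaf_ids[target_organism]
    mp0 = _single_tree_mp(forest, fam, {leaf: 0})
    mp1 = _single_tree_mp(forest, fam, {leaf: 1})
    lo = min(mp0, mp1)
    if lo == 0.0:
        return math.inf if mp0 != mp1 else 0.0
    return abs(mp0 - mp1) / lo


def _tree_preference(forest: CoEvolvingForest, fam: int, target_organism: int) -> int:
    """Tree-only prediction for the target leaf: the cheaper forced state (ties -> 0)."""
    leaf = forest.topology.leaf_ids[target_organism]
    mp0 = _single_tree_mp(forest, fam, {leaf: 0})
    mp1 = _single_tree_mp(forest, fam, {leaf: 1})
    return 0 if mp0 <= mp1 else 1


@dataclass
class DcesGraph:
    """Coverage graph: per-family entropy, tree weights, and pairwise MI."""

    families: list[str]
    H: np.ndarray  # (F,)
    W: np.ndarray  # (F,) tree-signal weights, may contain inf
    MI: np.ndarray  # (F, F) symmetric, zero where no edge
    target_organism: int

    @property
    def n_families(self) -> int:
        return len(self.families)


@dataclass
class DominantSetResult:
    """Selected set, per-family coverage justification, and imputation output."""

    ds: list[str]
    coverage: dict[str, dict]
    w1: float
    w2: float
    imputed: dict[str, int] = field(default_factory=dict)
    error_rate: float | None = None
    coevo_usage: float | None = None
    converged: bool = True
    score_trace: list[float] = field(default_factory=list)


def build_dces_graph(
    forest: CoEvolvingForest,
    target_organism: int,
    mi_floor: float = 0.05,
) -> DcesGraph:
    """Entropies, MI edges, and tree weights for the coverage graph.

    Profiles exclude the target organism's column, so hidden target values
    never leak into the coverage statistics.  MI edges follow the forest's
    declared co-evolving pairs; when the forest declares none, every pair
    with MI >= ``mi_floor`` gets an edge.
    """
    if not 0 <= target_organism < forest.topology.n_leaves:
        raise InputError(f"no organism with index {target_organism}")
    F = forest.n_families
    cols = np.arange(forest.topology.n_leaves) != target_organism
    profiles = forest.leaf_labels[:, cols]
    H = np.array([entropy(profiles[f]) for f in range(F)])
    MI = np.zeros((F, F))
    pairs = forest.coevo_pairs()
    if not pairs:
        pairs = [
            (i, j)
            for i in range(F)
            for j in range(i + 1, F)
            if mutual_information(profiles[i], profiles[j]) >= mi_floor
        ]
    for i, j in pairs:
        mi = mutual_information(profiles[i], profiles[j])
        MI[i, j] = MI[j, i] = mi
    W = np.array([tree_signal(forest, f, target_organism) for f in range(F)])
    return DcesGraph(
        families=list(forest.families), H=H, W=W, MI=MI, target_organism=target_organism
    )


def residuals(graph: DcesGraph, ds_mask: np.ndarray) -> np.ndarray:
    """H(F_i) - sum of MI from i to set members other than i, for every i."""
    # the MI diagonal is zero, so i's own membership never counts toward i
    return graph.H - (graph.MI * ds_mask[None, :]).sum(axis=1)


def select_dominant_set(
    graph: DcesGraph,
    w1: float,
    w2: float,
    criterion: str = "max_residual",
) -> DominantSetResult:
    """Greedy shrink from the full set under the two coverage thresholds.

    Starting from all families, repeatedly remove the family whose removal
    keeps every outside family covered (residual < ``w1`` or tree weight
    > ``w2``) and scores best under ``criterion``:

    - ``max_residual``: minimize the resulting maximum residual over
      outside families lacking tree coverage (default);
    - ``sum_residual``: minimize the resulting residual sum over those
      families (slower, sometimes more accurate).

    Stops when no family can be removed without breaking coverage.
    """
    if criterion not in ("max_residual", "sum_residual"):
        raise ContractError(f"unknown criterion {criterion!r}")
    F = graph.n_families
    ds = np.ones(F, dtype=bool)
    tree_cov = graph.W > w2
    resid = residuals(graph, ds)
    while ds.any():
        outside = ~ds
        # residual of i after removing candidate j: resid[i] + MI[i, j]
        after = resid[:, None] + graph.MI
        uncovered_after = (~tree_cov)[:, None] & (after >= w1)
        feasible = np.array(
            [
                ds[j]
                and not uncovered_after[outside, j].any()
                and (tree_cov[j] or resid[j] < w1)
                for j in range(F)
            ]
        )
        if not feasible.any():
            break
        needy = outside & ~tree_cov
        if criterion == "max_residual":
            scores = np.where(
                needy[:, None], after, -np.inf
            ).max(axis=0)
            self_term = np.where(~tree_cov, resid, -np.inf)
            scores = np.maximum(scores, self_term)
        else:
            scores = np.where(needy[:, None], after, 0.0).sum(axis=0)
            scores = scores + np.where(~tree_cov, resid, 0.0)
        scores = np.where(feasible, scores, np.inf)
        j = int(np.argmin(scores))
        ds[j] = False
        resid = resid + graph.MI[:, j]
    ds_ids = [graph.families[f] for f in range(F) if ds[f]]
    coverage = {}
    final_resid = residuals(graph, ds)
    for f in range(F):
        if ds[f]:
            continue
        entry: dict = {}
        if final_resid[f] < w1:
            entry["mi_covered"] = True
            entry["residual"] = float(final_resid[f])
        if tree_cov[f]:
            entry["tree_covered"] = True
            entry["tree_weight"] = float(graph.W[f])
        coverage[graph.families[f]] = entry
    return DominantSetResult(ds=ds_ids, coverage=coverage, w1=w1, w2=w2)


def default_w1(graph: DcesGraph) -> float:
    """A W1 that accepts strong-MI coverage but rejects uncovered families.

    Half the median entropy: a family whose set neighbours explain at least
    half of its uncertainty counts as MI-covered.
    """
    return 0.5 * float(np.median(graph.H))


def sweep_w2_for_size(
    graph: DcesGraph,
    target_fraction: float,
    w1: float | None = None,
    iters: int = 20,
) -> DominantSetResult:
    """Binary-search W2 so the selected set is close to a target size fraction.

    W1 stays fixed (default :func:`default_w1`) so MI coverage keeps its
    meaning; a smaller W2 declares more families tree-covered and shrinks
    the set.  Returns the probed result whose size fraction is nearest the
    target.
    """
    if w1 is None:
        w1 = default_w1(graph)
    finite_w = graph.W[np.isfinite(graph.W)]
    lo = -1.0
    hi = float(finite_w.max()) + 1.0 if finite_w.size else 1.0
    best = None
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        res = select_dominant_set(graph, w1, mid)
        frac = len(res.ds) / graph.n_families
        if best is None or abs(frac - target_fraction) < abs(
            len(best.ds) / graph.n_families - target_fraction
        ):
            best = res
        if frac > target_fraction:
            hi = mid  # set too big -> declare more families tree-covered
        else:
            lo = mid
    return best


def impute_target(
    forest: CoEvolvingForest,
    target_organism: int,
    ds: DominantSetResult,
    graph: DcesGraph | None = None,
    solver=None,
    tol: float = 1e-6,
    max_iter: int = 50,
    truth: dict[str, int] | None = None,
) -> DominantSetResult:
    """Fill in the target genome's non-set entries by iterated ACE solving.

    ``forest`` must have the target organism's non-set entries missing (see
    ``simulate.mask_genome``).  The initial guess per imputed family is the
    tree-preferred state when its tree weight exceeds ``ds.w2``, else the
    MI-weighted majority vote of its set neighbours' observed values.  Each
    round solves the whole forest with the guesses treated as observed,
    then flips any imputed value that lowers the score given the inferred
    ancestral labels, until the score change drops below ``tol``
    (relative) or ``max_iter`` rounds pass.

    With ``truth`` given, reports the imputation error rate over all
    imputed sites and the fraction whose final value departs from the
    tree-only prediction (co-evolution usage).
    """
    if solver is None:
        solver = lambda f: fpt_heuristic(f, max_component=10)  # noqa: E731
    if graph is None:
        graph = build_dces_graph(forest, target_organism)
    fam_index = {fam: f for f, fam in enumerate(forest.families)}
    ds_set = set(ds.ds)
    imputed_fams = [fam for fam in forest.families if fam not in ds_set]
    leaf_col = target_organism
    leaf_node = forest.topology.leaf_ids[target_organism]
    for fam in imputed_fams:
        if forest.leaf_labels[fam_index[fam], leaf_col] != MISSING:
            raise ContractError(
                f"family {fam!r} is outside the set but its target entry is observed"
            )

    out = DominantSetResult(ds=list(ds.ds), coverage=dict(ds.coverage), w1=ds.w1, w2=ds.w2)
    if not imputed_fams:
        out.error_rate = 0.0
        out.coevo_usage = 0.0
        return out

    tree_pref = {
        fam: _tree_preference(forest, fam_index[fam], target_organism)
        for fam in imputed_fams
    }
    ds_rows = np.array([fam_index[fam] for fam in ds.ds], dtype=int)
    guesses: dict[str, int] = {}
    for fam in imputed_fams:
        f = fam_index[fam]
        if graph.W[f] > ds.w2:
            guesses[fam] = tree_pref[fam]
            continue
        votes = np.zeros(2)
        for k in ds_rows:
            val = forest.leaf_labels[k, leaf_col]
            if val != MISSING and graph.MI[f, k] > 0:
                votes[val] += graph.MI[f, k]
        if votes[0] == votes[1]:
            guesses[fam] = tree_pref[fam]
        else:
            guesses[fam] = int(np.argmax(votes))

    prev_score = math.inf
    converged = False
    trace: list[float] = []
    work = forest
    for _ in range(max_iter):
        labels = work.leaf_labels.copy()
        for fam, val in guesses.items():
            labels[fam_index[fam], leaf_col] = val
        work = CoEvolvingForest(
            topology=forest.topology,
            families=list(forest.families),
            leaf_labels=labels,
            tree_tables=dict(forest.tree_tables),
            coevo_tables=dict(forest.coevo_tables),
            default_tree_table=forest.default_tree_table,
        )
        res = solver(work)
        full = res.labeling.labels.copy()
        # local flips of the imputed leaf entries, ancestral labels fixed
        improved = True
        while improved:
            improved = False
            for fam in imputed_fams:
                f = fam_index[fam]
                cur = int(full[f, leaf_node])
                d = _leaf_flip_delta(forest, full, f, leaf_node)
                if d < -1e-12:
                    full[f, leaf_node] = 1 - cur
                    improved = True
        for fam in imputed_fams:
            guesses[fam] = int(full[fam_index[fam], leaf_node])
        score = ace_score(forest_with(forest, guesses, fam_index, leaf_col), FullLabeling(full))
        trace.append(score)
        if abs(prev_score - score) < tol * max(1.0, abs(score)):
            converged = True
            break
        prev_score = score

    out.imputed = dict(guesses)
    out.converged = converged
    out.score_trace = trace
    if truth is not None:
        errs = [fam for fam in imputed_fams if guesses[fam] != truth[fam]]
        out.error_rate = len(errs) / len(imputed_fams)
        out.coevo_usage = (
            sum(1 for fam in imputed_fams if guesses[fam] != tree_pref[fam])
            / len(imputed_fams)
        )
    return out


def forest_with(
    forest: CoEvolvingForest,
    guesses: dict[str, int],
    fam_index: dict[str, int],
    leaf_col: int,
) -> CoEvolvingForest:
    """Forest copy with imputed target values written in as observations."""
    labels = forest.leaf_labels.copy()
    for fam, val in guesses.items():
        labels[fam_index[fam], leaf_col] = val
    return CoEvolvingForest(
        topology=forest.topology,
        families=list(forest.families),
        leaf_labels=labels,
        tree_tables=dict(forest.tree_tables),
        coevo_tables=dict(forest.coevo_tables),
        default_tree_table=forest.default_tree_table,
    )


def _leaf_flip_delta(forest: CoEvolvingForest, labels: np.ndarray, f: int, v: int) -> float:
    old = int(labels[f, v])
    new = 1 - old
    delta = 0.0
    p = int(forest.topology.parent[v])
    if p >= 0:
        t = forest.tree_table(f, v).as_array()
        delta += t[labels[f, p], new] - t[labels[f, p], old]
    for (i, j), table in forest.coevo_tables.items():
        if i == f:
            t = table.as_array()
            delta += t[new, labels[j, v]] - t[old, labels[j, v]]
        elif j == f:
            t = table.as_array()
            delta += t[labels[i, v], new] - t[labels[i, v], old]
    return float(delta)
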