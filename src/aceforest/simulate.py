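"""Seeded generator of co-evolving forests with known ground truth.

Families evolve 0/1 states root-to-leaves along a shared random topology
with a constant per-branch flip probability.  Coupled family pairs evolve
jointly: the second member copies (or anti-copies) the first with the
coupling strength as the copy probability, and otherwise mutates from its
own parent state.  Co-evolution tables are the -log of the kernel's exact
stationary joint distribution; tree tables are the -log of the stay/flip
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, InputError
from .forest import MISSING, CoEvolvingForest, FullLabeling, Topology
from .tables import WeightTable, table_from_joint

__all__ = ["SimulationConfig", "simulate_forest", "mask_genome", "random_topology"]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic forest.

    ``coupled_pairs`` maps ordered family-index pairs (i < j) to
    (strength in [0, 1], sign), sign ``+1`` for correlated and ``-1`` for
    anti-correlated evolution.  ``n_couples``/``coupling_strength``/
    ``coupling_sign`` instead draw that many disjoint random pairs.
    """

    n_organisms: int
    n_families: int
    n_couples: int = 0
    coupling_strength: float = 0.8
    coupling_sign: int = 1
    coupled_pairs: dict[tuple[int, int], tuple[float, int]] | None = None
    flip_prob: float = 0.1
    root_presence_prob: float = 0.5
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coupling_strength", "flip_prob", "root_presence_prob", "missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name}={v} must be in [0, 1]")
        if self.coupling_sign not in (-1, 1):
            raise ContractError("coupling_sign must be +1 or -1")
        if self.n_organisms < 2 or self.n_families < 1:
            raise ContractError("need >= 2 organisms and >= 1 family")
        if self.coupled_pairs is not None:
            seen: set[int] = set()
            for (i, j), (s, sign) in self.coupled_pairs.items():
                if not (0 <= i < j < self.n_families):
                    raise ContractError(f"bad coupled pair ({i}, {j})")
                if i in seen or j in seen:
                    raise ContractError("coupled pairs must be disjoint")
                seen.update((i, j))
                if not 0.0 <= s <= 1.0 or sign not in (-1, 1):
                    raise ContractError("bad coupling strength/sign")
        elif 2 * self.n_couples > self.n_families:
            raise ContractError(
                f"{self.n_couples} disjoint couples need >= {2 * self.n_couples} families"
            )



def random_topology(n_organisms: int, rng: np.random.Generator) -> Topology:
    """Uniform random rooted binary tree via coalescent-style pair joins."""
    labels = [f"org{i}" for i in range(n_organisms)]
    # build (children, name) records bottom-up, then renumber in preorder
    nodes: list[tuple[list[int], str]] = [([], lab) for lab in labels]
    active = list(range(n_organisms))
    while len(active) > 1:
        a_pos, b_pos = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[a_pos], active[b_pos]
        nodes.append(([a, b], ""))
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]
    root = active[0]
    parent: list[int] = []
    names: list[str] = []
    order: list[int] = []

    def walk(old: int, par: int) -> None:
        new = len(order)
        order.append(old)
        parent.append(par)
        ch, nm = nodes[old]
        names.append(nm if nm else f"n{new}")
        for c in ch:
            walk(c, new)

    walk(root, -1)
    return Topology(parent, names)


def _stationary_joint(s: float, sign: int, p: float) -> np.ndarray:
    """Stationary joint distribution of a coupled pair's states at a node.

    The driven family copies (sign=+1) or anti-copies (sign=-1) its driver
    with probability s per branch and otherwise mutates from its own parent
    with flip probability p.  With symmetric flips both marginals are
    uniform, so the joint is determined by the stationary agreement
    probability a*, the fixed point of

        a' = s + (1 - s) * (a q + (1 - a) r),
        q = p^2 + (1-p)^2,  r = 2 p (1-p),

    (for sign=-1 'agreement' means opposite states).
    """
    q = p * p + (1 - p) * (1 - p)
    r = 2 * p * (1 - p)
    denom = 1.0 - (1 - s) * (q - r)
    a = (s + (1 - s) * r) / denom if denom > 0 else 1.0
    if sign == 1:
        return np.array([[a / 2, (1 - a) / 2], [(1 - a) / 2, a / 2]])
    return np.array([[(1 - a) / 2, a / 2], [a / 2, (1 - a) / 2]])


def _pick_pairs(config: SimulationConfig, rng: np.random.Generator):
    if config.coupled_pairs is not None:
        return dict(config.coupled_pairs)
    fams = rng.permutation(config.n_families)[: 2 * config.n_couples]
    pairs = {}
    for k in range(config.n_couples):
        i, j = sorted((int(fams[2 * k]), int(fams[2 * k + 1])))
        pairs[(i, j)] = (config.coupling_strength, config.coupling_sign)
    return pairs


def simulate_forest(config: SimulationConfig) -> tuple[CoEvolvingForest, FullLabeling]:
    """Sample a forest plus its ground-truth labeling; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    topo = random_topology(config.n_organisms, rng)
    pairs = _pick_pairs(config, rng)
    F, N = config.n_families, topo.n_nodes
    p = config.flip_prob
    truth = np.zeros((F, N), dtype=np.int8)

    driven = {j: (i, s, sign) for (i, j), (s, sign) in pairs.items()}
    for f in range(F):
        if f in driven:
            continue  # filled when its driver is evolved
        truth[f, 0] = rng.random() < config.root_presence_prob
        for v in range(1, N):
            par = int(topo.parent[v])
            flip = rng.random() < p
            truth[f, v] = truth[f, par] ^ flip
    for (i, j), (s, sign) in sorted(pairs.items()):
        # the driven family copies (or anti-copies) its driver with prob s,
        # else mutates from its own parent state
        if rng.random() < s:
            truth[j, 0] = truth[i, 0] if sign == 1 else 1 - truth[i, 0]
        else:
            truth[j, 0] = rng.random() < config.root_presence_prob
        for v in range(1, N):
            if rng.random() < s:
                truth[j, v] = truth[i, v] if sign == 1 else 1 - truth[i, v]
            else:
                par = int(topo.parent[v])
                truth[j, v] = truth[j, par] ^ (rng.random() < p)

    # tree tables: -log of stay/flip probabilities, shared by every edge
    stay, flip = -np.log(max(1 - p, 1e-12)), -np.log(max(p, 1e-12))
    tree_table = WeightTable(stay, flip, flip, stay)

    coevo_tables = {}
    for (i, j) in sorted(pairs):
        s, sign = pairs[(i, j)]
        coevo_tables[(i, j)] = table_from_joint(_stationary_joint(s, sign, p))

    leaf_labels = truth[:, topo.leaf_ids].copy()
    if config.missing_fraction > 0:
        mask = rng.random(leaf_labels.shape) < config.missing_fraction
        leaf_labels[mask] = MISSING

    forest = CoEvolvingForest(
        topology=topo,
        families=[f"fam{f}" for f in range(F)],
        leaf_labels=leaf_labels,
        coevo_tables=coevo_tables,
        default_tree_table=tree_table,
    )
    return forest, FullLabeling(truth)


def mask_genome(
    forest: CoEvolvingForest, target_organism: int, keep: set[str]
) -> CoEvolvingForest:
    """Copy of the forest with the target organism's entries outside ``keep`` hidden."""
    unknown = keep - set(forest.families)
    if unknown:
        raise InputError(f"unknown family ids in keep: {sorted(unknown)}")
    if not 0 <= target_organism < forest.topology.n_leaves:
        raise InputError(f"no organism with index {target_organism}")
    labels = forest.leaf_labels.copy()
    for f, fam in enumerate(forest.families):
        if fam not in keep:
            labels[f, target_organism] = MISSING
    return CoEvolvingForest(
        topology=forest.topology,
        families=list(forest.families),
        leaf_labels=labels,
        tree_tables=dict(forest.tree_tables),
        coevo_tables=dict(forest.coevo_tables),
        default_tree_table=forest.default_tree_table,
    )
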