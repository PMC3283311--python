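"""Shared builders for randomized test instances."""

from __future__ import annotations

import numpy as np

from aceforest.forest import MISSING, CoEvolvingForest, Topology
from aceforest.simulate import random_topology
from aceforest.tables import GREEN_TABLE, RED_TABLE, WeightTable


def two_leaf_topology() -> Topology:
    """Root with two leaf children: the smallest non-trivial binary tree."""
    return Topology([-1, 0, 0], ["root", "A", "B"])


def single_node_topology(name: str = "A") -> Topology:
    """A one-node tree (the root is its only leaf)."""
    return Topology([-1], [name])


def random_table(rng: np.random.Generator) -> WeightTable:
    return WeightTable(*rng.uniform(0.0, 3.0, size=4))


def random_green_table(rng: np.random.Generator) -> WeightTable:
    a = float(rng.uniform(0.2, 3.0))
    return WeightTable(0.0, a, a, 0.0)


def random_red_table(rng: np.random.Generator) -> WeightTable:
    a = float(rng.uniform(0.2, 3.0))
    return WeightTable(a, 0.0, 0.0, a)


def random_forest(
    rng: np.random.Generator,
    max_trees: int = 3,
    max_leaves: int = 6,
    kind: str = "mixed",
    missing_frac: float = 0.2,
    coevo_prob: float = 0.7,
) -> CoEvolvingForest:
    """A small random forest with the requested table flavour.

    kind: 'mixed' (arbitrary non-negative tables), 'green' ((0,a,a,0) only),
    'red' ((a,0,0,a) only), or 'unit' (all tables (0,1,1,0)).
    """
    n_trees = int(rng.integers(1, max_trees + 1))
    n_leaves = int(rng.integers(2, max_leaves + 1))
    topo = random_topology(n_leaves, rng)
    makers = {
        "mixed": lambda: random_table(rng),
        "green": lambda: random_green_table(rng),
        "red": lambda: random_red_table(rng),
        "unit": lambda: GREEN_TABLE,
    }
    make = makers[kind]
    labels = rng.integers(0, 2, size=(n_trees, n_leaves)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(labels.shape) < missing_frac
        labels[mask] = MISSING
    tree_tables = {
        (f, c): make() for f in range(n_trees) for _, c in topo.edges()
    }
    coevo = {}
    for i in range(n_trees):
        for j in range(i + 1, n_trees):
            if rng.random() < coevo_prob:
                coevo[(i, j)] = make()
    return CoEvolvingForest(
        topology=topo,
        families=[f"fam{t}" for t in range(n_trees)],
        leaf_labels=labels,
        tree_tables=tree_tables,
        coevo_tables=coevo,
    )


def red_triangle_forest() -> CoEvolvingForest:
    """Three single-node trees whose red co-evolution edges form an odd cycle."""
    topo = single_node_topology()
    return CoEvolvingForest(
        topology=topo,
        families=["x", "y", "z"],
        leaf_labels=np.full((3, 1), MISSING, dtype=np.int8),
        coevo_tables={(0, 1): RED_TABLE, (0, 2): RED_TABLE, (1, 2): RED_TABLE},
        default_tree_table=RED_TABLE,
    )


def red_only_forest(rng: np.random.Generator, max_nodes: int = 12) -> CoEvolvingForest:
    """A random forest whose tables are all of the red form, <= max_nodes nodes."""
    while True:
        n_trees = int(rng.integers(2, 4))
        n_leaves = int(rng.integers(2, 4))
        topo = random_topology(n_leaves, rng)
        if n_trees * topo.n_nodes <= max_nodes:
            break
    labels = rng.integers(0, 2, size=(n_trees, n_leaves)).astype(np.int8)
    mask = rng.random(labels.shape) < 0.5
    labels[mask] = MISSING
    coevo = {}
    for i in range(n_trees):
        for j in range(i + 1, n_trees):
            if rng.random() < 0.6:
                coevo[(i, j)] = random_red_table(rng)
    return CoEvolvingForest(
        topology=topo,
        families=[f"fam{t}" for t in range(n_trees)],
        leaf_labels=labels,
        tree_tables={
            (f, c): random_red_table(rng) for f in range(n_trees) for _, c in topo.edges()
        },
        coevo_tables=coevo,
    )
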