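"""Core data model: shared tree topology, co-evolving forests, labelings, scoring.

A co-evolving forest is a set of trees (one per gene family) that share a
single rooted binary topology over the same organisms, plus co-evolution
edges linking every legal node pair of selected family pairs.  A node pair
is *legal* when the two nodes occupy the same position in the shared
topology, i.e. correspond to the same (extant or ancestral) organism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConsistencyError, ContractError, InputError
from .tables import GREEN_TABLE, WeightTable

__all__ = [
    "Topology",
    "CoEvolvingForest",
    "FullLabeling",
    "ace_score",
    "build_coevolutionary_graph",
    "MISSING",
]

#: Sentinel for a missing leaf label in profile arrays.
MISSING = -1


class Topology:
    """A rooted binary tree over named nodes, ids in preorder (root = 0).

    Parameters
    ----------
    parent : sequence of int
        ``parent[i]`` is the parent id of node i, and -1 for the root.
        Ids must be a preorder: every non-root has ``parent[i] < i``.
    names : sequence of str
        Unique node names; leaf names double as organism names.
    """

    def __init__(self, parent, names) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.names = list(names)
        n = len(self.parent)
        if len(self.names) != n:
            raise InputError("names and parent arrays differ in length")
        if len(set(self.names)) != n:
            raise InputError("node names must be unique")
        if n == 0 or self.parent[0] != -1 or (self.parent[1:] < 0).any():
            raise InputError("node 0 must be the unique root")
        self.children: list[tuple[int, ...]] = [() for _ in range(n)]
        for v in range(1, n):
            p = int(self.parent[v])
            if not 0 <= p < v:
                raise InputError(f"parent of node {v} must precede it in preorder")
            self.children[p] = self.children[p] + (v,)
        for v, ch in enumerate(self.children):
            if len(ch) not in (0, 2):
                raise InputError(
                    f"node {self.names[v]!r} has {len(ch)} children; tree must be binary"
                )
        self.leaf_ids = [v for v in range(n) if not self.children[v]]
        self.leaf_index = {v: i for i, v in enumerate(self.leaf_ids)}
        self.organisms = [self.names[v] for v in self.leaf_ids]
        self.name_to_id = {nm: v for v, nm in enumerate(self.names)}

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def edges(self) -> list[tuple[int, int]]:
        """Tree edges as (parent, child) pairs, ordered by child id."""
        return [(int(self.parent[v]), v) for v in range(1, self.n_nodes)]

    def postorder(self) -> list[int]:
        return sorted(range(self.n_nodes), reverse=True)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @classmethod
    def from_newick(cls, newick: str) -> "Topology":
        """Parse a rooted binary tree from a Newick string.

        Unnamed internal nodes are auto-named ``n<preorder index>``.
        """
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(tree.preorder_node_iter())
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        parent = []
        names = []
        for i, nd in enumerate(nodes):
            parent.append(-1 if nd.parent_node is None else ids[id(nd.parent_node)])
            label = nd.taxon.label if nd.taxon is not None else nd.label
            names.append(label if label else f"n{i}")
        return cls(parent, names)

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if self.is_leaf(v):
                return self.names[v]
            a, b = self.children[v]
            return f"({render(a)},{render(b)}){self.names[v]}"

        return render(0) + ";"


@dataclass
class CoEvolvingForest:
    """Trees with one shared topology, leaf profiles, and co-evolution edges.

    Attributes
    ----------
    topology : Topology
        Shared rooted binary topology.
    families : list of str
        Family (tree) identifiers; the i-th row of ``leaf_labels`` belongs
        to ``families[i]``.
    leaf_labels : ndarray of shape (n_families, n_leaves)
        Entries 0, 1, or ``MISSING`` (-1); columns follow
        ``topology.leaf_ids`` order.
    tree_tables : dict[(family index, child node id) -> WeightTable]
        Sparse overrides; absent entries default to ``default_tree_table``.
    coevo_tables : dict[(i, j) -> WeightTable]
        One table per co-evolving family pair, i < j; applied at every node
        of the shared topology, indexed (label of tree i, label of tree j).
    """

    topology: Topology
    families: list[str]
    leaf_labels: np.ndarray
    tree_tables: dict[tuple[int, int], WeightTable] = field(default_factory=dict)
    coevo_tables: dict[tuple[int, int], WeightTable] = field(default_factory=dict)
    default_tree_table: WeightTable = GREEN_TABLE

    def __post_init__(self) -> None:
        self.leaf_labels = np.asarray(self.leaf_labels, dtype=np.int8)
        F = len(self.families)
        if len(set(self.families)) != F:
            raise InputError("family ids must be unique")
        if self.leaf_labels.shape != (F, self.topology.n_leaves):
            raise InputError(
                f"leaf_labels shape {self.leaf_labels.shape} does not match "
                f"({F}, {self.topology.n_leaves})"
            )
        bad = ~np.isin(self.leaf_labels, (0, 1, MISSING))
        if bad.any():
            raise InputError("leaf labels must be 0, 1, or missing (-1)")
        for (i, j) in self.coevo_tables:
            if not (0 <= i < j < F):
                raise InputError(f"co-evolving pair ({i}, {j}) is not ordered/in range")

    # -- structural accessors -------------------------------------------------

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_nodes(self) -> int:
        return self.topology.n_nodes

    def tree_table(self, fam: int, child: int) -> WeightTable:
        return self.tree_tables.get((fam, child), self.default_tree_table)

    def coevo_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.coevo_tables)

    def n_forest_nodes(self) -> int:
        """|V(S_F)|: total nodes over all trees."""
        return self.n_families * self.n_nodes

    def n_forest_edges(self) -> int:
        """|E(S_F)|: tree edges plus co-evolution edges over all legal pairs."""
        return self.n_families * (self.n_nodes - 1) + len(self.coevo_tables) * self.n_nodes

    def observed_leaf(self, fam: int, node: int) -> int:
        """Leaf label of ``node`` in tree ``fam`` (0/1/MISSING); node must be a leaf."""
        return int(self.leaf_labels[fam, self.topology.leaf_index[node]])

    def free_slots(self) -> list[tuple[int, int]]:
        """Unconstrained (family, node) slots: internal nodes and missing leaves,
        in (family, preorder node) order."""
        out = []
        for f in range(self.n_families):
            for v in range(self.n_nodes):
                if self.topology.is_leaf(v):
                    if self.observed_leaf(f, v) == MISSING:
                        out.append((f, v))
                else:
                    out.append((f, v))
        return out

    def fixed_slots(self) -> list[tuple[int, int, int]]:
        """Observed (family, leaf node, label) triples."""
        out = []
        for f in range(self.n_families):
            for v in self.topology.leaf_ids:
                lab = self.observed_leaf(f, v)
                if lab != MISSING:
                    out.append((f, v, lab))
        return out


class FullLabeling:
    """A 0/1 assignment to every node of every tree of a forest.

    Backed by an ``(n_families, n_nodes)`` int8 array; supports
    ``labeling[fam, node]`` access.
    """

    def __init__(self, labels: np.ndarray) -> None:
        self.labels = np.asarray(labels, dtype=np.int8)

    def __getitem__(self, key: tuple[int, int]) -> int:
        return int(self.labels[key])

    def __eq__(self, other) -> bool:
        return isinstance(other, FullLabeling) and np.array_equal(self.labels, other.labels)

    def copy(self) -> "FullLabeling":
        return FullLabeling(self.labels.copy())

    @classmethod
    def from_free_assignment(
        cls, forest: CoEvolvingForest, assignment: dict[tuple[int, int], int]
    ) -> "FullLabeling":
        """Build a labeling from observed leaves plus values for all free slots."""
        labels = np.zeros((forest.n_families, forest.n_nodes), dtype=np.int8)
        for f, v, lab in forest.fixed_slots():
            labels[f, v] = lab
        for (f, v) in forest.free_slots():
            if (f, v) not in assignment:
                raise ContractError(f"free slot ({f}, {v}) missing from assignment")
            labels[f, v] = assignment[(f, v)]
        return cls(labels)

    def validate(self, forest: CoEvolvingForest) -> None:
        if self.labels.shape != (forest.n_families, forest.n_nodes):
            raise ContractError(
                f"labeling shape {self.labels.shape} does not cover all "
                f"({forest.n_families}, {forest.n_nodes}) nodes"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ContractError("labeling entries must be 0 or 1")
        for f, v, lab in forest.fixed_slots():
            if self.labels[f, v] != lab:
                raise ConsistencyError(
                    f"labeling contradicts observed leaf {forest.topology.names[v]!r} "
                    f"of family {forest.families[f]!r}: {self.labels[f, v]} != {lab}"
                )


def ace_score(forest: CoEvolvingForest, labeling: FullLabeling) -> float:
    """Total weight of a full labeling: tree-edge costs plus co-evolution costs.

    The sum runs over every tree edge of every family, table indexed
    (parent label, child label), and over every co-evolution edge — i.e.
    every node of the shared topology for each co-evolving family pair.
    """
    labeling.validate(forest)
    L = labeling.labels
    total = 0.0
    arr_cache: dict[int, np.ndarray] = {}

    def arr(table: WeightTable) -> np.ndarray:
        a = arr_cache.get(id(table))
        if a is None:
            a = table.as_array()
            arr_cache[id(table)] = a
        return a

    edges = forest.topology.edges()
    for f in range(forest.n_families):
        for p, c in edges:
            total += arr(forest.tree_table(f, c))[L[f, p], L[f, c]]
    for (i, j), table in forest.coevo_tables.items():
        total += float(arr(table)[L[i], L[j]].sum())
    return float(total)


def build_coevolutionary_graph(forest: CoEvolvingForest) -> nx.Graph:
    """One vertex per tree; an edge per co-evolving family pair."""
    g = nx.Graph()
    g.add_nodes_from(range(forest.n_families))
    g.add_edges_from(forest.coevo_tables)
    return g
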