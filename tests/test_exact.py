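import numpy as np
import pytest

from aceforest.errors import SizeCapError
from aceforest.exact import brute_force_optimum, component_dp, fpt_red_edges
from aceforest.forest import MISSING, CoEvolvingForest, FullLabeling, Topology, ace_score
from aceforest.tables import GREEN_TABLE, RED_TABLE, WeightTable
from util import random_forest, two_leaf_topology


def quartet_topology():
    return Topology(
        [-1, 0, 1, 1, 0, 4, 4],
        ["r", "u", "A", "B", "v", "C", "D"],
    )


class TestBruteForce:
    def test_all_ones_costs_zero(self):
        f = CoEvolvingForest(
            topology=quartet_topology(),
            families=["a", "b"],
            leaf_labels=np.ones((2, 4), dtype=np.int8),
        )
        res = brute_force_optimum(f)
        assert res.cost == 0.0
        assert res.optimal
        assert np.all(res.labeling.labels == 1)

    def test_two_conflicting_leaves(self):
        f = CoEvolvingForest(
            topology=two_leaf_topology(),
            families=["a"],
            leaf_labels=np.array([[1, 0]], dtype=np.int8),
        )
        assert brute_force_optimum(f).cost == 1.0

    def test_cost_matches_ace_score(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            f = random_forest(rng)
            res = brute_force_optimum(f)
            assert ace_score(f, res.labeling) == pytest.approx(res.cost, abs=1e-9)

    def test_cap(self):
        f = CoEvolvingForest(
            topology=quartet_topology(),
            families=[f"f{i}" for i in range(12)],
            leaf_labels=np.ones((12, 4), dtype=np.int8),
        )
        with pytest.raises(SizeCapError):
            brute_force_optimum(f, cap=10)

    def test_tie_break_is_lexicographic(self):
        # free root with two equally good states must resolve to 0
        f = CoEvolvingForest(
            topology=two_leaf_topology(),
            families=["a"],
            leaf_labels=np.array([[1, 0]], dtype=np.int8),
        )
        res = brute_force_optimum(f)
        assert res.labeling[0, 0] == 0


class TestComponentDp:
    def test_fitch_quartet(self):
        f = CoEvolvingForest(
            topology=quartet_topology(),
            families=["a"],
            leaf_labels=np.array([[1, 1, 0, 0]], dtype=np.int8),
        )
        assert component_dp(f).cost == 1.0

    def test_factorizes_without_coevolution(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            f = random_forest(rng, coevo_prob=0.0)
            assert not f.coevo_tables
            total = component_dp(f).cost
            per_tree = 0.0
            for t in range(f.n_families):
                sub = CoEvolvingForest(
                    topology=f.topology,
                    families=[f.families[t]],
                    leaf_labels=f.leaf_labels[[t]],
                    tree_tables={(0, c): tab for (ft, c), tab in f.tree_tables.items() if ft == t},
                )
                per_tree += brute_force_optimum(sub).cost
            assert total == pytest.approx(per_tree, abs=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            f = random_forest(rng)
            assert component_dp(f).cost == pytest.approx(
                brute_force_optimum(f).cost, abs=1e-9
            )

    def test_labeling_scores_its_cost(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            f = random_forest(rng)
            res = component_dp(f)
            assert ace_score(f, res.labeling) == pytest.approx(res.cost, abs=1e-9)

    def test_state_cap(self):
        f = CoEvolvingForest(
            topology=two_leaf_topology(),
            families=[f"f{i}" for i in range(5)],
            leaf_labels=np.ones((5, 2), dtype=np.int8),
            coevo_tables={(i, j): GREEN_TABLE for i in range(5) for j in range(i + 1, 5)},
        )
        with pytest.raises(SizeCapError):
            component_dp(f, state_cap=8)


class TestMonotonicity:
    def test_adding_edge_never_decreases_optimum(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            f = random_forest(rng, max_trees=3, coevo_prob=0.3)
            base = component_dp(f).cost
            free_pairs = [
                (i, j)
                for i in range(f.n_families)
                for j in range(i + 1, f.n_families)
                if (i, j) not in f.coevo_tables
            ]
            if not free_pairs:
                continue
            pair = free_pairs[rng.integers(len(free_pairs))]
            coevo = dict(f.coevo_tables)
            coevo[pair] = WeightTable(*rng.uniform(0, 2, size=4))
            bigger = CoEvolvingForest(
                topology=f.topology,
                families=f.families,
                leaf_labels=f.leaf_labels,
                tree_tables=f.tree_tables,
                coevo_tables=coevo,
                default_tree_table=f.default_tree_table,
            )
            assert component_dp(bigger).cost >= base - 1e-9


class TestFptRedEdges:
    def test_no_red_edges_matches_mincut(self):
        from aceforest.cuts import solve_green_forest

        rng = np.random.default_rng(37)
        for _ in range(10):
            f = random_forest(rng, kind="green")
            fpt = fpt_red_edges(f)
            assert fpt.info["red_incident_free_nodes"] == 0
            assert fpt.info["enumerated"] == 1
            assert fpt.cost == pytest.approx(solve_green_forest(f).cost, abs=1e-9)

    def test_enumeration_count_scaling(self):
        # co-evolution-only scoring: r free nodes incident to red edges -> 2^r
        topo = two_leaf_topology()
        f = CoEvolvingForest(
            topology=topo,
            families=["a", "b"],
            leaf_labels=np.full((2, 2), MISSING, dtype=np.int8),
            coevo_tables={(0, 1): RED_TABLE},
        )
        res = fpt_red_edges(f)
        assert res.info["red_incident_free_nodes"] == 6
        assert res.info["enumerated"] == 2 ** 6

    def test_matches_brute_force_with_red_pair(self):
        rng = np.random.default_rng(41)
        checked = 0
        while checked < 15:
            f = random_forest(rng, kind="green", max_trees=2, max_leaves=4)
            if not f.coevo_tables:
                continue
            pair = next(iter(f.coevo_tables))
            coevo = dict(f.coevo_tables)
            coevo[pair] = RED_TABLE
            f = CoEvolvingForest(
                topology=f.topology,
                families=f.families,
                leaf_labels=f.leaf_labels,
                tree_tables=f.tree_tables,
                coevo_tables=coevo,
            )
            assert fpt_red_edges(f).cost == pytest.approx(
                brute_force_optimum(f).cost, abs=1e-9
            )
            checked += 1
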