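import math

import numpy as np
import pytest

from aceforest.dces import (
    build_dces_graph,
    default_w1,
    entropy,
    impute_target,
    mutual_information,
    residuals,
    select_dominant_set,
    sweep_w2_for_size,
    tree_signal,
)
from aceforest.errors import ContractError
from aceforest.forest import MISSING, CoEvolvingForest, Topology
from aceforest.simulate import SimulationConfig, mask_genome, simulate_forest


class TestEntropy:
    def test_constant_profile(self):
        assert entropy([1, 1, 1, 1]) == 0.0
        assert entropy([0, 0]) == 0.0

    def test_balanced_profile(self):
        assert entropy([0, 1, 0, 1]) == pytest.approx(math.log(2))

    def test_quarter_ones(self):
        expected = -0.25 * math.log(0.25) - 0.75 * math.log(0.75)
        assert entropy([1, 1, 0, 0, 0, 0, 0, 0]) == pytest.approx(expected)

    def test_ignores_missing(self):
        assert entropy([1, MISSING, 0, MISSING]) == pytest.approx(math.log(2))

    def test_all_missing_errors(self):
        with pytest.raises(ContractError):
            entropy([MISSING, MISSING])


class TestMutualInformation:
    def test_independent_profiles(self):
        a = [0, 0, 1, 1, 0, 0, 1, 1]
        b = [0, 1, 0, 1, 0, 1, 0, 1]
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_identical_balanced_profiles(self):
        a = [0, 1, 0, 1]
        assert mutual_information(a, a) == pytest.approx(math.log(2))

    def test_hand_computed_joint(self):
        # joint counts [[3,1],[1,3]] over 8 organisms
        a = [0, 0, 0, 0, 1, 1, 1, 1]
        b = [0, 0, 0, 1, 0, 1, 1, 1]
        expected = 2 * (3 / 8) * math.log((3 / 8) / 0.25) + 2 * (1 / 8) * math.log(
            (1 / 8) / 0.25
        )
        assert mutual_information(a, b) == pytest.approx(expected)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(157)
        for _ in range(50):
            a = rng.integers(0, 2, size=12)
            b = rng.integers(0, 2, size=12)
            ab = mutual_information(a, b)
            assert ab == pytest.approx(mutual_information(b, a), abs=1e-12)
            assert -1e-12 <= ab <= min(entropy(a), entropy(b)) + 1e-12

    def test_disjoint_support_errors(self):
        with pytest.raises(ContractError):
            mutual_information([1, MISSING], [MISSING, 0])


class TestTreeSignal:
    def _quartet(self, leaves):
        topo = Topology([-1, 0, 1, 1, 0, 4, 4], ["r", "u", "A", "B", "v", "C", "D"])
        return CoEvolvingForest(
            topology=topo,
            families=["f"],
            leaf_labels=np.array([leaves], dtype=np.int8),
        )

    def test_asymmetric_pattern(self):
        # target A with B=1, C=0, D=1: forcing A=1 costs 1, forcing A=0 costs 2
        f = self._quartet([MISSING, 1, 0, 1])
        assert tree_signal(f, 0, 0) == pytest.approx(1.0)

    def test_decided_leaf_is_infinite(self):
        f = self._quartet([MISSING, 1, 1, 1])
        assert tree_signal(f, 0, 0) == math.inf

    def test_symmetric_pattern_is_zero(self):
        # B=1, C=0 and D free: both forced states cost the same
        f = self._quartet([MISSING, 1, 0, MISSING])
        assert tree_signal(f, 0, 0) == pytest.approx(0.0)

    def test_matches_brute_force_parsimony(self):
        from aceforest.exact import brute_force_optimum

        rng = np.random.default_rng(163)
        for _ in range(10):
            cfg = SimulationConfig(n_organisms=6, n_families=1, seed=int(rng.integers(1e6)))
            f, _ = simulate_forest(cfg)
            leaf = f.topology.leaf_ids[0]
            for forced in (0, 1):
                labels = f.leaf_labels.copy()
                labels[0, 0] = forced
                sub = CoEvolvingForest(
                    topology=f.topology,
                    families=["f"],
                    leaf_labels=labels,
                    default_tree_table=f.default_tree_table,
                )
                from aceforest.dces import _single_tree_mp

                assert _single_tree_mp(f, 0, {leaf: forced}) == pytest.approx(
                    brute_force_optimum(sub).cost, abs=1e-9
                )


class TestDcesGraph:
    def test_structural_counts(self):
        cfg = SimulationConfig(n_organisms=6, n_families=3, seed=3)
        f, _ = simulate_forest(cfg)
        g = build_dces_graph(f, 0)
        assert g.n_families == 3
        assert g.H.shape == (3,) and g.W.shape == (3,) and g.MI.shape == (3, 3)

    def test_planted_duplicate_has_max_mi(self):
        cfg = SimulationConfig(
            n_organisms=12,
            n_families=6,
            coupled_pairs={(0, 1): (1.0, 1)},
            seed=5,
        )
        f, _ = simulate_forest(cfg)
        g = build_dces_graph(f, 0)
        profiles = f.leaf_labels[:, [c for c in range(12) if c != 0]]
        all_mi = {
            (i, j): mutual_information(profiles[i], profiles[j])
            for i in range(6)
            for j in range(i + 1, 6)
        }
        assert g.MI[0, 1] == pytest.approx(max(all_mi.values()))

    def test_residual_formula_is_literal(self):
        cfg = SimulationConfig(n_organisms=8, n_families=5, n_couples=2, seed=7)
        f, _ = simulate_forest(cfg)
        g = build_dces_graph(f, 0)
        mask = np.array([True, False, True, True, False])
        res = residuals(g, mask)
        for i in range(5):
            expected = g.H[i] - sum(g.MI[i, k] for k in range(5) if mask[k] and k != i)
            assert res[i] == pytest.approx(expected, abs=1e-12)


class TestSelectDominantSet:
    def _graph(self, seed=11):
        cfg = SimulationConfig(n_organisms=10, n_families=8, n_couples=3, seed=seed)
        f, _ = simulate_forest(cfg)
        return f, build_dces_graph(f, 0)

    def test_infinite_w1_empties_the_set(self):
        _, g = self._graph()
        res = select_dominant_set(g, math.inf, math.inf)
        assert res.ds == []

    def test_impossible_coverage_keeps_everything(self):
        _, g = self._graph()
        res = select_dominant_set(g, -math.inf, math.inf)
        assert sorted(res.ds) == sorted(g.families)

    def test_planted_twin_covers_partner(self):
        cfg = SimulationConfig(
            n_organisms=12,
            n_families=4,
            coupled_pairs={(0, 1): (1.0, 1)},
            seed=13,
        )
        f, _ = simulate_forest(cfg)
        g = build_dces_graph(f, 0)
        res = select_dominant_set(g, w1=0.01, w2=math.inf)
        names = {"fam0", "fam1"}
        assert len(names & set(res.ds)) == 1
        outside = (names - set(res.ds)).pop()
        assert res.coverage[outside].get("mi_covered")

    def test_coverage_soundness(self):
        for seed in range(5):
            f, g = self._graph(seed)
            w1, w2 = default_w1(g), float(np.median(g.W[np.isfinite(g.W)]))
            res = select_dominant_set(g, w1, w2)
            ds_mask = np.array([fam in set(res.ds) for fam in g.families])
            final = residuals(g, ds_mask)
            for i, fam in enumerate(g.families):
                if not ds_mask[i]:
                    assert final[i] < w1 or g.W[i] > w2

    def test_sum_residual_criterion_runs(self):
        _, g = self._graph()
        res = select_dominant_set(g, default_w1(g), math.inf, criterion="sum_residual")
        ds_mask = np.array([fam in set(res.ds) for fam in g.families])
        final = residuals(g, ds_mask)
        assert all(final[i] < default_w1(g) for i in range(len(g.families)) if not ds_mask[i])


class TestImputeTarget:
    def test_ds_equals_all_is_degenerate(self):
        cfg = SimulationConfig(n_organisms=8, n_families=4, seed=17)
        f, truth = simulate_forest(cfg)
        g = build_dces_graph(f, 0)
        res = select_dominant_set(g, -math.inf, math.inf)
        out = impute_target(f, 0, res, graph=g)
        assert out.imputed == {}
        assert out.error_rate == 0.0

    def test_perfect_twin_forces_agreement(self):
        cfg = SimulationConfig(
            n_organisms=10,
            n_families=4,
            coupled_pairs={(0, 1): (1.0, 1)},
            seed=19,
        )
        f, truth = simulate_forest(cfg)
        g = build_dces_graph(f, 0)
        sel = select_dominant_set(g, 0.01, math.inf)
        names = {"fam0", "fam1"}
        outside = (names - set(sel.ds)).pop()
        inside = (names & set(sel.ds)).pop()
        masked = mask_genome(f, 0, set(sel.ds))
        out = impute_target(masked, 0, sel, graph=g)
        idx = {fam: i for i, fam in enumerate(f.families)}
        leaf = f.topology.leaf_ids[0]
        assert out.imputed[outside] == int(truth.labels[idx[inside], leaf])

    def test_score_trace_non_increasing(self):
        cfg = SimulationConfig(n_organisms=12, n_families=10, n_couples=4, seed=23)
        f, truth = simulate_forest(cfg)
        g = build_dces_graph(f, 0)
        sel = sweep_w2_for_size(g, 0.5)
        masked = mask_genome(f, 0, set(sel.ds))
        out = impute_target(masked, 0, sel, graph=g)
        trace = out.score_trace
        assert all(trace[k + 1] <= trace[k] + 1e-9 for k in range(len(trace) - 1))

    def test_observed_outside_entry_rejected(self):
        cfg = SimulationConfig(n_organisms=8, n_families=4, seed=29)
        f, _ = simulate_forest(cfg)
        g = build_dces_graph(f, 0)
        sel = select_dominant_set(g, math.inf, math.inf)
        with pytest.raises(ContractError):
            impute_target(f, 0, sel, graph=g)  # nothing masked
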