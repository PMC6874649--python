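import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pollinet import VisitMatrix, restoration as R
from pollinet.network import NetworkInputError
from pollinet.restoration import GAParams

from conftest import random_net


@pytest.fixture
def skewed_net():
    """5 plants with visit totals 50, 30, 10, 6, 4 over two bees."""
    counts = np.array([[40, 10], [20, 10], [5, 5], [3, 3], [2, 2]])
    return VisitMatrix(tuple(f"p{i+1}" for i in range(5)), ("b1", "b2"), counts)


class TestCoverage:
    def test_full_and_empty_sets(self, small_net):
        for criterion in R.CRITERIA:
            assert R.coverage(small_net, small_net.plant_labels, criterion) == 1.0
            assert R.coverage(small_net, set(), criterion) == 0.0

    def test_hand_counts(self, small_net):
        assert R.coverage(small_net, {"p1"}, "bee_richness") == 0.5
        assert R.coverage(small_net, {"p1"}, "bee_visitation") == 0.25

    def test_unknown_plant_rejected(self, small_net):
        with pytest.raises(NetworkInputError):
            R.coverage(small_net, {"zz"}, "bee_richness")


class TestRankPlants:
    def make_metrics(self, strength, visits):
        return pd.DataFrame(
            {"strength": strength, "total_visits": visits},
            index=[f"p{i+1}" for i in range(len(strength))],
        )

    def test_descending_by_metric(self):
        m = self.make_metrics([0.5, 1.5], [2, 6])
        assert R.rank_plants(m, "ST") == ["p2", "p1"]

    def test_tie_broken_by_visits_then_label(self):
        m = self.make_metrics([1.0, 1.0, 1.0], [5, 9, 5])
        assert R.rank_plants(m, "ST") == ["p2", "p1", "p3"]

    def test_unknown_metric_rejected(self):
        with pytest.raises(NetworkInputError):
            R.rank_plants(self.make_metrics([1], [1]), "nope")


class TestGreedy:
    def test_cumulative_visitation_example(self, skewed_net):
        ranking = [f"p{i+1}" for i in range(5)]
        res = R.simulate_greedy(skewed_net, ranking, "bee_visitation", 0.8)
        assert res.n_required == 2  # cumulative 80/100
        assert res.selection == ("p1", "p2")
        assert res.proportion_required == pytest.approx(0.4)

    def test_step_capping_evaluates_2_4_5(self, skewed_net):
        ranking = [f"p{i+1}" for i in range(5)]
        res = R.simulate_greedy(skewed_net, ranking, "bee_richness", 1.0)
        assert [k for k, _ in res.trajectory] == [2]  # both bees seen at k=2
        res2 = R.simulate_greedy(skewed_net, list(reversed(ranking)),
                                 "bee_visitation", 1.0)
        assert [k for k, _ in res2.trajectory] == [2, 4, 5]

    def test_trajectory_nondecreasing(self, skewed_net):
        ranking = [f"p{i+1}" for i in range(5)]
        res = R.simulate_greedy(skewed_net, ranking, "bee_visitation", 1.0, step=1)
        covs = [c for _, c in res.trajectory]
        assert covs == sorted(covs)


class TestRandomBaseline:
    def test_exact_richness_single_host_bee(self):
        # 3 plants, one bee hosted by exactly 1 plant: P(covered at k=1) = 1/3
        counts = np.array([[1, 1], [0, 2], [0, 3]])
        net = VisitMatrix(("p1", "p2", "p3"), ("b1", "b2"), counts)
        res = R.random_baseline(net, "bee_richness", 0.99, step=1)
        k1 = dict(res.trajectory)[1]
        assert k1 == pytest.approx((1 / 3 + 1.0) / 2)  # mean over the two bees

    def test_exact_visitation_is_k_over_p(self, skewed_net):
        res = R.random_baseline(skewed_net, "bee_visitation", 1.0, step=1)
        for k, cov in res.trajectory:
            assert cov == pytest.approx(k / skewed_net.n_plants)

    def test_monte_carlo_within_3se_of_exact(self):
        net = random_net(np.random.default_rng(11), n_plants=8, n_bees=10)
        exact = dict(
            R.random_baseline(net, "bee_richness", 1.0, step=1).trajectory
        )
        mc = R.random_baseline(net, "bee_richness", 1.0, step=1,
                               mode="monte_carlo", n_sims=10_000, seed=2)
        for k, cov in mc.trajectory:
            if k == net.n_plants:
                continue
            # binomial-style bound on the per-bee mean
            se = 0.5 / math.sqrt(10_000)
            assert abs(cov - exact[k]) < 3 * se + 1e-9


class TestGA:
    def test_finds_known_optimum(self):
        net = random_net(np.random.default_rng(5), n_plants=10, n_bees=12)
        best = R.brute_force_min_set(net, "bee_richness", 0.8)
        res = R.ga_select(net, "bee_richness", 0.8, step=1, seed=3)
        assert res.n_required == best.n_required
        assert R.coverage(net, res.selection, "bee_richness") >= 0.8

    def test_matches_greedy_for_additive_visitation(self):
        for seed in range(5):
            net = random_net(np.random.default_rng(seed), n_plants=9, n_bees=8)
            bf = R.brute_force_min_set(net, "bee_visitation", 0.8)
            ga = R.ga_select(net, "bee_visitation", 0.8, step=1, seed=seed)
            assert ga.n_required == bf.n_required

    def test_deterministic_given_seed(self):
        net = random_net(np.random.default_rng(9), n_plants=10, n_bees=10)
        a = R.ga_select(net, "bee_richness", 0.8, seed=42)
        b = R.ga_select(net, "bee_richness", 0.8, seed=42)
        assert a.selection == b.selection

    def test_invalid_params_rejected(self):
        with pytest.raises(NetworkInputError):
            GAParams(population=1)
        with pytest.raises(NetworkInputError):
            GAParams(mutation_rate=2.0)


class TestBruteForce:
    def test_visitation_shortcut_equals_exhaustion(self):
        for seed in range(5):
            net = random_net(np.random.default_rng(50 + seed), n_plants=8, n_bees=6)
            bf = R.brute_force_min_set(net, "bee_visitation", 0.8)
            totals = dict(zip(net.plant_labels, net.plant_totals))
            target = 0.8 * net.grand_total - 1e-9
            best = next(
                k
                for k in range(1, net.n_plants + 1)
                if any(
                    sum(totals[p] for p in combo) >= target
                    for combo in itertools.combinations(net.plant_labels, k)
                )
            )
            assert bf.n_required == best

    def test_full_richness_is_min_set_cover(self):
        net = random_net(np.random.default_rng(60), n_plants=8, n_bees=8)
        bf = R.brute_force_min_set(net, "bee_richness", 1.0)
        assert R.coverage(net, bf.selection, "bee_richness") == 1.0
        # no smaller set covers everything
        for combo in itertools.combinations(net.plant_labels, bf.n_required - 1):
            assert R.coverage(net, combo, "bee_richness") < 1.0

    def test_zero_threshold_gives_empty_set(self, skewed_net):
        bf = R.brute_force_min_set(skewed_net, "bee_richness", 0.0)
        assert bf.n_required == 0 and bf.selection == ()

    def test_size_guard(self):
        net = random_net(np.random.default_rng(1), n_plants=25, n_bees=10, total=500)
        with pytest.raises(R.SizeLimitError):
            R.brute_force_min_set(net, "bee_richness", 0.9)

    def test_never_worse_than_any_strategy(self):
        for seed in range(4):
            net = random_net(np.random.default_rng(70 + seed), n_plants=9, n_bees=9)
            bf = R.brute_force_min_set(net, "bee_richness", 0.8)
            for strat in R.METRIC_STRATEGIES:
                res = R.run_strategy(net, strat, "bee_richness", 0.8, step=1)
                assert bf.n_required <= res.n_required


class TestThresholdSweep:
    def test_n_required_monotone_in_threshold(self):
        net = random_net(np.random.default_rng(80), n_plants=12, n_bees=12, total=400)
        table = R.threshold_sweep(net, "ST", "bee_visitation",
                                  robustness_iter=50, seed=0)
        assert table["n_required"].is_monotonic_increasing

    def test_skewed_low_threshold_needs_far_fewer(self):
        cfg_rng = np.random.default_rng(81)
        net = random_net(cfg_rng, n_plants=14, n_bees=12, total=600)
        table = R.threshold_sweep(net, "ST", "bee_visitation",
                                  thresholds=(0.1, 0.9), robustness_iter=50)
        low, high = table["n_required"].tolist()
        assert low < high

    def test_rejects_unsorted_thresholds(self, skewed_net):
        with pytest.raises(NetworkInputError):
            R.threshold_sweep(skewed_net, "ST", "bee_richness",
                              thresholds=(0.5, 0.2))


@given(st.integers(0, 500))
def test_proportion_required_in_unit_interval(seed):
    net = random_net(np.random.default_rng(seed), n_plants=6, n_bees=8, total=150)
    res = R.run_strategy(net, "ST", "bee_richness", 0.8)
    assert 0 < res.proportion_required <= 1
    assert res.trajectory[-1][1] >= 0.8
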