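"""Forecast metrics, trajectory selection, WGD statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from alfak.evaluation import (
    PopulationState,
    angle_metric,
    angle_null_test,
    baseline_comparison,
    classify_wgd,
    fit_saturation,
    overlap_coefficient,
    permutation_ks,
    profile_correlation,
    random_angle_sample,
    select_nonoverlapping_trajectories,
    wasserstein_distance,
)
from alfak.karyospace import DIPLOID


def _state(pairs):
    return PopulationState(dict(pairs))


K1 = DIPLOID
K2 = (3,) + (2,) * 21
K3 = (3, 3) + (2,) * 20
K4 = (5, 2, 1) + (2,) * 19


class TestAngleMetric:
    def test_identical_direction_is_zero(self):
        v = np.arange(1.0, 23.0)
        assert angle_metric(v, 3.7 * v) == pytest.approx(0.0, abs=1e-6)

    def test_opposite_direction_is_180(self):
        v = np.ones(22)
        assert angle_metric(v, -v) == pytest.approx(180.0)

    def test_orthogonal_is_90(self):
        assert angle_metric(np.eye(22)[0], np.eye(22)[1]) == pytest.approx(90.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=22), rng.normal(size=22)
        assert angle_metric(a, b) == pytest.approx(angle_metric(10 * a, 0.01 * b), abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_metric(np.zeros(22), np.ones(22))


class TestAngleNull:
    def test_null_median_is_ninety_degrees(self):
        rng = np.random.default_rng(1)
        med = np.median(random_angle_sample(100_000, rng))
        assert med == pytest.approx(90.0, abs=0.5)

    def test_perfect_alignment_gives_minimal_p(self):
        res = angle_null_test([[0.0, 0.0], [0.0]], n_iter=999, seed=0)
        assert res["p"] == pytest.approx(1 / 1000)

    def test_null_angles_give_large_p(self):
        rng = np.random.default_rng(2)
        units = [list(random_angle_sample(8, rng)) for _ in range(5)]
        res = angle_null_test(units, n_iter=500, seed=3)
        assert res["p"] > 0.05

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            angle_null_test([[10.0], []], n_iter=10)


class TestWasserstein:
    def test_identical_states_zero(self):
        s = _state([(K1, 0.5), (K2, 0.5)])
        assert wasserstein_distance(s, s) == 0.0

    def test_point_masses_pay_manhattan_distance(self):
        a = _state([(K1, 1.0)])
        b = _state([(K4, 1.0)])  # distance |5-2|+|1-2| = 4
        assert wasserstein_distance(a, b) == pytest.approx(4.0)

    def test_four_point_instance_matches_bruteforce_plans(self):
        # masses in units of 1/4 allow exhaustive enumeration of integer plans
        a = _state([(K1, 0.5), (K2, 0.25), (K3, 0.25)])
        b = _state([(K2, 0.5), (K4, 0.5)])
        support = sorted(set(a.freqs) | set(b.freqs))
        wa = np.array([round(a.freqs.get(k, 0) * 4) for k in support])
        wb = np.array([round(b.freqs.get(k, 0) * 4) for k in support])
        C = np.array(
            [[sum(abs(x - y) for x, y in zip(p, q)) for q in support] for p in support]
        )
        n = len(support)
        best = np.inf
        # enumerate all integer transport plans with the given marginals
        cells = [(i, j) for i in range(n) for j in range(n)]

        def rec(idx, rem_a, rem_b, cost, plan_cost_bound):
            nonlocal best
            if cost >= best:
                return
            if idx == len(cells):
                if not rem_a.any() and not rem_b.any():
                    best = min(best, cost)
                return
            i, j = cells[idx]
            hi = min(rem_a[i], rem_b[j])
            for m in range(hi, -1, -1):
                rem_a[i] -= m
                rem_b[j] -= m
                rec(idx + 1, rem_a, rem_b, cost + m * C[i, j], plan_cost_bound)
                rem_a[i] += m
                rem_b[j] += m

        rec(0, wa.copy(), wb.copy(), 0, None)
        assert wasserstein_distance(a, b) == pytest.approx(best / 4, abs=1e-9)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(4)
        supports = [K1, K2, K3, K4, (2, 4) + (2,) * 20]
        for _ in range(100):
            states = []
            for _ in range(3):
                w = rng.dirichlet(np.ones(len(supports)))
                states.append(PopulationState(dict(zip(supports, w))))
            d01 = wasserstein_distance(states[0], states[1])
            d12 = wasserstein_distance(states[1], states[2])
            d02 = wasserstein_distance(states[0], states[2])
            assert d02 <= d01 + d12 + 1e-9


class TestBaselineAndOverlap:
    def test_exact_forecast_beats_baseline(self):
        future = _state([(K2, 1.0)])
        last = _state([(K1, 1.0)])
        res = baseline_comparison(future, future, last)
        assert res["beats_baseline"]

    def test_ties_lose(self):
        future = _state([(K2, 1.0)])
        last = _state([(K1, 1.0)])
        res = baseline_comparison(last, future, last)
        assert not res["beats_baseline"]

    def test_overlap_hand_example(self):
        a = _state([(K1, 0.7), (K2, 0.3)])
        b = _state([(K1, 0.4), (K2, 0.6)])
        assert overlap_coefficient(a, b) == pytest.approx(0.7)

    def test_overlap_bounds_and_symmetry(self):
        rng = np.random.default_rng(5)
        supports = [K1, K2, K3, K4]
        for _ in range(50):
            wa = rng.dirichlet(np.ones(4))
            wb = rng.dirichlet(np.ones(4))
            a = PopulationState(dict(zip(supports, wa)))
            b = PopulationState(dict(zip(supports, wb)))
            o = overlap_coefficient(a, b)
            assert 0.0 <= o <= 1.0
            assert o == pytest.approx(overlap_coefficient(b, a))
        assert overlap_coefficient(_state([(K1, 1.0)]), _state([(K2, 1.0)])) == 0.0
        s = _state([(K1, 0.5), (K3, 0.5)])
        assert overlap_coefficient(s, s) == pytest.approx(1.0)


class TestTrajectories:
    def test_single_chain_gives_one_trajectory(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        assert select_nonoverlapping_trajectories(g, 0) == [["A", "B", "C"]]

    def test_fork_selects_one_branch_and_both_appear_across_seeds(self):
        g = nx.DiGraph([("A", "B"), ("A", "C")])
        seen = set()
        for seed in range(100):
            paths = select_nonoverlapping_trajectories(g, seed)
            assert len(paths) == 1 and len(paths[0]) == 2
            seen.add(paths[0][1])
        assert seen == {"B", "C"}

    def test_disjointness_invariant(self):
        g = nx.DiGraph(
            [("r1", "a"), ("a", "b"), ("a", "c"), ("r2", "c2"), ("c2", "d"),
             ("b", "e"), ("c", "f"), ("r2", "g")]
        )
        for seed in range(200):
            paths = select_nonoverlapping_trajectories(g, seed)
            flat = list(itertools.chain.from_iterable(paths))
            assert len(flat) == len(set(flat))

    def test_cyclic_graph_rejected(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError):
            select_nonoverlapping_trajectories(g, 0)


class TestProfileCorrelation:
    def test_proportional_profiles_cap_positive(self):
        p = np.arange(44, dtype=float)
        assert profile_correlation(p, 2 * p) == pytest.approx(6.0)

    def test_antiproportional_cap_negative(self):
        p = np.arange(44, dtype=float)
        assert profile_correlation(p, -p) == pytest.approx(-6.0)

    def test_independent_profiles_average_to_zero(self):
        rng = np.random.default_rng(6)
        zs = [
            profile_correlation(rng.normal(size=44), rng.normal(size=44))
            for _ in range(1000)
        ]
        assert abs(np.mean(zs)) < 3 * np.std(zs) / np.sqrt(len(zs)) + 0.02

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation(np.ones(44), np.arange(44.0))

    def test_missing_entries_need_three_shared(self):
        p = np.full(44, np.nan)
        p[:2] = [1.0, 2.0]
        with pytest.raises(ValueError):
            profile_correlation(p, p)


class TestWGD:
    def test_diploid_is_wgd_negative(self):
        assert not classify_wgd(DIPLOID)

    def test_tetraploid_is_wgd_positive(self):
        assert classify_wgd((4,) * 22)

    def test_modal_tie_resolves_high(self):
        k = (2,) * 11 + (4,) * 11
        assert classify_wgd(k)
        assert not classify_wgd(k, tie="low")


class TestSaturationFit:
    def test_noise_free_recovery(self):
        t = np.linspace(0, 40, 25)
        y = 8.0 * (1 - np.exp(-0.1 * t))
        fit = fit_saturation(t, y)
        assert fit["params"]["A"] == pytest.approx(8.0, rel=0.01)
        assert abs(fit["params"]["r"]) == pytest.approx(0.1, rel=0.01)

    def test_flat_zero_signal_gives_zero_asymptote(self):
        t = np.linspace(0, 30, 12)
        fit = fit_saturation(t, np.zeros_like(t))
        assert abs(fit["params"]["A"]) < 1e-6

    def test_group_contrast_power(self):
        rng = np.random.default_rng(7)
        detections = 0
        for _ in range(100):
            t = np.tile(np.linspace(1, 40, 20), 2)
            g = np.repeat([0, 1], 20)
            A = np.where(g == 0, 4.0, 8.0)
            y = A * (1 - np.exp(-0.1 * t)) + rng.normal(0, 0.4, t.size)
            fit = fit_saturation(t, y, groups=g)
            if fit["wald_p"]["dA[1]"] < 0.05:
                detections += 1
        assert detections >= 90


class TestPermutationKS:
    def test_identical_groups_large_p(self):
        a = np.linspace(0, 1, 15)
        res = permutation_ks(a, a, n_perm=200, seed=0)
        assert res["p"] > 0.5

    def test_separated_groups_small_p(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        res = permutation_ks(a, b, n_perm=2000, seed=1)
        assert res["p"] <= 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_ks([], [1.0], n_perm=10)
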