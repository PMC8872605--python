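"""2SFCA carrying capacity: threshold, kernel, both steps, Jenks grading."""

import itertools

import numpy as np
import pytest

from medcarry import (
    ODMatrix,
    classify_capacity,
    compute_threshold,
    jenks_breaks,
    kernel_weight,
    step1_ratios,
    step2_capacity,
)


def od_from_array(values):
    values = np.asarray(values, dtype=float)
    nd, ns = values.shape
    return ODMatrix(
        demand_ids=[f"d{i}" for i in range(nd)],
        supply_ids=[f"s{j}" for j in range(ns)],
        values=values,
    )


def triple_loop_2sfca(s, d, dist, d0, mode):
    """Naive reference: explicit loops over supply, demand, catchments."""

    def g(x):
        if d0 == 0:
            return 1.0 if x == 0 else 0.0
        return 0.75 * (1 - (x / d0) ** 2) if x <= d0 else 0.0

    ns, nd = len(s), len(d)
    r = []
    for j in range(ns):
        denom = 0.0
        for k in range(nd):
            if dist[k][j] <= d0:
                denom += g(dist[k][j]) * d[k]
        r.append(0.0 if denom == 0 else s[j] / denom)
    a = []
    for i in range(nd):
        tot = 0.0
        for j in range(ns):
            if dist[i][j] <= d0:
                tot += r[j] * (g(dist[i][j]) if mode == "symmetric" else 1.0)
        a.append(tot)
    return np.array(r), np.array(a)


class TestThreshold:
    def test_max_of_nearest_distances(self):
        # nearest supply per demand point at 2, 5, 9 -> d0 = 9
        od = od_from_array([[2, 7], [5, 6], [9, 12]])
        assert compute_threshold(od) == 9.0

    def test_single_colocated_pair(self):
        assert compute_threshold(od_from_array([[0.0]])) == 0.0

    def test_all_equal_distances(self):
        assert compute_threshold(od_from_array(np.full((3, 2), 4.2))) == 4.2

    def test_supply_side_reading(self):
        od = od_from_array([[1, 10], [2, 3]])
        # demand side: max(min(1,10), min(2,3)) = 2
        # supply side: max(min over demand per supply) = max(1, 3) = 3
        assert compute_threshold(od) == 2.0
        assert compute_threshold(od, side="supply") == 3.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(ODMatrix())


class TestKernel:
    def test_boundary_values(self):
        assert kernel_weight(0.0, 10.0) == pytest.approx(0.75)
        assert kernel_weight(10.0, 10.0) == 0.0
        assert kernel_weight(5.0, 10.0) == pytest.approx(0.5625)
        assert kernel_weight(11.0, 10.0) == 0.0

    def test_strictly_decreasing_inside_catchment(self):
        d = np.linspace(0, 1, 1000)
        g = kernel_weight(d, 1.0)
        assert np.all(np.diff(g) < 0)

    def test_degenerate_zero_threshold_indicator(self):
        assert kernel_weight(0.0, 0.0) == 1.0
        assert kernel_weight(0.5, 0.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_weight(-1.0, 5.0)


class TestStepOne:
    def test_colocated_pair_ratio_one(self):
        od = od_from_array([[0.0]])
        r, flagged = step1_ratios([90.0], [120.0], od, d0=10.0)
        assert r[0] == pytest.approx(90.0 / (0.75 * 120.0))
        assert not flagged[0]

    def test_out_of_range_supply_flagged_zero(self):
        od = od_from_array([[100.0]])
        r, flagged = step1_ratios([50.0], [10.0], od, d0=5.0)
        assert r[0] == 0.0
        assert flagged[0]

    def test_demand_exactly_at_threshold_zero_weight(self):
        # in catchment but kernel weight 0 -> empty weighted demand
        od = od_from_array([[5.0]])
        r, flagged = step1_ratios([50.0], [10.0], od, d0=5.0)
        assert r[0] == 0.0
        assert flagged[0]

    def test_doubling_demand_halves_ratios(self, rng):
        dist = rng.uniform(0, 10, size=(6, 4))
        od = od_from_array(dist)
        s = rng.uniform(1, 5, 4)
        d = rng.uniform(10, 100, 6)
        r1, _ = step1_ratios(s, d, od, d0=8.0)
        r2, _ = step1_ratios(s, 2 * d, od, d0=8.0)
        np.testing.assert_allclose(r2, r1 / 2)


class TestStepTwo:
    def test_colocated_pair_paper_mode(self):
        od = od_from_array([[0.0]])
        r, _ = step1_ratios([90.0], [120.0], od, d0=10.0)
        a = step2_capacity(r, od, d0=10.0, mode="paper")
        assert a[0] == pytest.approx(90.0 / (0.75 * 120.0))

    def test_colocated_pair_symmetric_mode(self):
        od = od_from_array([[0.0]])
        r, _ = step1_ratios([90.0], [120.0], od, d0=10.0)
        a = step2_capacity(r, od, d0=10.0, mode="symmetric")
        assert a[0] == pytest.approx(90.0 / 120.0)

    def test_unreachable_demand_zero_capacity(self):
        od = od_from_array([[1.0], [50.0]])
        r, _ = step1_ratios([10.0], [5.0, 5.0], od, d0=2.0)
        a = step2_capacity(r, od, d0=2.0, mode="paper")
        assert a[1] == 0.0
        assert a[0] > 0.0

    def test_matches_triple_loop_oracle(self, rng):
        """Both modes equal the naive reimplementation on small instances."""
        for _ in range(25):
            nd, ns = rng.integers(1, 6, size=2)
            dist = rng.uniform(0, 10, size=(nd, ns)).round(1)
            s = rng.uniform(0.5, 5, ns)
            d = rng.uniform(10, 100, nd)
            od = od_from_array(dist)
            d0 = compute_threshold(od)
            for mode in ("paper", "symmetric"):
                r_ref, a_ref = triple_loop_2sfca(s, d, dist, d0, mode)
                r, _ = step1_ratios(s, d, od, d0)
                a = step2_capacity(r, od, d0, mode)
                np.testing.assert_allclose(r, r_ref, rtol=1e-13, atol=0)
                np.testing.assert_allclose(a, a_ref, rtol=1e-13, atol=0)

    def test_symmetric_mode_conserves_supply(self, rng):
        """sum_i D_i A_i == sum_j S_j when every supply point has demand in range."""
        for _ in range(30):
            nd, ns = rng.integers(2, 51, size=2)
            dist = rng.uniform(0, 10, size=(nd, ns))
            s = rng.uniform(0.5, 5, ns)
            d = rng.uniform(10, 100, nd)
            od = od_from_array(dist)
            d0 = float(dist.max()) * 1.01  # everyone in range, weights > 0
            r, flagged = step1_ratios(s, d, od, d0)
            assert not flagged.any()
            a = step2_capacity(r, od, d0, mode="symmetric")
            assert float(d @ a) == pytest.approx(float(s.sum()), abs=1e-9 * s.sum())

    def test_homogeneity_in_supply_and_demand(self, rng):
        dist = rng.uniform(0, 10, size=(8, 5))
        od = od_from_array(dist)
        s = rng.uniform(0.5, 5, 5)
        d = rng.uniform(10, 100, 8)
        d0 = 8.0
        for mode in ("paper", "symmetric"):
            r, _ = step1_ratios(s, d, od, d0)
            a = step2_capacity(r, od, d0, mode)
            r2, _ = step1_ratios(3 * s, d, od, d0)
            np.testing.assert_allclose(
                step2_capacity(r2, od, d0, mode), 3 * a, rtol=1e-12
            )
            r3, _ = step1_ratios(s, 2 * d, od, d0)
            np.testing.assert_allclose(
                step2_capacity(r3, od, d0, mode), a / 2, rtol=1e-12
            )

    def test_removing_supply_never_increases_capacity(self, rng):
        dist = rng.uniform(0, 10, size=(10, 6))
        s = rng.uniform(0.5, 5, 6)
        d = rng.uniform(10, 100, 10)
        od = od_from_array(dist)
        d0 = 9.0
        r, _ = step1_ratios(s, d, od, d0)
        a_full = step2_capacity(r, od, d0, "paper")
        od_less = od_from_array(dist[:, :-1])
        r_less, _ = step1_ratios(s[:-1], d, od_less, d0)
        a_less = step2_capacity(r_less, od_less, d0, "paper")
        assert np.all(a_less <= a_full + 1e-12)

    def test_symmetric_all_equal_distances_equal_capacity(self, rng):
        dist = np.full((5, 3), 2.0)
        s = rng.uniform(1, 3, 3)
        d = rng.uniform(10, 20, 5)
        od = od_from_array(dist)
        r, _ = step1_ratios(s, d, od, d0=4.0)
        a = step2_capacity(r, od, d0=4.0, mode="paper")
        np.testing.assert_allclose(a, a[0])


def exhaustive_jenks(values, k):
    """Oracle: try every contiguous partition of the sorted values."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    best, best_cost = None, np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = sum(
            ((x[a:b] - x[a:b].mean()) ** 2).sum()
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        if cost < best_cost - 1e-12:
            best_cost, best = cost, bounds
    return best_cost, [x[0]] + [float(x[i]) for i in best[1:-1]] + [float(x[-1])]


class TestJenks:
    def test_two_obvious_groups(self):
        edges = jenks_breaks([1, 2, 3, 10, 11, 12], 2)
        assert edges == [1.0, 10.0, 12.0]

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(5, 13))
            k = int(rng.integers(2, 5))
            x = rng.uniform(0, 100, n).round(1)
            if len(np.unique(x)) < k:
                continue
            cost_ref, _ = exhaustive_jenks(x, k)
            edges = jenks_breaks(x, k)
            # recompute the DP partition's cost from its edges
            xs = np.sort(x)
            idx = np.searchsorted(xs, edges[1:-1])
            bounds = [0, *idx, len(xs)]
            cost = sum(
                ((xs[a:b] - xs[a:b].mean()) ** 2).sum()
                for a, b in zip(bounds[:-1], bounds[1:])
                if b > a
            )
            assert cost == pytest.approx(cost_ref, abs=1e-9)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks([3.0, 3.0, 3.0, 3.0, 3.0], 2)


class TestClassifyCapacity:
    def test_five_grade_labels_ordered(self, rng):
        x = np.concatenate(
            [rng.normal(loc, 0.3, 40) for loc in (0, 3, 6, 9, 12)]
        )
        breaks, labels = classify_capacity(x, 5)
        assert len(breaks) == 6
        means = {
            g: x[labels == g].mean()
            for g in ("lower", "low", "middle", "high", "higher")
        }
        ordered = [means[g] for g in ("lower", "low", "middle", "high", "higher")]
        assert ordered == sorted(ordered)

    def test_interval_convention_top_closed(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        _, labels = classify_capacity(values, 2, labels=["a", "b"])
        assert list(labels) == ["a", "a", "a", "b", "b", "b"]

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            classify_capacity(np.ones(10), 5)
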