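"""NSGA-II components against brute-force and distributional oracles."""

import numpy as np
import pandas as pd
import pytest

from tpmslat import moo


def brute_force_fronts(F):
    """O(n^3) reference partition by repeated non-dominated extraction."""
    F = np.asarray(F, dtype=float)
    idx = list(range(len(F)))
    fronts = []
    while idx:
        cur = [i for i in idx
               if not any(moo.dominates(F[j], F[i]) for j in idx if j != i)]
        fronts.append(sorted(cur))
        idx = [i for i in idx if i not in cur]
    return fronts


class TestDominates:
    def test_componentwise_examples(self):
        assert moo.dominates([2, 2, 2], [1, 1, 1])
        assert not moo.dominates([2, 1], [1, 2])
        assert not moo.dominates([1, 2], [2, 1])
        assert not moo.dominates([1, 1], [1, 1])

    def test_antisymmetry_and_transitivity(self, rng):
        for _ in range(200):
            a, b, c = rng.integers(0, 4, size=(3, 3))
            if moo.dominates(a, b):
                assert not moo.dominates(b, a)
            if moo.dominates(a, b) and moo.dominates(b, c):
                assert moo.dominates(a, c)


class TestNonDominatedSort:
    def test_single_individual(self):
        assert moo.fast_non_dominated_sort([[1.0, 2.0]]) == [[0]]

    def test_matches_brute_force_on_random_sets(self, rng):
        for m in (2, 3):
            F = rng.random((64, m))
            fast = [sorted(f) for f in moo.fast_non_dominated_sort(F)]
            assert fast == brute_force_fronts(F)

    def test_duplicates_share_a_front(self):
        F = [[1, 1], [1, 1], [0, 0]]
        fronts = moo.fast_non_dominated_sort(F)
        assert sorted(fronts[0]) == [0, 1]

    def test_no_dominance_within_returned_front(self, rng):
        F = rng.random((40, 3))
        front = moo.fast_non_dominated_sort(F)[0]
        for i in front:
            for j in front:
                assert not moo.dominates(F[i], F[j])


class TestCrowdingDistance:
    def test_two_individuals_both_infinite(self):
        assert np.isinf(moo.crowding_distance([[1, 2], [3, 4]])).all()

    def test_three_collinear_equally_spaced(self):
        # middle individual spans the full normalized range: distance 1
        d = moo.crowding_distance([[0.0], [0.5], [1.0]])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(1.0)

    def test_permutation_invariant(self, rng):
        F = rng.random((12, 2))
        perm = rng.permutation(12)
        d = moo.crowding_distance(F)
        dp = moo.crowding_distance(F[perm])
        np.testing.assert_allclose(dp, d[perm])

    def test_zero_range_objective_contributes_nothing(self):
        d = moo.crowding_distance([[0.0, 5.0], [0.5, 5.0], [1.0, 5.0]])
        assert d[1] == pytest.approx(1.0)


BOUNDS = np.array([[0.0, 1.0], [-2.0, 3.0], [10.0, 11.0]])


class TestOperators:
    def test_identical_parents_identical_children(self, rng):
        p = np.array([0.5, 0.0, 10.5])
        c1, c2 = moo.sbx_crossover(p, p.copy(), BOUNDS, 15, 1.0, rng)
        np.testing.assert_array_equal(c1, p)
        np.testing.assert_array_equal(c2, p)

    def test_children_respect_bounds(self, rng):
        lo, hi = BOUNDS[:, 0], BOUNDS[:, 1]
        for _ in range(2000):
            p1 = lo + rng.random(3) * (hi - lo)
            p2 = lo + rng.random(3) * (hi - lo)
            for c in moo.sbx_crossover(p1, p2, BOUNDS, 15, 0.9, rng):
                assert ((c >= lo) & (c <= hi)).all()

    def test_large_eta_children_converge_to_parents(self, rng):
        lo, hi = BOUNDS[:, 0], BOUNDS[:, 1]
        offsets = []
        for _ in range(500):
            p1 = lo + rng.random(3) * (hi - lo)
            p2 = lo + rng.random(3) * (hi - lo)
            c1, c2 = moo.sbx_crossover(p1, p2, BOUNDS, 1e6, 1.0, rng)
            # each child coordinate approaches one of the two parent values
            # (crossed variables may swap between the children)
            for c in (c1, c2):
                near = np.minimum(np.abs(c - p1), np.abs(c - p2))
                offsets.append(near.max())
        assert np.mean(offsets) < 1e-3

    def test_mutation_prob_zero_is_identity(self, rng):
        x = np.array([0.3, 1.0, 10.2])
        np.testing.assert_array_equal(
            moo.polynomial_mutation(x, BOUNDS, 20, 0.0, rng), x)

    def test_mutation_respects_bounds(self, rng):
        lo, hi = BOUNDS[:, 0], BOUNDS[:, 1]
        for _ in range(2000):
            x = lo + rng.random(3) * (hi - lo)
            y = moo.polynomial_mutation(x, BOUNDS, 20, 1.0, rng)
            assert ((y >= lo) & (y <= hi)).all()

    def test_empirical_mutation_rate(self, rng):
        prob, n = 0.3, 20_000
        changed = 0
        x = np.array([0.5, 0.5, 10.5])
        for _ in range(n):
            y = moo.polynomial_mutation(x, BOUNDS, 20, prob, rng)
            changed += int((y != x).sum())
        rate = changed / (3 * n)
        se = np.sqrt(prob * (1 - prob) / (3 * n))
        assert abs(rate - prob) < 4 * se


class TestRunNSGA2:
    def test_concave_toy_front_spans_extremes(self):
        # maximize (x, 1 - x^2): the whole [0, 1] segment is Pareto-optimal
        def f(X):
            X = np.atleast_2d(X)
            return np.column_stack([X[:, 0], 1 - X[:, 0] ** 2])
        res = moo.run_nsga2(f, np.array([[0.0, 1.0]]),
                            moo.NSGAConfig(population_size=40,
                                           generations=30, seed=0))
        assert res.X.min() < 0.02 and res.X.max() > 0.98

    def test_seed_determinism(self):
        def f(X):
            X = np.atleast_2d(X)
            return np.column_stack([X[:, 0], 1 - X[:, 0]])
        cfg = moo.NSGAConfig(population_size=20, generations=10, seed=9)
        a = moo.run_nsga2(f, np.array([[0.0, 1.0], [0.0, 1.0]]), cfg)
        b = moo.run_nsga2(f, np.array([[0.0, 1.0], [0.0, 1.0]]), cfg)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.F, b.F)

    def test_elitism_best_objectives_non_decreasing(self):
        def f(X):
            X = np.atleast_2d(X)
            return np.column_stack([X[:, 0], 1 - X[:, 0] ** 2])
        res = moo.run_nsga2(f, np.array([[0.0, 1.0]]),
                            moo.NSGAConfig(population_size=30,
                                           generations=20, seed=2))
        for col in ("best_0", "best_1"):
            assert res.history[col].is_monotonic_increasing

    def test_returned_front_is_non_dominated(self):
        def f(X):
            X = np.atleast_2d(X)
            return np.column_stack([X[:, 0], 1 - X[:, 0] ** 2])
        res = moo.run_nsga2(f, np.array([[0.0, 1.0]]),
                            moo.NSGAConfig(population_size=30,
                                           generations=10, seed=4))
        assert brute_force_fronts(res.F)[0] == list(range(len(res.F)))

    def test_evaluator_failure_contextualized(self):
        def bad(X):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="initial population"):
            moo.run_nsga2(bad, np.array([[0.0, 1.0]]),
                          moo.NSGAConfig(population_size=10, generations=2))


class TestRdFilter:
    def test_inclusive_band(self):
        front = pd.DataFrame({"rd_pred": [19.9, 20.0, 30.0, 40.0, 40.1]})
        kept, rejected = moo.rd_filter(front)
        assert list(kept.rd_pred) == [20.0, 30.0, 40.0]
        assert list(rejected.rd_pred) == [19.9, 40.1]

    def test_empty_front(self):
        front = pd.DataFrame({"rd_pred": []})
        kept, rejected = moo.rd_filter(front)
        assert kept.empty and rejected.empty

    def test_partition(self, rng):
        front = pd.DataFrame({"rd_pred": rng.uniform(0, 60, 50)})
        kept, rejected = moo.rd_filter(front)
        assert len(kept) + len(rejected) == 50
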