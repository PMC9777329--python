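"""Feature conditioning and genetic-algorithm selection."""

import itertools

import numpy as np
import pytest

import radioga as rg
from radioga.selection import Chromosome, _knn3_predict
from radioga.tables import FeatureTable


def table_from(values, labels=None):
    values = np.asarray(values, float)
    return FeatureTable(
        values,
        [f"f{i:03d}" for i in range(values.shape[1])],
        labels if labels is not None else np.zeros(values.shape[0], int),
    )


class TestDropZeroVariance:
    def test_one_constant_among_five(self, rng):
        X = rng.normal(size=(6, 5))
        X[:, 2] = 3.14
        out = rg.drop_zero_variance(table_from(X))
        assert out.n_features == 4
        assert "f002" not in out.feature_names

    def test_no_constants_identity(self, rng):
        t = table_from(rng.normal(size=(5, 4)))
        out = rg.drop_zero_variance(t)
        assert out.feature_names == t.feature_names
        np.testing.assert_array_equal(out.values, t.values)

    def test_planted_constants_survivors(self, rng):
        X = rng.normal(size=(10, 20))
        planted = [3, 7, 15]
        for j in planted:
            X[:, j] = j
        out = rg.drop_zero_variance(table_from(X))
        assert out.n_features == 17
        # independent recomputation of which columns vary
        expected = [f"f{j:03d}" for j in range(20) if len(set(X[:, j])) > 1]
        assert out.feature_names == expected

    def test_idempotent(self, rng):
        X = rng.normal(size=(8, 6))
        X[:, 0] = 0
        once = rg.drop_zero_variance(table_from(X))
        twice = rg.drop_zero_variance(once)
        assert once.feature_names == twice.feature_names

    def test_all_constant_raises(self):
        with pytest.raises(rg.ValidationError):
            rg.drop_zero_variance(table_from(np.ones((4, 3))))


class TestWhiten:
    def test_hand_example_n_minus_1(self):
        out = rg.whiten(table_from(np.array([[1.0], [2.0], [3.0]])))
        np.testing.assert_allclose(out.values.ravel(), [-1, 0, 1])

    def test_postcondition_mean0_sd1(self, rng):
        out = rg.whiten(table_from(rng.normal(3, 7, size=(20, 5))))
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        assert np.abs(out.values.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_idempotent_up_to_tolerance(self, rng):
        once = rg.whiten(table_from(rng.normal(size=(12, 3))))
        twice = rg.whiten(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_zero_variance_column_raises(self):
        with pytest.raises(rg.ValidationError, match="drop_zero_variance"):
            rg.whiten(table_from(np.ones((4, 2))))


class TestFitness:
    def test_perfect_predictor(self):
        y = np.array([0, 1] * 10)
        X = np.column_stack([y.astype(float), np.zeros(20)])
        t = FeatureTable(X, ["perfect", "junk"], y)
        assert rg.fitness([0], t) == 1.0

    def test_noise_near_half_monte_carlo(self):
        """Pure-noise features on permuted labels score ~0.5 on average."""
        accs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            y = r.permutation(np.array([0, 1] * 100))
            t = FeatureTable(r.normal(size=(200, 5)), [f"n{i}" for i in range(5)], y)
            accs.append(rg.fitness([0, 1, 2], t, seed=seed))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_deterministic_under_seed(self, rng):
        y = np.array([0, 1] * 15)
        t = FeatureTable(rng.normal(size=(30, 4)), list("abcd"), y)
        assert rg.fitness([1, 3], t, seed=9) == rg.fitness([1, 3], t, seed=9)

    def test_single_class_raises(self, rng):
        t = FeatureTable(rng.normal(size=(10, 2)), ["a", "b"], np.zeros(10, int))
        with pytest.raises(rg.ValidationError):
            rg.fitness([0], t)

    def test_knn_scorer_agrees_with_sklearn(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        Xtr = rng.normal(size=(40, 3))
        ytr = (rng.random(40) < 0.5).astype(int)
        if len(set(ytr)) < 2:
            ytr[0] = 1 - ytr[0]
        Xte = rng.normal(size=(25, 3))
        clf = KNeighborsClassifier(n_neighbors=3).fit(Xtr, ytr)
        np.testing.assert_array_equal(
            _knn3_predict(Xtr, ytr, Xte), clf.predict(Xte)
        )


class TestEvolve:
    def test_single_feature_returned_immediately(self):
        y = np.array([0, 1] * 5)
        t = FeatureTable(y.astype(float).reshape(-1, 1), ["only"], y)
        cfg = rg.GAConfig(chromosome_size=1, population_size=4, max_generations=10, seed=1)
        best = rg.evolve(t, cfg)
        assert best.genes == (0,)

    def test_finds_exhaustive_best_pair(self):
        """Oracle: enumerate all feature pairs; the GA's answer must match
        the exhaustive-search optimum."""
        t = rg.make_feature_table(60, 12, 2, effect_size=2.0, seed=4)
        w = rg.whiten(t)
        cfg = rg.GAConfig(
            chromosome_size=2,
            population_size=20,
            max_generations=40,
            fitness_goal=1.01,  # unreachable: force a full search
            seed=11,
        )
        best = rg.evolve(w, cfg)
        scores = {
            pair: rg.fitness(list(pair), w, seed=11)
            for pair in itertools.combinations(range(12), 2)
        }
        best_score = max(scores.values())
        assert best.fitness == pytest.approx(best_score)
        top_pairs = [p for p, s in scores.items() if s == best_score]
        assert tuple(sorted(best.genes)) in top_pairs

    def test_unreachable_goal_runs_all_generations(self, rng):
        y = np.array([0, 1] * 8)
        t = FeatureTable(rng.normal(size=(16, 6)), list("abcdef"), y)
        cfg = rg.GAConfig(
            chromosome_size=2, population_size=6, max_generations=7,
            fitness_goal=1.01, seed=3,
        )
        best, history = rg.evolve(t, cfg, return_history=True)
        assert len(history) == 8  # initial population + 7 generations

    def test_elitism_best_fitness_nondecreasing(self, rng):
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        t = FeatureTable(rng.normal(size=(30, 10)), [f"f{i}" for i in range(10)], y)
        cfg = rg.GAConfig(
            chromosome_size=3, population_size=8, max_generations=15,
            fitness_goal=1.01, seed=5,
        )
        _, history = rg.evolve(t, cfg, return_history=True)
        assert all(b >= a for a, b in zip(history, history[1:]))


class TestCollectSolutions:
    def test_frequencies_sum(self):
        t = rg.make_feature_table(30, 10, 1, 3.0, seed=2)
        cfg = rg.GAConfig(
            chromosome_size=3, population_size=8, max_generations=5,
            n_solutions=6, seed=7,
        )
        res = rg.collect_solutions(rg.whiten(t), cfg)
        assert res.gene_frequency.sum() == 6 * 3
        assert len(res.rank_trajectory) == 6

    def test_single_solution_indicator(self):
        t = rg.make_feature_table(20, 8, 1, 3.0, seed=2)
        cfg = rg.GAConfig(
            chromosome_size=2, population_size=6, max_generations=5,
            n_solutions=1, seed=7,
        )
        res = rg.collect_solutions(rg.whiten(t), cfg)
        freq = res.gene_frequency
        assert sorted(np.flatnonzero(freq)) == sorted(res.solutions[0].genes)

    def test_same_master_seed_identical(self):
        t = rg.whiten(rg.make_feature_table(20, 8, 1, 3.0, seed=2))
        cfg = rg.GAConfig(
            chromosome_size=2, population_size=6, max_generations=5,
            n_solutions=4, seed=13,
        )
        a = rg.collect_solutions(t, cfg)
        b = rg.collect_solutions(t, cfg)
        assert [c.genes for c in a.solutions] == [c.genes for c in b.solutions]
        assert [c.fitness for c in a.solutions] == [c.fitness for c in b.solutions]


class TestStableGenes:
    def _result(self, names, chromosomes):
        return rg.GAResult(
            solutions=[Chromosome(tuple(c), 0.9) for c in chromosomes],
            feature_names=names,
        )

    def test_k_zero_empty(self):
        res = self._result(["a", "b"], [(0, 1)])
        assert rg.stable_genes(res, 0) == []

    def test_seven_names(self):
        t = rg.make_feature_table(30, 12, 2, 4.0, seed=3)
        cfg = rg.GAConfig(
            chromosome_size=3, population_size=8, max_generations=5,
            n_solutions=5, seed=3,
        )
        res = rg.collect_solutions(rg.whiten(t), cfg)
        assert len(rg.stable_genes(res, 7)) == 7

    def test_tiebreak_by_name(self):
        # A and B tie on frequency and mean rank; C trails
        names = ["B", "A", "C"]
        res = self._result(names, [(0, 1), (1, 0), (0, 1, 2)][:2])
        assert rg.stable_genes(res, 2) == ["A", "B"]

    def test_k_too_large_raises(self):
        res = self._result(["a"], [(0,)])
        with pytest.raises(rg.ValidationError):
            rg.stable_genes(res, 5)


class TestForwardSelect:
    def test_perfect_single_predictor(self):
        y = np.array([0, 1] * 10)
        X = np.column_stack([y.astype(float), np.random.default_rng(1).normal(size=20)])
        t = FeatureTable(X, ["hit", "noise"], y)
        assert rg.forward_select(t, ["hit", "noise"]) == ["hit"]

    def test_complementary_half_predictors_both_kept(self):
        # f1 separates the first half of the cohort, f2 the second half
        rng = np.random.default_rng(0)
        n = 40
        y = np.array([0, 1] * (n // 2))
        f1 = np.where(np.arange(n) < n // 2, y * 4.0, 0.0) + rng.normal(0, 0.1, n)
        f2 = np.where(np.arange(n) >= n // 2, y * 4.0, 0.0) + rng.normal(0, 0.1, n)
        t = FeatureTable(np.column_stack([f1, f2]), ["g1", "g2"], y)
        kept = rg.forward_select(t, ["g1", "g2"], seed=1)
        acc1 = rg.fitness([0], t, seed=1)
        acc12 = rg.fitness([0, 1], t, seed=1)
        assert acc12 > acc1  # the increment the greedy rule must see
        assert kept == ["g1", "g2"]

    def test_matches_independent_greedy(self, rng):
        """Oracle: an explicit reimplementation of the greedy rule."""
        y = (rng.random(24) < 0.5).astype(int)
        y[:2] = [0, 1]
        t = FeatureTable(rng.normal(size=(24, 6)), [f"f{i}" for i in range(6)], y)
        ranked = [f"f{i}" for i in range(6)]
        kept = rg.forward_select(t, ranked, seed=2)

        expected = [ranked[0]]
        idx = [0]
        best = rg.fitness(idx, t, seed=2)
        for j, g in enumerate(ranked[1:], start=1):
            acc = rg.fitness(idx + [j], t, seed=2)
            if acc > best:
                best, idx = acc, idx + [j]
                expected.append(g)
        assert kept == expected

    def test_empty_ranking_raises(self, rng):
        t = FeatureTable(rng.normal(size=(6, 2)), ["a", "b"], np.array([0, 1] * 3))
        with pytest.raises(rg.ValidationError):
            rg.forward_select(t, [])
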