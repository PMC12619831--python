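"""GA / elastic-net engine: metric arithmetic, fitness penalty, evolution
invariants (elitism, determinism), nested-CV leakage contract and bootstrap
confidence intervals."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from metabopanel import ga_en
from metabopanel.ga_en import (
    GAConfig,
    GAError,
    bootstrap_metrics,
    brier,
    en_logistic_fit,
    fitness,
    ga_evolve,
    mcc,
    metrics_from_probs,
    nested_cv,
    reduced_config,
)


class TestMetricOracles:
    @pytest.mark.parametrize(
        "counts, expected",
        # (3,1,2,2): (3*2 - 1*2) / sqrt((3+1)(3+2)(2+1)(2+2)) = 4/sqrt(240),
        # cross-checked against sklearn.metrics.matthews_corrcoef
        [((5, 0, 5, 0), 1.0), ((0, 5, 0, 5), -1.0),
         ((3, 1, 2, 2), 4 / np.sqrt(240)), ((5, 5, 0, 0), 0.0)],
    )
    def test_mcc_hand_values(self, counts, expected):
        assert mcc(*counts) == pytest.approx(expected)

    def test_mcc_rejects_bad_counts(self):
        with pytest.raises(GAError):
            mcc(-1, 0, 0, 1)
        with pytest.raises(GAError):
            mcc(0, 0, 0, 0)

    def test_brier_trivial_and_oracle(self):
        assert brier([1.0, 0.0], [1, 0]) == 0.0
        assert brier([0.5, 0.5, 0.5], [1, 0, 1]) == 0.25
        rng = np.random.default_rng(0)
        p = rng.random(20)
        y = rng.integers(0, 2, 20)
        assert brier(p, y) == pytest.approx(
            sum((pi - yi) ** 2 for pi, yi in zip(p, y)) / 20)
        with pytest.raises(GAError):
            brier([1.2], [1])

    def test_auc_matches_concordance_enumeration(self):
        probs = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1.0])
        pairs = [(i, j) for i in range(4) for j in range(4) if y[i] == 0 and y[j] == 1]
        conc = np.mean([(probs[j] > probs[i]) + 0.5 * (probs[j] == probs[i])
                        for i, j in pairs])
        assert metrics_from_probs(probs, y)["auc"] == pytest.approx(conc)


class TestElasticNet:
    def test_infinite_strength_shrinks_to_prevalence(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.standard_normal((40, 5)))
        y = np.array([0.0] * 30 + [1.0] * 10)
        # strength 10 already zeroes every coefficient; the unpenalized
        # intercept then sits at the class-prevalence logit
        model = en_logistic_fit(x, y, strength=10.0, tol=1e-12, max_iter=50_000)
        assert np.abs(model.coefficients).max() == 0.0
        assert model.intercept == pytest.approx(np.log(10 / 30), abs=0.05)

    def test_l1_ratio_one_matches_lasso_path(self):
        from metabopanel.lasso_panel import lasso_select

        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.standard_normal((60, 8)),
                         columns=[f"F{j}" for j in range(8)])
        y = pd.Series(["a"] * 30 + ["b"] * 30, index=x.index)
        x.loc[y == "b", "F0"] += 2.0
        lam = 0.05
        sel = lasso_select(x, y, lambda_grid=[lam], folds=4)
        model = en_logistic_fit(x, y, l1_ratio=1.0, strength=len(y) * lam,
                                tol=1e-10, max_iter=50_000, positive="b")
        dense = np.zeros(8)
        for f, c in zip(sel.feature_ids, sel.coefficients):
            dense[x.columns.get_loc(f)] = c
        np.testing.assert_allclose(model.coefficients, dense, atol=1e-4)

    def test_prox_solver_matches_saga_optimum(self):
        """The JIT fitness solver and sklearn's saga optimize the same
        strictly convex objective; their optima coincide."""
        import warnings

        from sklearn.linear_model import LogisticRegression

        from metabopanel._en_prox import en_logistic_prox

        rng = np.random.default_rng(4)
        for _ in range(5):
            n, p = 24, int(rng.integers(2, 12))
            X = rng.standard_normal((n, p))
            y = (rng.random(n) < 0.5).astype(float)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            X[:, 0] += y * 1.5
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = LogisticRegression(solver="saga", l1_ratio=0.5, C=1.0,
                                         max_iter=50_000, tol=1e-10).fit(X, y)
            b, w = en_logistic_prox(X, y, C=1.0, l1_ratio=0.5,
                                    max_iter=20_000, tol=1e-10)
            np.testing.assert_allclose(w, clf.coef_.ravel(), atol=1e-5)
            assert b == pytest.approx(clf.intercept_[0], abs=1e-5)

    def test_planted_sign_is_recovered(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.standard_normal((50, 4)))
        y = pd.Series(["a"] * 25 + ["b"] * 25, index=x.index)
        x.loc[y == "b", 0] -= 2.0
        model = en_logistic_fit(x, y, positive="b")
        assert model.coefficients[0] < 0


def perfect_feature_data(seed=0, n=40, p=25):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
    X[:, 0] = y * 6 - 3 + rng.normal(0, 0.1, n)  # near-perfect single feature
    return X, y


class TestFitness:
    def test_perfect_single_feature_fitness_one(self):
        X, y = perfect_feature_data()
        skf = StratifiedKFold(4, shuffle=True, random_state=0)
        splits = list(skf.split(X, y))
        mask = np.zeros(25, bool)
        mask[0] = True
        assert fitness(mask, X, y, splits, reduced_config()) == pytest.approx(1.0)

    def test_penalty_arithmetic_is_exact(self):
        """Duplicating a perfect predictor into k = 10 columns keeps MCC at 1
        and subtracts penalty_weight * (10 - 8)."""
        X, y = perfect_feature_data(p=12)
        for j in range(1, 10):
            X[:, j] = X[:, 0]
        skf = StratifiedKFold(4, shuffle=True, random_state=0)
        splits = list(skf.split(X, y))
        cfg = reduced_config()
        mask = np.zeros(12, bool)
        mask[:10] = True
        assert fitness(mask, X, y, splits, cfg) == pytest.approx(
            1.0 - cfg.penalty_weight * 2)

    def test_empty_mask_sentinel(self):
        X, y = perfect_feature_data()
        assert fitness(np.zeros(25, bool), X, y, [], reduced_config()) == -1.0

    def test_noise_mask_fitness_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 10))
            y = np.array([0.0] * 20 + [1.0] * 20)
            skf = StratifiedKFold(4, shuffle=True, random_state=seed)
            mask = np.zeros(10, bool)
            mask[:3] = True
            vals.append(fitness(mask, X, y, list(skf.split(X, y)),
                                reduced_config()))
        assert -0.2 < np.mean(vals) < 0.2


class TestEvolution:
    def _landscape(self, mask):
        # single perfect feature 0; mild parsimony elsewhere
        return (1.0 if mask[0] else 0.2) - 0.01 * (mask.sum() - mask[0])

    def test_same_seed_identical_trace(self):
        X, y = perfect_feature_data(1)
        cfg = GAConfig(population_size=30, max_generations=8, seed=5)
        r1 = ga_evolve(X, y, [], cfg, fitness_fn=self._landscape)
        r2 = ga_evolve(X, y, [], cfg, fitness_fn=self._landscape)
        np.testing.assert_array_equal(r1.history, r2.history)
        np.testing.assert_array_equal(r1.best_mask, r2.best_mask)

    def test_best_fitness_nondecreasing(self):
        X, y = perfect_feature_data(2)
        cfg = GAConfig(population_size=40, max_generations=15, seed=3)
        res = ga_evolve(X, y, [], cfg, fitness_fn=self._landscape)
        assert (np.diff(res.history) >= 0).all()

    def test_no_variation_operators_keep_initial_best(self):
        X, y = perfect_feature_data(3)
        cfg = GAConfig(population_size=30, max_generations=6, crossover_prob=0.0,
                       mutation_prob_start=0.0, mutation_prob_end=0.0, seed=7)
        res = ga_evolve(X, y, [], cfg, fitness_fn=self._landscape)
        assert res.history[-1] == res.history[0]

    def test_perfect_feature_found_on_small_landscape(self):
        hits = 0
        for seed in range(5):
            X, y = perfect_feature_data(seed)
            cfg = GAConfig(population_size=50, max_generations=12, seed=seed)
            res = ga_evolve(X, y, [], cfg, fitness_fn=self._landscape)
            hits += bool(res.best_mask[0])
        assert hits == 5

    def test_tiny_population_errors(self):
        X, y = perfect_feature_data()
        with pytest.raises(GAError):
            ga_evolve(X, y, [], GAConfig(population_size=1))


class TestNestedCV:
    def test_leakage_contract_heldout_label_flip(self):
        """Perturbing a held-out sample's label never changes its own
        out-of-fold probability (its fold's training set excludes it)."""
        X, y = perfect_feature_data(4, n=24, p=10)
        frame = pd.DataFrame(X)
        cfg = GAConfig(population_size=20, max_generations=4, seed=0)
        n = len(y)
        folds = [(np.setdiff1d(np.arange(n), te), te)
                 for te in np.array_split(np.arange(n), 3)]
        target = folds[0][1][0]
        base = nested_cv(frame, y, cfg, outer=folds, inner=3)
        y2 = y.copy()
        y2[target] = 1 - y2[target]
        flipped = nested_cv(frame, y2, cfg, outer=folds, inner=3)
        assert flipped.oof_probs[target] == pytest.approx(
            base.oof_probs[target], abs=1e-12)

    def test_result_structure_and_frequencies(self):
        X, y = perfect_feature_data(5, n=24, p=8)
        cfg = GAConfig(population_size=20, max_generations=4, seed=1)
        res = nested_cv(pd.DataFrame(X), y, cfg, outer=3, inner=3)
        assert len(res.outer_folds) == 3
        assert np.isfinite(res.oof_probs).all()
        assert ((res.stability_frequency >= 0) & (res.stability_frequency <= 1)).all()
        for fold in res.outer_folds:
            assert set(fold.retained_features) <= set(res.feature_ids)
            # out-of-fold predictions were never produced by a model trained
            # on the held-out samples
            assert set(fold.train_idx).isdisjoint(set(fold.test_idx))

    def test_lost_class_errors(self):
        X, y = perfect_feature_data(6, n=12, p=4)
        folds = [(np.where(y == 0)[0], np.where(y == 1)[0])]
        with pytest.raises(GAError, match="class"):
            nested_cv(pd.DataFrame(X), y, GAConfig(population_size=10,
                                                   max_generations=2),
                      outer=folds, inner=2)


class TestBootstrap:
    def test_perfect_predictor_collapses_cis(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        probs = y.copy()
        b = bootstrap_metrics(probs, y, n_boot=200, seed=0)
        for name, ideal in [("auc", 1.0), ("acc", 1.0), ("f1", 1.0),
                            ("sens", 1.0), ("spec", 1.0), ("mcc", 1.0),
                            ("brier", 0.0)]:
            m = getattr(b, name)
            assert (m.point, m.ci_low, m.ci_high) == (ideal, ideal, ideal)

    def test_cis_contain_point_estimate(self):
        rng = np.random.default_rng(1)
        y = np.array([0.0] * 15 + [1.0] * 15)
        probs = np.clip(y * 0.5 + rng.random(30) * 0.5, 0, 1)
        b = bootstrap_metrics(probs, y, n_boot=300, seed=2)
        for m in vars(b).values():
            assert m.ci_low <= m.point <= m.ci_high

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (20, 200):
            y = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
            probs = np.clip(0.3 + 0.4 * y + rng.normal(0, 0.15, n), 0, 1)
            b = bootstrap_metrics(probs, y, n_boot=300, seed=4)
            widths.append(b.auc.ci_high - b.auc.ci_low)
        assert widths[1] < widths[0]

    def test_single_class_errors(self):
        with pytest.raises(GAError):
            bootstrap_metrics([0.5, 0.6], [1.0, 1.0], n_boot=10)
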