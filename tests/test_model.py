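"""PLS fitting, cross-validation harness, component scan and benchmark."""

import numpy as np
import pytest

from ncaabind import model
from ncaabind.model import (
    AffinityModel,
    RegressorSpec,
    back_transform,
    benchmark_regressors,
    cross_validate,
    fit_pls,
    make_folds,
    scan_components,
    transform_target,
)


class TestTargetTransform:
    @pytest.mark.parametrize(
        "ic50,expected", [(1.0, 0.0), (1000.0, 3.0), (65000.0, 4.8129)]
    )
    def test_log10_scale(self, ic50, expected):
        assert transform_target(ic50) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.0, -5.0, np.nan])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            transform_target(bad)

    def test_round_trip_with_back_transform(self):
        y = np.array([0.5, 2.0, 4.8])
        np.testing.assert_allclose(transform_target(back_transform(y)), y, atol=1e-10)


def linear_problem(n=30, p=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 1.5 + noise * rng.normal(size=n)
    return X, y


class TestFitPLS:
    def test_exact_fit_at_full_rank(self):
        X, y = linear_problem()
        m = fit_pls(X, y, n_components=6)
        r2 = 1 - np.sum((y - m.predict(X)) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_full_component_pls_equals_ols(self):
        """With as many components as predictors, PLS predictions coincide
        with the ordinary-least-squares solution from the normal equations."""
        X, y = linear_problem(n=25, p=5, seed=2, noise=0.3)
        m = fit_pls(X, y, n_components=5)
        X1 = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
        np.testing.assert_allclose(m.predict(X), X1 @ beta, atol=1e-6)

    def test_single_planted_factor_recovered(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=(80, 1))
        loadings = rng.normal(size=(1, 40))
        X = t @ loadings + 0.01 * rng.normal(size=(80, 40))
        y = t.ravel() * 2.0 + 0.01 * rng.normal(size=80)
        m = fit_pls(X, y, n_components=1, scale_x=False)
        score = m._x_scores[:, 0]
        cosine = np.abs(score @ t.ravel()) / (
            np.linalg.norm(score) * np.linalg.norm(t)
        )
        assert cosine > 0.99

    def test_mean_input_predicts_mean_response(self):
        X, y = linear_problem(noise=0.5, seed=4)
        m = fit_pls(X, y, n_components=3)
        assert m.predict(X.mean(axis=0, keepdims=True))[0] == pytest.approx(
            y.mean(), abs=1e-8
        )

    def test_component_nesting(self):
        """NIPALS deflation: the first c' latent scores of a c-component fit
        equal the scores of a c'-component fit."""
        X, y = linear_problem(n=40, p=8, seed=5, noise=0.2)
        big = fit_pls(X, y, n_components=6)
        small = fit_pls(X, y, n_components=3)
        np.testing.assert_allclose(big._x_scores[:, :3], small._x_scores, atol=1e-8)

    def test_constant_columns_tolerated(self):
        X, y = linear_problem(n=30, p=4, seed=6, noise=0.1)
        Xpad = np.hstack([X, np.zeros((30, 3))])
        m = fit_pls(Xpad, y, n_components=4)
        assert np.all(np.isfinite(m.predict(Xpad)))
        np.testing.assert_array_equal(m.coefficients[4:], np.zeros(3))

    def test_too_few_samples_rejected(self):
        X, y = linear_problem(n=5, p=6)
        with pytest.raises(ValueError):
            fit_pls(X, y, n_components=6)

    def test_serialization_round_trip_identical_predictions(self, tmp_path):
        X, y = linear_problem(noise=0.2, seed=7)
        m = fit_pls(X, y, n_components=3)
        path = tmp_path / "model.json"
        m.save(path)
        again = AffinityModel.load(path)
        np.testing.assert_array_equal(again.predict(X), m.predict(X))

    def test_width_mismatch_rejected(self):
        X, y = linear_problem()
        m = fit_pls(X, y, n_components=2)
        with pytest.raises(ValueError, match="width"):
            m.predict(np.zeros((3, 4)))


class TestFolds:
    @pytest.mark.parametrize("n,k", [(10, 5), (23, 5), (150, 5), (7, 3)])
    def test_partition_disjoint_near_equal(self, n, k):
        folds = make_folds(n, k, seed=11)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(n))
        sizes = [len(t) for _, t in folds]
        assert max(sizes) - min(sizes) <= 1
        for train, test in folds:
            assert set(train) & set(test) == set()
            assert len(train) + len(test) == n

    def test_seed_determines_split(self):
        a = make_folds(50, 5, seed=1)
        b = make_folds(50, 5, seed=1)
        c = make_folds(50, 5, seed=2)
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
        assert any(
            not np.array_equal(ta, tc) for (_, ta), (_, tc) in zip(a, c)
        )


class _Oracle:
    """Test double: answers with the true y for any memorized row."""

    def __init__(self, X, y):
        self.table = {row.tobytes(): val for row, val in zip(X, y)}

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.table[row.tobytes()] for row in X])


class _TrainMean:
    def fit(self, X, y):
        self.mean = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean)


class TestCrossValidate:
    def test_oracle_predictor_perfect_scores(self):
        X, y = linear_problem(n=40, noise=0.5, seed=8)
        cv = cross_validate(X, y, lambda: _Oracle(X, y), k=5, seed=0)
        assert cv.mean_r2 == pytest.approx(1.0)
        assert cv.mean_rmse == pytest.approx(0.0, abs=1e-12)
        assert all(f["test_r2"] == pytest.approx(1.0) for f in cv.per_fold)

    def test_train_mean_predictor_nonpositive_r2(self):
        X, y = linear_problem(n=60, noise=0.5, seed=9)
        cv = cross_validate(X, y, _TrainMean, k=5, seed=0)
        assert cv.mean_r2 <= 0.0

    def test_metrics_match_loop_free_re_evaluation(self):
        """Harness metrics agree with refitting each fold by hand outside it."""
        X, y = linear_problem(n=45, p=6, seed=10, noise=0.4)
        seed = 13
        cv = cross_validate(X, y, n_components=3, k=5, seed=seed)
        for (train, test), fold in zip(make_folds(45, 5, seed), cv.per_fold):
            m = fit_pls(X[train], y[train], n_components=3)
            pred = m.predict(X[test])
            sst = np.sum((y[test] - y[test].mean()) ** 2)
            assert fold["test_r2"] == pytest.approx(
                1 - np.sum((y[test] - pred) ** 2) / sst, abs=1e-10
            )
            assert fold["test_rmse"] == pytest.approx(
                np.sqrt(np.mean((y[test] - pred) ** 2)), abs=1e-10
            )
        assert cv.mean_r2 == pytest.approx(
            np.mean([f["test_r2"] for f in cv.per_fold])
        )

    def test_tiny_fold_rejected(self):
        X, y = linear_problem(n=6)
        with pytest.raises(ValueError, match="undefined"):
            cross_validate(X, y, n_components=2, k=6, seed=0)


class TestScan:
    def test_identical_folds_across_component_counts(self):
        """The scan's per-component results are comparable because every row
        used the same seeded split; re-running reproduces the table."""
        X, y = linear_problem(n=50, p=8, seed=12, noise=0.3)
        a = scan_components(X, y, range(2, 6), seed=3)
        b = scan_components(X, y, range(2, 6), seed=3)
        assert a.equals(b)

    def test_single_best_row_flagged(self):
        X, y = linear_problem(n=50, p=8, seed=12, noise=0.3)
        table = scan_components(X, y, range(2, 8), seed=3)
        assert table["best"].sum() == 1
        best = table.loc[table["best"], "mean_r2"].iloc[0]
        assert best == table["mean_r2"].max()


class TestBenchmark:
    def test_oracle_outranks_constant_in_every_cycle(self):
        X, y = linear_problem(n=40, noise=0.5, seed=14)
        specs = [
            RegressorSpec("oracle", lambda: _Oracle(X, y)),
            RegressorSpec("constant", _TrainMean),
        ]
        table = benchmark_regressors(X, y, specs, k=5, seed=0)
        oracle_rows = table[table.regressor == "oracle"]
        assert (oracle_rows["rank"] == 1).all()

    def test_same_seed_reproduces_table(self):
        X, y = linear_problem(n=40, noise=0.5, seed=15)
        specs = [RegressorSpec("constant", _TrainMean)]
        a = benchmark_regressors(X, y, specs, k=5, seed=4)
        b = benchmark_regressors(X, y, specs, k=5, seed=4)
        assert a.equals(b)

    def test_failing_regressor_recorded_not_fatal(self):
        X, y = linear_problem(n=40, seed=16)

        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        table = benchmark_regressors(
            X, y, [RegressorSpec("broken", Broken), RegressorSpec("constant", _TrainMean)],
            k=5, seed=0,
        )
        broken = table[table.regressor == "broken"]
        assert broken["error"].str.contains("boom").all()
        assert np.isnan(broken["test_r2"]).all()

    def test_ranking_matches_independent_re_run(self):
        X, y = linear_problem(n=50, p=8, seed=17, noise=0.4)
        specs = model.default_regressor_specs(seed=0)[:4]
        table = benchmark_regressors(X, y, specs, k=5, seed=5)
        for train, test in [make_folds(50, 5, 5)[0]]:
            for spec in specs:
                est = spec.build()
                est.fit(X[train], y[train])
                pred = np.ravel(est.predict(X[test]))
                sst = np.sum((y[test] - y[test].mean()) ** 2)
                want = 1 - np.sum((y[test] - pred) ** 2) / sst
                got = table[(table.cycle == 1) & (table.regressor == spec.name)][
                    "test_r2"
                ].iloc[0]
                assert got == pytest.approx(want, abs=1e-10)
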