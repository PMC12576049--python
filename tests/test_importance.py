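import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survexplain import (AnalyticModel, KaplanMeierModel, TimeGrid,
                         brier_loss, cpi, holm_adjust, importance_inference,
                         loco, pfi, sample_knockoffs)
from survexplain.importance import ImportanceResult
from survexplain.metrics import LossCurve

from conftest import make_dataset


def x1_model():
    return AnalyticModel(
        lambda t, X: np.exp(-np.outer(np.exp(X["x1"].to_numpy()), t)))


@pytest.fixture
def censored_two_feature():
    rng = np.random.default_rng(11)
    n = 150
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    T = rng.exponential(1.0, n) * np.exp(-X["x1"].to_numpy())
    C = rng.exponential(2.5, n)
    return make_dataset(np.maximum(np.minimum(T, C), 1e-6), (T <= C).astype(int), X)


class TestPFI:
    def test_ignored_feature_importance_exactly_zero(self, censored_two_feature):
        ds = censored_two_feature
        grid = TimeGrid(np.quantile(ds.times, [0.3, 0.6]))
        res = pfi(x1_model(), ds, brier_loss(ds), n_repeats=3,
                  time_grid=grid, seed=1)
        by = {r.feature: r for r in res}
        np.testing.assert_array_equal(by["x2"].fi_d, 0.0)
        assert by["x1"].time_average > 0

    def test_exhaustive_enumeration_matches_formula(self):
        # n=3: averaging over all 6 permutations of the column
        X = pd.DataFrame({"x1": [0.0, 1.0, 2.0],
                          "pad": [0.0, 0.0, 1.0]})
        ds = make_dataset([1.0, 2.0, 3.0], [1, 1, 1], X)
        grid = TimeGrid([1.5])
        loss = brier_loss(ds)
        model = x1_model()
        res = pfi(model, ds, loss, n_repeats="all", time_grid=grid)
        by = {r.feature: r for r in res}
        from itertools import permutations

        vals = []
        base = loss(ds, model.predict_survival(X, grid), grid).values
        for perm in permutations(range(3)):
            Xp = X.copy()
            Xp["x1"] = X["x1"].to_numpy()[list(perm)]
            vals.append(loss(ds, model.predict_survival(Xp, grid), grid).values
                        - base)
        np.testing.assert_allclose(by["x1"].fi_d, np.mean(vals, axis=0),
                                   atol=1e-14)

    def test_featureless_km_predictor_all_zero(self, censored_two_feature):
        ds = censored_two_feature
        model = KaplanMeierModel().fit(ds)
        grid = TimeGrid(np.quantile(ds.times, [0.3, 0.6]))
        res = pfi(model, ds, brier_loss(ds), n_repeats=2, time_grid=grid)
        for r in res:
            np.testing.assert_array_equal(r.fi_d, 0.0)

    def test_difference_and_quotient_rank_agree(self, censored_two_feature):
        ds = censored_two_feature
        grid = TimeGrid(np.quantile(ds.times, [0.4]))
        res = pfi(x1_model(), ds, brier_loss(ds), n_repeats=5,
                  time_grid=grid, seed=2)
        by_d = sorted(res, key=lambda r: -r.time_average)
        by_q = sorted(res, key=lambda r: -np.nanmean(r.fi_q))
        assert [r.feature for r in by_d] == [r.feature for r in by_q]


class TestKnockoffs:
    def test_independent_columns_covariance_structure(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((5000, 3)),
                         columns=["a", "b", "c"])
        ko = sample_knockoffs(X, seed=1)
        # s = min(1, 2*lambda_min) ~ 1 for independent columns, so
        # cov(X_j, knockoff_j) ~ 1 - s_j ~ 0
        for j, c in enumerate(X.columns):
            emp = np.cov(X[c], ko.values[c])[0, 1]
            assert emp == pytest.approx(1 - ko.s[j], abs=0.05)

    def test_single_column_marginal_preserved(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.standard_normal(5000) * 2 + 1})
        ko = sample_knockoffs(X, seed=4)
        ks = stats.ks_2samp(X["a"], ko.values["a"])
        assert ks.pvalue > 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        k1 = sample_knockoffs(X, seed=9)
        k2 = sample_knockoffs(X, seed=9)
        pd.testing.assert_frame_equal(k1.values, k2.values)

    def test_correlated_columns_preserve_cross_covariance(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(6000)
        X = pd.DataFrame({"a": z + 0.3 * rng.standard_normal(6000),
                          "b": z + 0.3 * rng.standard_normal(6000)})
        ko = sample_knockoffs(X, seed=7)
        # cross covariances cov(knockoff_a, b) should match cov(a, b)
        assert np.cov(ko.values["a"], X["b"])[0, 1] == pytest.approx(
            np.cov(X["a"], X["b"])[0, 1], abs=0.1)


class TestCPI:
    def test_null_feature_small_importance(self, censored_two_feature):
        ds = censored_two_feature
        grid = TimeGrid(np.quantile(ds.times, [0.3, 0.6]))
        res = cpi(x1_model(), ds, brier_loss(ds), seed=0, time_grid=grid)
        by = {r.feature: r for r in res}
        np.testing.assert_array_equal(by["x2"].fi_d, 0.0)  # model ignores x2
        assert by["x2"].p_value > 0.2

    def test_degenerate_knockoff_gives_exact_zero(self, censored_two_feature):
        from survexplain.importance import KnockoffMatrix

        ds = censored_two_feature
        grid = TimeGrid(np.quantile(ds.times, [0.4]))
        identity = KnockoffMatrix(ds.features.copy(), "identity", 0)
        res = cpi(x1_model(), ds, brier_loss(ds), seed=0, time_grid=grid,
                  knockoffs=identity)
        for r in res:
            np.testing.assert_array_equal(r.fi_d, 0.0)
            assert r.p_value == 1.0

    def test_correlated_cpi_attenuated_versus_pfi(self):
        # under strong correlation, conditional resampling keeps the
        # correlated partner's information, so CPI(x1) < PFI(x1)
        rng = np.random.default_rng(21)
        n = 400
        z = rng.standard_normal(n)
        X = pd.DataFrame({"x1": z + 0.2 * rng.standard_normal(n),
                          "x2": z + 0.2 * rng.standard_normal(n)})
        T = rng.exponential(1.0, n) * np.exp(-X["x1"].to_numpy())
        ds = make_dataset(np.maximum(T, 1e-6), np.ones(n, int), X)
        grid = TimeGrid(np.quantile(ds.times, [0.3, 0.6]))
        loss = brier_loss(ds)
        model = x1_model()
        p = {r.feature: r for r in pfi(model, ds, loss, n_repeats=10,
                                       time_grid=grid, seed=1)}
        c = {r.feature: r for r in cpi(model, ds, loss, seed=1,
                                       time_grid=grid)}
        assert c["x1"].time_average < p["x1"].time_average


class TestLOCO:
    def test_requires_refit_capability(self, censored_two_feature):
        ds = censored_two_feature
        with pytest.raises(TypeError):
            loco(x1_model(), ds, ds, brier_loss(ds))

    def test_informative_feature_dominates_noise(self):
        from survexplain import CoxModel

        rng = np.random.default_rng(31)
        n = 500
        X = pd.DataFrame({"signal": rng.normal(size=n),
                          "noise": rng.normal(size=n)})
        T = rng.exponential(1.0, n) * np.exp(-X["signal"].to_numpy())
        ds = make_dataset(np.maximum(T, 1e-6), np.ones(n, int), X)
        tr = ds.subset(np.arange(0, 350))
        te = ds.subset(np.arange(350, n))
        model = CoxModel().fit(tr)
        grid = TimeGrid(np.quantile(te.times, [0.25, 0.5, 0.75]))
        res = loco(model, tr, te, brier_loss(tr), time_grid=grid)
        by = {r.feature: r for r in res}
        assert by["signal"].time_average > by["noise"].time_average
        assert by["signal"].time_average > 0
        assert abs(by["noise"].time_average) < 0.02


class TestInference:
    def test_all_zero_differences_never_significant(self):
        res = _dummy_result(np.zeros(20))
        assert importance_inference(res) == 1.0

    def test_t_statistic_matches_hand_computation(self):
        d = np.array([0.02, 0.05, 0.01, 0.03, 0.04])
        res = _dummy_result(d)
        p = importance_inference(res, kind="t")
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        expected = 1 - stats.t.cdf(t, df=4)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_holm_adjustment_monotone_and_bounded(self):
        raw = np.array([0.01, 0.04, 0.3, 0.9])
        adj = holm_adjust(raw)
        assert np.all(adj >= raw)
        assert np.all(adj <= 1.0)
        np.testing.assert_allclose(adj, [0.04, 0.12, 0.6, 0.9])


def _dummy_result(diffs):
    grid = TimeGrid([1.0])
    base = LossCurve(grid, np.array([0.2]))
    return ImportanceResult("f", grid, np.array([0.0]), np.array([1.0]),
                            np.zeros((1, 1)), base, "cpi",
                            per_observation_diff=diffs)


class TestSpecifiedBehaviours:
    def test_cpi_power_on_strong_effect(self):
        """A genuinely predictive feature is flagged significant across the
        vast majority of knockoff seeds."""
        from survexplain import CoxModel, SimulationConfig, simulate
        from survexplain import train_test_split

        ds = simulate(SimulationConfig.td_treatment(n=3000, seed=61))
        tr, te = train_test_split(ds, 0.3, seed=62)
        model = CoxModel().fit(tr)
        grid = TimeGrid.from_dataset(te, max_points=20)
        loss = brier_loss(tr)
        hits = 0
        for seed in range(20):
            res = {r.feature: r for r in cpi(model, te, loss, seed=seed,
                                             time_grid=grid,
                                             features=["treatment"])}
            hits += res["treatment"].p_value < 0.05
        assert hits >= 19

    def test_loco_redundant_copy_carries_no_unique_information(self):
        """Removing one of two duplicated columns costs nothing; removing
        the duplicated signal entirely does."""
        from survexplain import CoxModel

        rng = np.random.default_rng(63)
        n = 600
        sig = rng.normal(size=n)
        X = pd.DataFrame({"sig": sig, "sig_copy": sig.copy(),
                          "noise": rng.normal(size=n)})
        T = rng.exponential(1.0, n) * np.exp(-sig)
        ds = make_dataset(np.maximum(T, 1e-6), np.ones(n, int), X)
        tr = ds.subset(np.arange(0, 400))
        te = ds.subset(np.arange(400, n))
        model = CoxModel(alpha=1e-2).fit(tr)
        grid = TimeGrid(np.quantile(te.times, [0.25, 0.5, 0.75]))
        loss = brier_loss(tr)
        res = {r.feature: r for r in loco(model, tr, te, loss,
                                          time_grid=grid)}
        # both-copies-removed loss increase, via a model on noise only
        both_out = model.refit(tr.drop_feature("sig").drop_feature("sig_copy"))
        preds = both_out.predict_survival(te.features[["noise"]], grid)
        full_preds = model.predict_survival(te.features, grid)
        gap = (loss(te, preds, grid).values
               - loss(te, full_preds, grid).values).mean()
        assert res["sig_copy"].time_average < gap

    def test_pfi_near_zero_before_first_events(self):
        """Before essentially any events have occurred the Brier score has
        nothing to distinguish, so importance starts near zero."""
        from survexplain import (RandomSurvivalForestModel, SimulationConfig,
                                 simulate, train_test_split)

        ds = simulate(SimulationConfig.td_treatment(n=1500, seed=64))
        tr, te = train_test_split(ds, 0.3, seed=65)
        model = RandomSurvivalForestModel(random_state=64).fit(tr)
        t_early = float(np.quantile(te.times[te.events == 1], 0.01))
        grid = TimeGrid([t_early] + list(
            np.quantile(te.times[te.events == 1], [0.3, 0.6])))
        res = pfi(model, te, brier_loss(tr), n_repeats=3, time_grid=grid,
                  seed=0)
        for r in res:
            assert abs(r.fi_d[0]) < 0.005
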