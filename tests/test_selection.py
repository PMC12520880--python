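"""Feature-selection cascade: univariate screen, correlation pruning and
cross-validated lasso."""

import itertools

import numpy as np
import pandas as pd
import pytest

from habitatmri.selection import (
    SelectionCascade,
    correlation_prune,
    lasso_select,
    univariate_filter,
)


def exact_mannwhitney_p(a, b):
    """Two-sided p by enumerating every group assignment of the pooled
    sample (valid for small tie-free samples)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    def u_stat(group):
        r = sum(ranks[v] for v in group)
        return r - n_a * (n_a + 1) / 2
    u_obs = u_stat(a)
    d_obs = abs(u_obs - len(a) * len(b) / 2)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        group = pooled[list(combo)]
        d = abs(u_stat(group) - len(a) * len(b) / 2)
        count += d >= d_obs - 1e-12
        total += 1
    return count / total


class TestUnivariateFilter:
    def test_identical_groups_p_one_dropped(self):
        table = pd.DataFrame({"f": [1.0] * 10})
        kept, p = univariate_filter(table, np.array([0] * 5 + [1] * 5))
        assert kept == [] and p["f"] == 1.0

    def test_extreme_separation_small_groups(self):
        # U = 0; the exact two-sided p for 3 vs 3 is 2/20 = 0.1
        table = pd.DataFrame({"f": [1, 2, 3, 10, 11, 12.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        kept, p = univariate_filter(table, y, alpha=0.05)
        assert p["f"] == pytest.approx(0.1, abs=1e-12)
        assert kept == []  # 0.1 is not < 0.05

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exact_enumeration_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(3, 7, 2)
        a = rng.normal(size=n_a)
        b = rng.normal(loc=rng.normal(), size=n_b)
        table = pd.DataFrame({"f": np.concatenate([a, b])})
        y = np.array([0] * n_a + [1] * n_b)
        _, p = univariate_filter(table, y)
        assert p["f"] == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-9)

    def test_power_at_unit_shift(self):
        retained = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame({"f": np.concatenate(
                [rng.normal(0, 1, 400), rng.normal(1, 1, 400)])})
            y = np.array([0] * 400 + [1] * 400)
            kept, _ = univariate_filter(table, y)
            retained += kept == ["f"]
        assert retained >= 29  # >= 99% nominal power, allow one failure

    def test_anova_variant(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"f": np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(2, 1, 50)])})
        y = np.array([0] * 50 + [1] * 50)
        kept, _ = univariate_filter(table, y, method="anova")
        assert kept == ["f"]


class TestCorrelationPrune:
    def test_exact_duplicates_keep_one(self, rng):
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        p = pd.Series({"a": 0.01, "b": 0.02, "c": 0.03})
        kept, dropped = correlation_prune(table, p)
        assert kept == ["a", "c"]
        assert dropped[0][:2] == ("b", "a")

    def test_independent_features_all_kept(self, rng):
        table = pd.DataFrame(rng.normal(size=(2000, 6)),
                             columns=list("abcdef"))
        p = pd.Series(np.linspace(0.001, 0.04, 6), index=list("abcdef"))
        kept, _ = correlation_prune(table, p)
        assert kept == list("abcdef")

    def test_chain_keeps_endpoints(self, rng):
        # A~B and B~C above threshold, A~C below: greedy keeps {A, C}
        n = 4000
        a = rng.normal(size=n)
        c = 0.82 * a + np.sqrt(1 - 0.82**2) * rng.normal(size=n)
        resid = a + c
        b = resid / resid.std() * 1.0
        b = b + rng.normal(size=n) * 0.12
        table = pd.DataFrame({"a": a, "b": b, "c": c})
        corr = table.corr().abs()
        assert corr.loc["a", "b"] > 0.9 and corr.loc["b", "c"] > 0.9
        assert corr.loc["a", "c"] <= 0.9
        p = pd.Series({"a": 0.01, "b": 0.02, "c": 0.03})
        kept, _ = correlation_prune(table, p)
        assert kept == ["a", "c"]

    def test_zero_variance_excluded(self, rng):
        table = pd.DataFrame({"flat": np.ones(20), "x": rng.normal(size=20)})
        p = pd.Series({"flat": 0.001, "x": 0.01})
        kept, _ = correlation_prune(table, p)
        assert kept == ["x"]


class TestLassoSelect:
    def _planted(self, seed, n=500, n_noise=48):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2 + n_noise))
        lin = 1.0 * X[:, 0] - 1.0 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        cols = ["inf_0", "inf_1"] + [f"noise_{i}" for i in range(n_noise)]
        return pd.DataFrame(X, columns=cols), y

    def test_large_lambda_end_of_path_all_zero(self):
        X, y = self._planted(0)
        rep = lasso_select(X, y, seed=0)
        # at lambda_max (grid start) every coefficient shrinks to zero
        from sklearn.linear_model import Lasso
        Z = (X - X.mean()) / X.std(ddof=0)
        model = Lasso(alpha=rep.lambda_grid[0]).fit(Z, y.astype(float))
        assert np.allclose(model.coef_, 0.0)

    def test_determinism(self):
        X, y = self._planted(1)
        a = lasso_select(X, y, seed=5)
        b = lasso_select(X, y, seed=5)
        assert a.chosen_lambda == b.chosen_lambda
        assert a.coefficients == b.coefficients

    def test_chosen_lambda_minimizes_recorded_mse(self):
        X, y = self._planted(2)
        rep = lasso_select(X, y, seed=2)
        assert rep.chosen_lambda == rep.lambda_grid[np.argmin(rep.cv_mse)]

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError):
            lasso_select(X, np.ones(20, dtype=int))

    def test_lambda_zero_limit_approaches_ols(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        beta = np.array([0.5, -0.7, 0.2])
        y01 = (X.values @ beta + rng.normal(0, 0.5, n) > 0).astype(int)
        rep = lasso_select(X, y01, seed=0, lambda_min_ratio=1e-6)
        from numpy.linalg import lstsq
        Z = (X - X.mean()) / X.std(ddof=0)
        Zc = np.column_stack([np.ones(n), Z.values])
        ols = lstsq(Zc, y01.astype(float), rcond=None)[0][1:]
        # smallest-lambda fit is close to OLS on standardized features
        from sklearn.linear_model import Lasso
        small = Lasso(alpha=rep.lambda_grid[-1], max_iter=100_000).fit(
            Z.values, y01.astype(float))
        assert np.allclose(small.coef_, ols, atol=0.02)


class TestCascade:
    def test_stage_containment(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 20)),
                         columns=[f"f{i}" for i in range(20)])
        X["f0"] += np.repeat([0, 1.2], 60)
        y = np.array([0] * 60 + [1] * 60)
        casc = SelectionCascade(seed=0).fit(X, y)
        rep = casc.report_
        assert set(rep.selected_features) <= set(rep.after_pruning)
        assert set(rep.after_pruning) <= set(rep.after_univariate)
        assert set(rep.after_univariate) <= set(rep.input_features)

    def test_missing_rows_imputed(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"f{i}" for i in range(5)])
        X.iloc[0, 0] = np.nan
        X["f1"] += np.repeat([0, 1.5], 30)
        y = np.array([0] * 30 + [1] * 30)
        casc = SelectionCascade(seed=0).fit(X, y)
        out = casc.transform(X)
        assert np.isfinite(out.to_numpy()).all()

    def test_radscore_is_linear_in_selected_features(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=[f"f{i}" for i in range(6)])
        X["f2"] += np.repeat([0, 1.5], 100)
        y = np.array([0] * 100 + [1] * 100)
        casc = SelectionCascade(seed=1).fit(X, y)
        if not casc.selected_features_:
            pytest.skip("no feature survived on this draw")
        s1 = casc.radscore(X)
        X2 = X.copy()
        other = [c for c in X.columns if c not in casc.selected_features_]
        X2[other] += 100.0  # unselected features must not move the score
        assert np.allclose(casc.radscore(X2), s1)


def test_lasso_recovery_of_planted_features():
    """2 informative features among 50 recovered in >= 90% of seeds."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(500, 50))
        lin = 1.0 * X[:, 0] - 1.0 * X[:, 1]
        y = (rng.random(500) < 1 / (1 + np.exp(-lin))).astype(int)
        cols = ["inf_0", "inf_1"] + [f"n{i}" for i in range(48)]
        rep = lasso_select(pd.DataFrame(X, columns=cols), y, seed=seed)
        hits += {"inf_0", "inf_1"} <= set(rep.selected_features)
    assert hits >= 18
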