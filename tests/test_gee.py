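"""Exchangeable-correlation GEE: oracles, edge cases, test families."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tugkin.gee import (
    fit_gee_exchangeable,
    test_bias_vs_zero,
    test_rmse_vs_lowest,
)


def brute_force_gee(y, clusters, levels, level_order, n_iter=200):
    """Independent estimating-equation solve with dense matrices.

    Same moment equations as the shipped solver, but built from explicit
    block matrices and ``np.linalg.inv`` of the full exchangeable
    correlation matrix — no shared code path.
    """
    y = np.asarray(y, float)
    ids = list(dict.fromkeys(clusters))
    col = {lev: j for j, lev in enumerate(level_order)}
    p = len(level_order)
    groups = []
    for cid in ids:
        idx = [i for i, c in enumerate(clusters) if c == cid]
        Xi = np.zeros((len(idx), p))
        for row, i in enumerate(idx):
            Xi[row, col[levels[i]]] = 1.0
        groups.append((Xi, y[idx]))
    X = np.vstack([g[0] for g in groups])
    beta = np.linalg.pinv(X) @ y
    N = len(y)
    rho = 0.0
    for _ in range(n_iter):
        ssr = sum(float((yi - Xi @ beta) @ (yi - Xi @ beta)) for Xi, yi in groups)
        scale = ssr / (N - p)
        num, pairs = 0.0, 0
        for Xi, yi in groups:
            r = yi - Xi @ beta
            for a in range(len(r)):
                for b in range(a + 1, len(r)):
                    num += r[a] * r[b]
                    pairs += 1
        rho = num / (scale * (pairs - p)) if scale > 0 and pairs - p > 0 else 0.0
        A = np.zeros((p, p))
        rhs = np.zeros(p)
        for Xi, yi in groups:
            n = len(yi)
            R = (1 - rho) * np.eye(n) + rho * np.ones((n, n))
            Rinv = np.linalg.inv(R)
            A += Xi.T @ Rinv @ Xi
            rhs += Xi.T @ Rinv @ yi
        beta = np.linalg.solve(A, rhs)
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for Xi, yi in groups:
        n = len(yi)
        R = (1 - rho) * np.eye(n) + rho * np.ones((n, n))
        Rinv = np.linalg.inv(R)
        B += Xi.T @ Rinv @ Xi
        g = Xi.T @ Rinv @ (yi - Xi @ beta)
        M += np.outer(g, g)
    cov = np.linalg.inv(B) @ M @ np.linalg.inv(B)
    return beta, cov, rho


def _clustered_data(rng, m, levels, rho, sigma=1.0, means=None, n_per_level=1):
    means = means or {lev: 0.0 for lev in levels}
    rows = []
    for i in range(m):
        u = rng.normal(0, np.sqrt(rho) * sigma)
        for lev in levels:
            for _ in range(n_per_level):
                rows.append(
                    (f"c{i}", lev, means[lev] + u + rng.normal(0, np.sqrt(1 - rho) * sigma))
                )
    return pd.DataFrame(rows, columns=["cluster", "level", "y"])


class TestFitGee:
    def test_constant_responses_give_exact_mean_and_zero_se(self):
        y = np.full(12, 4.2)
        cl = np.repeat(["a", "b", "c"], 4)
        lev = np.tile(["p", "q"], 6)
        fit = fit_gee_exchangeable(y, cl, lev)
        np.testing.assert_allclose(fit.beta, 4.2, atol=1e-12)
        np.testing.assert_allclose(fit.se, 0.0, atol=1e-12)

    def test_one_observation_per_cluster_closed_form(self):
        """Single level, one obs per cluster: LS mean is the grand mean and
        the robust SE is sqrt(sum (y_i - ybar)^2) / m."""
        y = np.array([1.0, 3.0, 2.0, 6.0, 4.0])
        m = len(y)
        fit = fit_gee_exchangeable(y, [f"c{i}" for i in range(m)], ["p"] * m)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-12)
        expected_se = np.sqrt(np.sum((y - y.mean()) ** 2)) / m
        assert fit.se[0] == pytest.approx(expected_se, abs=1e-12)
        assert fit.rho == 0.0  # no within-cluster pairs exist

    def test_matches_brute_force_on_small_unbalanced_data(self, rng):
        """<=5 clusters, unbalanced: LS means to 1e-6, sandwich SEs to 1e-4
        relative, against the dense-matrix oracle."""
        levels = ["A", "B"]
        rows = []
        for i, sizes in enumerate([3, 2, 4, 1, 5]):
            u = rng.normal(0, 1)
            for k in range(sizes):
                lev = levels[k % 2]
                rows.append((f"c{i}", lev, (1.5 if lev == "B" else 0.0) + u + rng.normal(0, 0.7)))
        df = pd.DataFrame(rows, columns=["cluster", "level", "y"])
        fit = fit_gee_exchangeable(df.y, df.cluster, df.level, level_order=levels)
        beta, cov, rho = brute_force_gee(df.y.tolist(), df.cluster.tolist(), df.level.tolist(), levels)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-6)
        se = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(fit.se, se, rtol=1e-4)
        assert fit.rho == pytest.approx(rho, abs=1e-6)

    def test_matches_statsmodels_on_balanced_data(self, rng):
        import statsmodels.api as sm

        df = _clustered_data(rng, m=10, levels=["A", "B", "C"], rho=0.4,
                             means={"A": 0, "B": 1, "C": 2})
        fit = fit_gee_exchangeable(df.y, df.cluster, df.level, level_order=["A", "B", "C"])
        X = pd.get_dummies(df.level)[["A", "B", "C"]].to_numpy(float)
        smfit = sm.GEE(
            df.y, X, groups=df.cluster, cov_struct=sm.cov_struct.Exchangeable()
        ).fit()
        np.testing.assert_allclose(fit.beta, smfit.params.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.se, smfit.bse.to_numpy(), rtol=1e-4)

    def test_recovers_exchangeable_correlation(self, rng):
        """Moment estimator is consistent: averaged over replicate datasets
        of 200 clusters, the estimated working correlation is within 0.05
        of the true 0.5."""
        estimates = []
        for _ in range(5):
            df = _clustered_data(rng, m=200, levels=["A"], rho=0.5, n_per_level=4)
            fit = fit_gee_exchangeable(df.y, df.cluster, df.level)
            estimates.append(fit.rho)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.05)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            fit_gee_exchangeable([1.0, 2.0], ["c0", "c0"], ["p", "p"])

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError):
            fit_gee_exchangeable(
                [1.0, 2.0], ["c0", "c1"], ["p", "p"], level_order=["p", "q"]
            )


class TestBiasVsZero:
    def test_zero_mean_unit_se_gives_p_one(self):
        fit = fit_gee_exchangeable(
            [1.0, -1.0, 2.0, -2.0], ["a", "b", "c", "d"], ["p"] * 4
        )
        res = test_bias_vs_zero(fit)
        assert res.p_value[0] == pytest.approx(1.0, abs=1e-9)

    def test_normal_quantile(self):
        """An LS mean at 1.96 standard errors has p = 0.05."""
        from tugkin.gee import GeeFit

        fit = GeeFit(
            levels=["p"], beta=np.array([1.96]), cov=np.array([[1.0]]),
            rho=0.0, scale=1.0, n_clusters=5, n_obs=5, n_iter=1, converged=True,
        )
        res = test_bias_vs_zero(fit)
        assert res.p_value[0] == pytest.approx(0.05, abs=0.001)
        assert not res.highlighted[0]

    def test_zero_se_edge_cases(self):
        from tugkin.gee import GeeFit

        biased = GeeFit(["p"], np.array([2.0]), np.zeros((1, 1)), 0.0, 0.0, 3, 3, 1, True)
        unbiased = GeeFit(["p"], np.array([0.0]), np.zeros((1, 1)), 0.0, 0.0, 3, 3, 1, True)
        assert test_bias_vs_zero(biased).p_value[0] == 0.0
        assert test_bias_vs_zero(unbiased).p_value[0] == 1.0


class TestRmseVsLowest:
    def test_identical_pairs_contrast_p_one(self):
        y = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]
        cl = ["a", "a", "b", "b", "c", "c"]
        lev = ["p", "q"] * 3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # deliberate tie
            res = test_rmse_vs_lowest(fit_gee_exchangeable(y, cl, lev))
        other = res[~res.is_lowest].iloc[0]
        assert other.p_value == pytest.approx(1.0)
        assert other.highlighted

    def test_lowest_pair_is_marked_na(self):
        rng = np.random.default_rng(5)
        df = _clustered_data(rng, m=6, levels=["lo", "hi"], rho=0.2,
                             means={"lo": 2.0, "hi": 6.0})
        res = test_rmse_vs_lowest(
            fit_gee_exchangeable(df.y, df.cluster, df.level, level_order=["lo", "hi"])
        )
        assert res.is_lowest.sum() == 1
        low = res[res.is_lowest].iloc[0]
        assert low.pair == "lo" and np.isnan(low.p_value)

    def test_power_to_separate_2_vs_6_degrees(self):
        """7 clusters, RMSE 2 vs 6 deg: the contrast rejects in most
        replicate studies."""
        rng = np.random.default_rng(99)
        hits = 0
        reps = 30
        for _ in range(reps):
            df = _clustered_data(rng, m=7, levels=["A", "B"], rho=0.3, sigma=1.0,
                                 means={"A": 2.0, "B": 6.0}, n_per_level=3)
            res = test_rmse_vs_lowest(
                fit_gee_exchangeable(df.y, df.cluster, df.level, level_order=["A", "B"])
            )
            hits += res[~res.is_lowest].p_value.iloc[0] < 0.05
        assert hits / reps > 0.7
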