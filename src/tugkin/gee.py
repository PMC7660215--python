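"""Generalized estimating equations for comparing sensor combinations.

Per-trial bias and RMSE values are clustered within participants (each
subject contributes several TUG trials), so sensor combinations are
compared with marginal (population-averaged) means fitted by GEE:

* cell-means design — one coefficient per sensor pair, i.e. the
  least-squares mean of the metric for that pair;
* Gaussian working variance and identity link (the responses are
  continuous, in degrees);
* exchangeable working correlation within subject — any two records from
  the same participant share a common correlation ``rho``;
* robust (sandwich) covariance for the standard errors, so inference does
  not lean on the working-correlation choice.

Two Wald test families are provided, mirroring the study's tables:
``test_bias_vs_zero`` asks whether each pair's mean bias differs from
zero, and ``test_rmse_vs_lowest`` compares each pair's RMSE to the lowest
RMSE in the same joint x segment cell (the lowest pair itself is marked
not-applicable).  Cells with p > 0.05 are flagged as "highlighted"
(unbiased, or statistically indistinguishable from the best pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GeeFit",
    "fit_gee_exchangeable",
    "test_bias_vs_zero",
    "test_rmse_vs_lowest",
    "analyze_joint",
    "format_joint_table",
]


@dataclass
class GeeFit:
    """Fitted GEE cell-means model for one joint x segment x metric cell.

    ``beta`` holds the least-squares mean per factor level (sensor pair),
    ``cov`` the robust sandwich covariance of those means.
    """

    levels: list[str]
    beta: np.ndarray
    cov: np.ndarray
    rho: float
    scale: float
    n_clusters: int
    n_obs: int
    n_iter: int
    converged: bool
    cluster_sizes: list[int] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def _exch_inverse(n: int, rho: float) -> np.ndarray:
    """Closed-form inverse of the n x n exchangeable correlation matrix."""
    if n == 1:
        return np.ones((1, 1))
    a = 1.0 / (1.0 - rho)
    b = -rho / ((1.0 - rho) * (1.0 + (n - 1) * rho))
    return a * np.eye(n) + b * np.ones((n, n))


def fit_gee_exchangeable(
    y,
    clusters,
    levels,
    *,
    level_order: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GeeFit:
    """Fit the exchangeable-correlation GEE cell-means model.

    Parameters
    ----------
    y : (n,) responses (bias or RMSE values, degrees)
    clusters : (n,) cluster labels (participant ids)
    levels : (n,) factor labels (sensor pair per observation)
    level_order : explicit ordering of factor levels; defaults to order of
        first appearance.  Every level must occur in the data.

    Notes
    -----
    The estimating equations are solved by iterating generalized least
    squares updates with moment re-estimation of the dispersion and of the
    common intra-cluster correlation:

    ``scale = sum(r^2) / (N - p)`` and
    ``rho = sum over clusters of pairwise residual products /
    (scale * (total pairs - p))``,

    the conventional moment estimators for Gaussian GEE.  Convergence is
    declared when the largest coefficient change drops below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    levels = np.asarray(levels)
    if y.ndim != 1 or y.shape != clusters.shape or y.shape != levels.shape:
        raise ValueError("y, clusters and levels must be equal-length 1-d arrays")

    if level_order is None:
        level_order = list(pd.unique(levels))
    level_order = list(level_order)
    missing = set(levels) - set(level_order)
    if missing:
        raise ValueError(f"levels not in level_order: {sorted(missing)}")
    p = len(level_order)
    col = {lev: j for j, lev in enumerate(level_order)}
    if len(set(levels)) < p:
        raise ValueError("every factor level must be observed at least once")

    cluster_ids = list(pd.unique(clusters))
    m = len(cluster_ids)
    if m < 2:
        raise ValueError("GEE requires at least 2 clusters (no between-cluster variance otherwise)")

    # per-cluster design matrices / responses
    Xs, ys = [], []
    for cid in cluster_ids:
        idx = np.flatnonzero(clusters == cid)
        Xi = np.zeros((idx.size, p))
        Xi[np.arange(idx.size), [col[lev] for lev in levels[idx]]] = 1.0
        Xs.append(Xi)
        ys.append(y[idx])
    sizes = [len(v) for v in ys]
    n_obs = int(sum(sizes))
    if n_obs <= p:
        raise ValueError("need more observations than factor levels")

    # initial OLS (rho = 0)
    X = np.vstack(Xs)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    rho = 0.0
    scale = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # moment estimates of scale and rho from current residuals
        ssr = 0.0
        pair_sum = 0.0
        n_pairs = 0
        for Xi, yi in zip(Xs, ys):
            ri = yi - Xi @ beta
            ssr += float(ri @ ri)
            s = float(ri.sum())
            pair_sum += (s * s - float(ri @ ri)) / 2.0
            n_pairs += len(ri) * (len(ri) - 1) // 2
        scale = ssr / (n_obs - p)
        if scale > 0.0 and n_pairs - p > 0:
            rho = pair_sum / (scale * (n_pairs - p))
        else:
            rho = 0.0
        max_n = max(sizes)
        lo = -0.99 / (max_n - 1) if max_n > 1 else 0.0
        rho = float(np.clip(rho, lo, 0.99))

        # GLS update with the working correlation
        A = np.zeros((p, p))
        b = np.zeros(p)
        for Xi, yi in zip(Xs, ys):
            Wi = _exch_inverse(len(yi), rho)
            XtW = Xi.T @ Wi
            A += XtW @ Xi
            b += XtW @ yi
        new_beta = np.linalg.solve(A, b)
        delta = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("GEE did not converge within max_iter; results flagged", stacklevel=2)

    # robust sandwich covariance: B^-1 M B^-1 (working scale cancels)
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for Xi, yi in zip(Xs, ys):
        Wi = _exch_inverse(len(yi), rho)
        XtW = Xi.T @ Wi
        B += XtW @ Xi
        ri = yi - Xi @ beta
        g = XtW @ ri
        M += np.outer(g, g)
    Binv = np.linalg.inv(B)
    cov = Binv @ M @ Binv

    return GeeFit(
        levels=level_order,
        beta=beta,
        cov=cov,
        rho=rho,
        scale=scale,
        n_clusters=m,
        n_obs=n_obs,
        n_iter=it,
        converged=converged,
        cluster_sizes=sizes,
    )


def _wald_p(est: float, se: float) -> float:
    """Two-sided Wald p-value against the standard normal reference."""
    if se == 0.0:
        return 1.0 if est == 0.0 else 0.0
    return float(2.0 * norm.sf(abs(est) / se))


def test_bias_vs_zero(fit: GeeFit) -> pd.DataFrame:
    """Wald test per sensor pair: is the mean bias different from zero?

    ``highlighted`` marks pairs with p > 0.05, i.e. pairs whose
    measurements are statistically unbiased.
    """
    se = fit.se
    rows = []
    for j, lev in enumerate(fit.levels):
        pval = _wald_p(float(fit.beta[j]), float(se[j]))
        rows.append(
            {
                "pair": lev,
                "ls_mean": float(fit.beta[j]),
                "se": float(se[j]),
                "p_value": pval,
                "highlighted": pval > 0.05,
            }
        )
    return pd.DataFrame(rows)


def test_rmse_vs_lowest(fit: GeeFit) -> pd.DataFrame:
    """Wald contrast of each pair's RMSE against the lowest-RMSE pair.

    The pair with the lowest least-squares mean is the comparator and gets
    no p-value (``is_lowest`` True, p NaN — the "n/a" cell of the study
    tables).  Ties are broken by level order and logged.  ``highlighted``
    marks pairs statistically indistinguishable from the lowest (p > 0.05).
    """
    if len(fit.levels) < 2:
        raise ValueError("RMSE-vs-lowest comparison needs at least 2 pairs")
    best = int(np.argmin(fit.beta))
    ties = np.flatnonzero(np.isclose(fit.beta, fit.beta[best], rtol=0.0, atol=1e-12))
    if ties.size > 1:
        warnings.warn(
            f"tie for lowest RMSE among {[fit.levels[i] for i in ties]}; "
            f"keeping {fit.levels[best]} (first in pair order)",
            stacklevel=2,
        )
    rows = []
    for j, lev in enumerate(fit.levels):
        if j == best:
            rows.append(
                {
                    "pair": lev,
                    "ls_mean": float(fit.beta[j]),
                    "se": float(fit.se[j]),
                    "p_value": float("nan"),
                    "is_lowest": True,
                    "highlighted": True,
                }
            )
            continue
        diff = float(fit.beta[j] - fit.beta[best])
        var = float(fit.cov[j, j] + fit.cov[best, best] - 2.0 * fit.cov[j, best])
        se = float(np.sqrt(max(var, 0.0)))
        pval = _wald_p(diff, se)
        rows.append(
            {
                "pair": lev,
                "ls_mean": float(fit.beta[j]),
                "se": float(fit.se[j]),
                "p_value": pval,
                "is_lowest": False,
                "highlighted": pval > 0.05,
            }
        )
    return pd.DataFrame(rows)


# these are library operations, not pytest tests, despite the names
test_bias_vs_zero.__test__ = False
test_rmse_vs_lowest.__test__ = False


def analyze_joint(
    records: pd.DataFrame,
    joint: str,
    *,
    pair_order: list[str] | None = None,
) -> pd.DataFrame:
    """Fit one GEE per segment x metric for a joint and collect cell results.

    ``records`` is the long-format error table (already walk-pooled if
    desired) with columns subject/joint/proximal/distal/segment/bias_deg/
    rmse_deg.  Returns one row per segment x pair x metric with the LS
    mean, robust SE, p-value, test family and highlight flag.
    """
    sub = records[records["joint"] == joint].copy()
    if sub.empty:
        return pd.DataFrame(
            columns=["joint", "segment", "pair", "metric", "ls_mean", "se",
                     "p_value", "test", "is_lowest", "highlighted", "n", "subs"]
        )
    sub["pair"] = sub["proximal"] + "/" + sub["distal"]
    out = []
    for segment in pd.unique(sub["segment"]):
        seg = sub[sub["segment"] == segment]
        counts = seg.groupby("pair", sort=False).agg(
            n=("bias_deg", "size"), subs=("subject", "nunique")
        )
        for metric, column, tester, test_name in (
            ("bias", "bias_deg", test_bias_vs_zero, "vs_zero"),
            ("rmse", "rmse_deg", test_rmse_vs_lowest, "vs_lowest"),
        ):
            fit = fit_gee_exchangeable(
                seg[column].to_numpy(),
                seg["subject"].to_numpy(),
                seg["pair"].to_numpy(),
                level_order=pair_order,
            )
            res = tester(fit)
            res["joint"] = joint
            res["segment"] = segment
            res["metric"] = metric
            res["test"] = test_name
            if "is_lowest" not in res.columns:
                res["is_lowest"] = False
            res = res.join(counts, on="pair")
            out.append(res)
    cols = ["joint", "segment", "pair", "metric", "ls_mean", "se",
            "p_value", "test", "is_lowest", "highlighted", "n", "subs"]
    return pd.concat(out, ignore_index=True)[cols]


def format_joint_table(results: pd.DataFrame) -> pd.DataFrame:
    """Publication-style wide table: rows = segment x metric, columns = pairs.

    Cells read ``mean (se), p=..`` with ``p=n/a`` for the lowest-RMSE pair
    and a trailing ``*`` on highlighted cells.
    """
    def cell(row) -> str:
        if row["is_lowest"]:
            ptxt = "p=n/a"
        elif np.isnan(row["p_value"]):
            ptxt = "p=n/a"
        else:
            ptxt = f"p={row['p_value']:.3f}"
        star = " *" if row["highlighted"] else ""
        return f"{row['ls_mean']:.2f} ({row['se']:.2f}), {ptxt}{star}"

    tbl = results.copy()
    tbl["cell"] = tbl.apply(cell, axis=1)
    wide = tbl.pivot_table(
        index=["segment", "metric"],
        columns="pair",
        values="cell",
        aggfunc="first",
        sort=False,
    )
    return wide
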