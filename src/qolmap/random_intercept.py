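"""Random-intercept linear panel model with cluster-robust inference.

Model:  y_ij = x_ij' beta + b_i + e_ij,  b_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

for patient (cluster) i and repeated questionnaire j.  The marginal
covariance of a cluster is sigma^2 (I + lambda J) with lambda =
tau^2/sigma^2 and J the all-ones matrix, so V^{-1} has the Sherman-Morrison
closed form and the whole fit reduces to a one-dimensional (RE)ML profile
over lambda with a GLS solve per candidate.  That makes refitting cheap,
which matters because backward selection refits the model once per dropped
term.

Fixed-effect inference uses a cluster-robust (sandwich) covariance

    cov(beta) = A^{-1} (sum_i g_i g_i') A^{-1},   g_i = X_i' W_i e_i,

with A = sum_i X_i' W_i X_i, W_i = I - (lambda/(1+lambda n_i)) J, a G/(G-1)
small-sample factor and t statistics on G-1 degrees of freedom (G =
number of clusters).  Setting ``method="ols"`` fixes lambda = 0, which is
exactly pooled OLS with cluster-robust standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["RandomInterceptResult", "fit_random_intercept"]


@dataclass
class RandomInterceptResult:
    """Fitted fixed effects with cluster-robust uncertainty."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    sigma2: float
    tau2: float
    n_obs: int
    n_clusters: int
    cov_type: str
    method: str
    cov_params: pd.DataFrame = field(repr=False, default=None)

    @property
    def resid_sd(self) -> float:
        return float(np.sqrt(self.sigma2))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = X[self.params.index]
        return X.to_numpy(dtype=float) @ self.params.to_numpy()


def _cluster_slices(groups: np.ndarray):
    """Sorted order + per-cluster index arrays."""
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    _, starts = np.unique(sorted_groups, return_index=True)
    bounds = np.append(starts, len(groups))
    return order, bounds


def fit_random_intercept(
    y,
    X: pd.DataFrame,
    groups,
    method: str = "reml",
    cov_type: str = "cluster",
) -> RandomInterceptResult:
    """Fit the random-intercept model.

    Parameters
    ----------
    y : array-like, outcome (one row per questionnaire).
    X : DataFrame of fixed-effect regressors; include a constant column
        (conventionally named ``const``) if an intercept is wanted.
    groups : array-like cluster (patient) labels.
    method : ``"reml"`` (default), ``"ml"``, or ``"ols"`` (lambda fixed at 0,
        i.e. pooled OLS with cluster-robust errors).
    cov_type : ``"cluster"`` (sandwich, default) or ``"model"``.
    """
    names = list(X.columns)
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    n, p = Xm.shape
    if len(yv) != n or len(groups) != n:
        raise ValueError("y, X and groups must have the same number of rows")
    if np.isnan(Xm).any() or np.isnan(yv).any():
        raise ValueError("missing values in outcome or regressors")

    order, bounds = _cluster_slices(groups)
    Xs, ys = Xm[order], yv[order]
    G = len(bounds) - 1
    sizes = np.diff(bounds).astype(float)

    # per-cluster sufficient statistics
    XtX = Xs.T @ Xs
    Xty = Xs.T @ ys
    yty = float(ys @ ys)
    S = np.empty((G, p))  # X_i' 1
    t = np.empty(G)       # y_i' 1
    for i in range(G):
        sl = slice(bounds[i], bounds[i + 1])
        S[i] = Xs[sl].sum(axis=0)
        t[i] = ys[sl].sum()

    def gls(lam):
        c = lam / (1.0 + lam * sizes)  # per-cluster shrinkage weight
        A = XtX - (S * c[:, None]).T @ S
        b = Xty - S.T @ (c * t)
        beta = np.linalg.solve(A, b)
        rss = (yty - c @ t**2) - 2.0 * beta @ b + beta @ A @ beta
        return beta, A, b, max(rss, 1e-300)

    def neg_profile_ll(log_lam):
        lam = np.exp(log_lam)
        beta, A, _, rss = gls(lam)
        logdet_v = float(np.sum(np.log1p(lam * sizes)))
        if method == "reml":
            dof = n - p
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            return dof * np.log(rss / dof) + logdet_v + logdet_a
        return n * np.log(rss / n) + logdet_v

    if method == "ols" or G == 1:
        lam = 0.0
    elif method in ("reml", "ml"):
        res = optimize.minimize_scalar(neg_profile_ll, bounds=(-12.0, 8.0), method="bounded",
                                       options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
        # check the lambda -> 0 boundary
        if neg_profile_ll(-30.0) <= res.fun:
            lam = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")

    beta, A, b, rss = gls(lam)
    dof = n - p if method in ("reml", "ols") else n
    sigma2 = rss / dof
    tau2 = lam * sigma2

    # residual cluster scores g_i = X_i' W_i e_i
    e = ys - Xs @ beta
    c = lam / (1.0 + lam * sizes)
    Gmat = np.empty((G, p))
    esum = np.empty(G)
    for i in range(G):
        sl = slice(bounds[i], bounds[i + 1])
        esum[i] = e[sl].sum()
        Gmat[i] = Xs[sl].T @ e[sl]
    Gmat -= (c * esum)[:, None] * S

    Ainv = np.linalg.inv(A)
    if cov_type == "cluster" and G > 1:
        meat = Gmat.T @ Gmat
        cov = Ainv @ meat @ Ainv * (G / (G - 1.0))
        df_t = G - 1
    else:
        cov = sigma2 * Ainv
        df_t = n - p
        cov_type = "model"

    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_t)
    crit = stats.t.ppf(0.975, df=df_t)
    ci = np.column_stack([beta - crit * se, beta + crit * se])

    idx = pd.Index(names)
    return RandomInterceptResult(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        conf_int=pd.DataFrame(ci, index=idx, columns=["lower", "upper"]),
        sigma2=float(sigma2),
        tau2=float(tau2),
        n_obs=int(n),
        n_clusters=int(G),
        cov_type=cov_type,
        method=method,
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
    )
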