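"""Least-squares ("linear") estimators for VAR and gLV models.

These are the fast, deterministic counterparts of the Bayesian routines:
per-equation ordinary (or ridge) least squares for the lag-1 VAR, and
gradient matching on log-abundances for the generalized Lotka-Volterra
model.  Both return a :class:`~microdyn.inference.summaries.FitSummary`
with classical confidence intervals.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from scipy.linalg import lstsq

from ..timeseries import TimeSeries, to_relative_abundance
from .summaries import EstimationError, FitSummary, MissingDataError


def _require_complete(data: TimeSeries) -> None:
    if data.has_missing:
        n_missing = int((~data.mask).sum())
        raise MissingDataError(
            f"{n_missing} missing entries: impute the series first "
            "(microdyn.imputation) — inference never drops data silently"
        )


def _gaussian_loglik(resid: np.ndarray, sigma: np.ndarray) -> float:
    """Independent-Gaussian log-likelihood, one sigma per column."""
    T = resid.shape[0]
    z2 = np.sum((resid / sigma) ** 2)
    return float(
        -0.5 * z2 - T * np.sum(np.log(sigma)) - 0.5 * resid.size * math.log(2 * math.pi)
    )


def _ols_block(
    D: np.ndarray,
    Y: np.ndarray,
    ridge_lambda: float,
    level: float,
    penalize_intercept: bool = False,
):
    """Multi-response least squares of Y on D (last design column = 1).

    Returns (coef (m, p), residuals, per-response sigma_mle, per-coef
    standard errors (m, p) or None when dof <= 0).
    """
    T, p = D.shape
    if ridge_lambda == 0.0:
        rank = np.linalg.matrix_rank(D)
        if rank < p:
            raise EstimationError(
                f"design matrix is rank deficient (rank {rank} < {p}); "
                "add timepoints or use ridge regularization"
            )
        beta, *_ = lstsq(D, Y)
    else:
        pen = np.full(p, ridge_lambda)
        if not penalize_intercept:
            pen[-1] = 0.0  # intercept column unpenalized
        G = D.T @ D + np.diag(pen)
        beta = np.linalg.solve(G, D.T @ Y)
    resid = Y - D @ beta
    sigma_mle = np.sqrt(np.mean(resid**2, axis=0))
    dof = T - p
    se = None
    if dof > 0 and ridge_lambda == 0.0:
        XtX_inv = np.linalg.inv(D.T @ D)
        s2 = np.sum(resid**2, axis=0) / dof  # unbiased, per response
        se = np.sqrt(np.outer(np.diag(XtX_inv), s2)).T  # (m, p)
    return beta.T, resid, np.maximum(sigma_mle, 1e-12), se, dof


def infer_var_linear(
    data: TimeSeries,
    penalty: str | None = None,
    ridge_lambda: float = 0.0,
    level: float = 0.95,
    relative_abundance: bool = False,
) -> FitSummary:
    """Per-equation least squares for ``X_t = A X_{t-1} + c + eps_t``.

    With ``penalty=None`` and a full-rank design this is the unique OLS
    solution; ``penalty="ridge"`` shrinks the A coefficients (intercepts are
    never penalized).  Confidence intervals are classical t-intervals
    (OLS only).  Missing entries are refused — impute first.
    """
    if penalty not in (None, "none", "ridge"):
        raise ValueError(f"unknown penalty {penalty!r}")
    lam = float(ridge_lambda) if penalty == "ridge" else 0.0
    if penalty == "ridge" and lam <= 0:
        raise ValueError("ridge penalty requires ridge_lambda > 0")
    _require_complete(data)
    if relative_abundance:
        data = to_relative_abundance(data)
    X = data.values
    T, n = X.shape
    if T < n + 2:
        raise EstimationError(
            f"need at least n_vars + 2 = {n + 2} timepoints, got {T}"
        )
    D = np.column_stack([X[:-1], np.ones(T - 1)])
    coef, resid, sigma, se, dof = _ols_block(D, X[1:], lam, level)
    A_hat, c_hat = coef[:, :n], coef[:, n]

    lower = {"A": A_hat.copy(), "intercept": c_hat.copy()}
    upper = {"A": A_hat.copy(), "intercept": c_hat.copy()}
    if se is not None:
        tq = stats.t.ppf(0.5 + level / 2, dof)
        lower["A"], upper["A"] = A_hat - tq * se[:, :n], A_hat + tq * se[:, :n]
        lower["intercept"] = c_hat - tq * se[:, n]
        upper["intercept"] = c_hat + tq * se[:, n]

    loglik = _gaussian_loglik(resid, sigma)
    meta = dict(data.meta)
    return FitSummary(
        point_estimates={"A": A_hat, "intercept": c_hat, "noise_sd": sigma},
        lower={**lower, "noise_sd": sigma},
        upper={**upper, "noise_sd": sigma},
        level=level,
        log_likelihood=loglik,
        n_params=n * (n + 1) + n,
        n_obs=(T - 1) * n,
        residual_sd=sigma,
        method="var_ols" if lam == 0 else "var_ridge",
        meta=meta,
    )


def glv_gradient_design(data: TimeSeries):
    """Gradient-matching design for gLV: central-difference d(ln x)/dt
    regressed on (1, x).  Returns (response (T, n), design (T, n+1))."""
    _require_complete(data)
    X = data.values
    if np.any(X <= 0):
        t_idx, v_idx = np.argwhere(X <= 0)[0]
        raise ValueError(
            f"gLV inference needs strictly positive abundances; "
            f"variable {data.names[v_idx]!r} at time {data.times[t_idx]!r} "
            f"is {X[t_idx, v_idx]!r}"
        )
    if data.n_timepoints < 3:
        raise EstimationError("gLV gradient matching needs >= 3 timepoints")
    dlog = np.gradient(np.log(X), data.times, axis=0)
    D = np.column_stack([X, np.ones(X.shape[0])])
    return dlog, D


def infer_glv_linear(
    data: TimeSeries, level: float = 0.95, ridge_lambda: float = 0.0
) -> FitSummary:
    """Gradient-matching estimate of gLV growth rates mu and interactions M.

    Per species i, regresses the numerical log-derivative d(ln x_i)/dt on
    (x_1..x_n, 1): the slope vector estimates row i of M and the intercept
    estimates mu_i.  Accurate when sampling is dense relative to the
    dynamics; the finite-difference bias grows with the sampling interval.
    """
    dlog, D = glv_gradient_design(data)
    n = data.n_vars
    coef, resid, sigma, se, dof = _ols_block(D, dlog, ridge_lambda, level)
    M_hat, mu_hat = coef[:, :n], coef[:, n]
    lower = {"M": M_hat.copy(), "mu": mu_hat.copy()}
    upper = {"M": M_hat.copy(), "mu": mu_hat.copy()}
    if se is not None:
        tq = stats.t.ppf(0.5 + level / 2, dof)
        lower["M"], upper["M"] = M_hat - tq * se[:, :n], M_hat + tq * se[:, :n]
        lower["mu"], upper["mu"] = mu_hat - tq * se[:, n], mu_hat + tq * se[:, n]
    return FitSummary(
        point_estimates={"mu": mu_hat, "M": M_hat, "noise_sd": sigma},
        lower={**lower, "noise_sd": sigma},
        upper={**upper, "noise_sd": sigma},
        level=level,
        log_likelihood=_gaussian_loglik(resid, sigma),
        n_params=n * (n + 1) + n,
        n_obs=dlog.size,
        residual_sd=sigma,
        method="glv_gradient_matching",
        meta=dict(data.meta),
    )
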