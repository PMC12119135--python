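"""Gaussian-process regression over time for filling missing observations.

Longitudinal microbiome tables are rarely complete: dropouts, failed
extractions and uneven sampling leave holes that lag-based inference cannot
tolerate.  Each variable is fitted with an independent one-dimensional GP
over time (RBF or Matern-3/2 kernel plus a white-noise term), hyperparameters
chosen by maximizing the log marginal likelihood with random restarts.  The
GP posterior gives a mean prediction and an equal-tailed Gaussian band at any
query time; :func:`impute` replaces the masked entries of a
:class:`~microdyn.timeseries.TimeSeries` by posterior means and records
which entries were filled.

The fitting itself is delegated to scikit-learn's
``GaussianProcessRegressor``; this module owns the kernel configuration,
per-variable bookkeeping, and the imputation contract (observed entries are
never touched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, Matern, WhiteKernel

from .timeseries import TimeSeries


class ImputationError(RuntimeError):
    pass


_KERNELS = ("rbf", "matern32")


def _make_kernel(kernel: str, t_span: float):
    if kernel not in _KERNELS:
        raise ImputationError(f"unknown kernel {kernel!r}; choose from {_KERNELS}")
    length0 = max(t_span / 4.0, 1e-3)
    bounds = (max(t_span * 1e-3, 1e-6), max(t_span * 10.0, 1.0))
    if kernel == "rbf":
        core = RBF(length_scale=length0, length_scale_bounds=bounds)
    else:
        core = Matern(length_scale=length0, length_scale_bounds=bounds, nu=1.5)
    signal = ConstantKernel(1.0, (1e-6, 1e6))
    noise = WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-12, 1e2))
    return signal * core + noise


@dataclass
class GPFit:
    """Per-variable fitted GPs plus the training data they saw.

    ``models[name]`` is a fitted scikit-learn GP for one variable;
    ``train_times``/``train_values`` hold the observed points actually used.
    ``hyperparameters`` records the optimized kernel per variable
    (lengthscale, signal variance, noise variance) and the achieved log
    marginal likelihood alongside the pre-optimization one.
    """

    kernel: str
    names: list[str]
    models: dict = field(default_factory=dict)
    train_times: dict = field(default_factory=dict)
    train_values: dict = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)
    log1p: bool = False

    def prior_variance(self, name: str) -> float:
        """Kernel variance at a point, before conditioning on data
        (on the original output scale)."""
        gp = self.models[name]
        scale = float(getattr(gp, "_y_train_std", 1.0)) ** 2
        return float(gp.kernel_.diag(np.zeros((1, 1)))[0]) * scale

    def prior_mean(self, name: str) -> float:
        """GP prior mean on the original output scale (the training mean)."""
        return float(getattr(self.models[name], "_y_train_mean", 0.0))


def gp_fit(
    data: TimeSeries,
    kernel: str = "rbf",
    per_variable: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
    log1p: bool = False,
) -> GPFit:
    """Fit one GP per variable to the observed (unmasked) entries.

    Hyperparameters maximize the log marginal likelihood with
    ``n_restarts`` random restarts (seed-controlled).  ``log1p`` fits on
    log1p-transformed values (useful for nonnegative abundances); predictions
    are mapped back.  Every variable needs at least 2 observed points.
    """
    if not per_variable:
        raise ImputationError(
            "only independent per-variable GPs are implemented"
        )
    t_span = float(data.times[-1] - data.times[0]) if data.n_timepoints > 1 else 1.0
    fit = GPFit(kernel=kernel, names=list(data.names), log1p=log1p)
    rng = np.random.default_rng(seed)
    for j, name in enumerate(data.names):
        obs = data.mask[:, j]
        if int(obs.sum()) < 2:
            raise ImputationError(
                f"variable {name!r} has {int(obs.sum())} observed points; "
                "need at least 2 to fit a GP"
            )
        t = data.times[obs].reshape(-1, 1)
        y = data.values[obs, j]
        if log1p:
            if np.any(y < 0):
                raise ImputationError(
                    f"log1p transform requires nonnegative values ({name!r})"
                )
            y = np.log1p(y)
        k0 = _make_kernel(kernel, t_span)
        gp = GaussianProcessRegressor(
            kernel=k0,
            n_restarts_optimizer=n_restarts,
            normalize_y=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        initial_lml = None
        gp.fit(t, y)
        initial_lml = float(gp.log_marginal_likelihood(k0.theta))
        fit.models[name] = gp
        fit.train_times[name] = t.ravel()
        fit.train_values[name] = data.values[obs, j]
        fit.hyperparameters[name] = {
            "kernel": str(gp.kernel_),
            "log_marginal_likelihood": float(
                gp.log_marginal_likelihood(gp.kernel_.theta)
            ),
            "initial_log_marginal_likelihood": initial_lml,
        }
    return fit


def gp_predict(fit: GPFit, query_times, level: float = 0.95):
    """Posterior mean and equal-tailed Gaussian band at ``query_times``.

    Returns ``(mean, lower, upper)`` arrays of shape
    (len(query_times), n_vars).  The band includes the fitted observation
    noise, so it is a predictive interval for new observations.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    if q.size == 0:
        raise ValueError("empty query times")
    z = stats.norm.ppf(0.5 + level / 2.0)
    n_vars = len(fit.names)
    mean = np.empty((q.size, n_vars))
    lower = np.empty_like(mean)
    upper = np.empty_like(mean)
    for j, name in enumerate(fit.names):
        gp = fit.models[name]
        mu, sd = gp.predict(q.reshape(-1, 1), return_std=True)
        lo, hi = mu - z * sd, mu + z * sd
        if fit.log1p:
            mu, lo, hi = np.expm1(mu), np.expm1(lo), np.expm1(hi)
        mean[:, j], lower[:, j], upper[:, j] = mu, lo, hi
    return mean, lower, upper


def gp_posterior_variance(fit: GPFit, query_times) -> np.ndarray:
    """Predictive variance (including noise) at query times, per variable."""
    q = np.atleast_1d(np.asarray(query_times, dtype=float)).reshape(-1, 1)
    out = np.empty((q.shape[0], len(fit.names)))
    for j, name in enumerate(fit.names):
        _, sd = fit.models[name].predict(q, return_std=True)
        out[:, j] = sd**2
    return out


def impute(data: TimeSeries, fit: GPFit | None = None, **fit_kwargs) -> TimeSeries:
    """Fill masked entries with GP posterior means.

    Observed entries are bit-identical before and after; the returned series
    has a fully-True mask, and ``meta["imputed"]`` maps variable names to the
    list of times that were filled.  With no missing entries the input is
    returned unchanged (a copy).
    """
    out = data.copy()
    if not data.has_missing:
        return out
    if fit is None:
        fit = gp_fit(data, **fit_kwargs)
    imputed: dict[str, list[float]] = {}
    for j, name in enumerate(data.names):
        holes = ~data.mask[:, j]
        if not holes.any():
            continue
        gp = fit.models[name]
        mu = gp.predict(data.times[holes].reshape(-1, 1))
        if fit.log1p:
            mu = np.expm1(mu)
        out.values[holes, j] = mu
        imputed[name] = [float(t) for t in data.times[holes]]
    out.mask = np.ones_like(out.mask, dtype=bool)
    out.meta["imputed"] = imputed
    out.meta["imputation_kernel"] = fit.kernel
    return out
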