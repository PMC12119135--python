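"""Point-estimate summaries, intervals, and information criteria."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..timeseries import atomic_write_text


class EstimationError(RuntimeError):
    """Estimation cannot proceed (rank deficiency, bad inputs)."""


class MissingDataError(ValueError):
    """Inference refuses masked entries; impute first."""


@dataclass
class FitSummary:
    """Point estimates with interval bounds and fit metadata.

    ``point_estimates``, ``lower`` and ``upper`` are dicts keyed by parameter
    name (e.g. ``"A"``, ``"intercept"``, ``"noise_sd"``) holding arrays of the
    parameter's natural shape.  ``level`` is the credible/confidence level of
    the intervals.  ``log_likelihood`` is evaluated at the point estimates.
    """

    point_estimates: dict
    lower: dict
    upper: dict
    level: float
    log_likelihood: float
    n_params: int
    n_obs: int
    residual_sd: np.ndarray | None = None
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, pt in self.point_estimates.items():
            lo, hi = self.lower.get(name), self.upper.get(name)
            if lo is None or hi is None:
                continue
            if np.any(np.asarray(lo) > np.asarray(pt) + 1e-12) or np.any(
                np.asarray(pt) > np.asarray(hi) + 1e-12
            ):
                raise ValueError(
                    f"interval for {name!r} does not bracket the point estimate"
                )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.point_estimates[name]

    def to_dict(self) -> dict:
        def arr(d):
            return {k: np.asarray(v).tolist() for k, v in d.items()}

        return {
            "method": self.method,
            "level": self.level,
            "point_estimates": arr(self.point_estimates),
            "lower": arr(self.lower),
            "upper": arr(self.upper),
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "residual_sd": None
            if self.residual_sd is None
            else np.asarray(self.residual_sd).tolist(),
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        atomic_write_text(path, json.dumps(self.to_dict(), indent=2))


def information_criteria(fit: FitSummary) -> tuple[float, float]:
    """Akaike and Bayesian information criteria of a fitted model.

    AIC = 2k - 2 lnL; BIC = k ln(n) - 2 lnL, with k the number of free
    parameters and n the number of scalar observations.
    """
    if fit.n_obs < 2:
        raise ValueError("information criteria need at least 2 observations")
    if not math.isfinite(fit.log_likelihood):
        raise ValueError("fit has no finite log-likelihood")
    k, lnl = fit.n_params, fit.log_likelihood
    aic = 2.0 * k - 2.0 * lnl
    bic = k * math.log(fit.n_obs) - 2.0 * lnl
    return aic, bic
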