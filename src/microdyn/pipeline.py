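"""The end-to-end workflow: impute -> (normalize) -> infer -> stability.

Mirrors the standard analysis of a longitudinal species/metabolite panel:
fill gaps with GP regression, optionally convert taxa to relative
abundances, infer the interaction matrices with Bayesian (or linear)
methods, and classify the stability of the inferred taxa matrix across the
posterior.  Each stage derives its own seed from the master seed, every
output file is written atomically, and a provenance record (config hash,
seeds, package versions) accompanies the results.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .imputation import gp_fit, impute
from .inference import (
    FitSummary,
    PosteriorSamples,
    infer_mvar_bayes,
    infer_var_bayes,
    infer_var_linear,
    posterior_summary,
)
from .stability import StabilityReport, posterior_stability, stability_eigen
from .timeseries import (
    TimeSeries,
    atomic_write_text,
    to_relative_abundance,
    write_timeseries,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    imputed: TimeSeries
    posterior: PosteriorSamples | None
    summary: FitSummary
    stability: StabilityReport | None
    seeds: dict
    outputs: dict = field(default_factory=dict)


def _stage_seeds(master: int) -> dict:
    rng = np.random.default_rng(master)
    return {
        "master": master,
        "impute": int(rng.integers(0, 2**31 - 1)),
        "infer": int(rng.integers(0, 2**31 - 1)),
    }


def _summary_frame(fs: FitSummary) -> pd.DataFrame:
    rows = []
    for name, pt in fs.point_estimates.items():
        pt = np.atleast_1d(np.asarray(pt))
        lo = np.atleast_1d(np.asarray(fs.lower[name]))
        hi = np.atleast_1d(np.asarray(fs.upper[name]))
        for idx in np.ndindex(pt.shape):
            suffix = "_".join(str(i) for i in idx)
            rows.append(
                {
                    "parameter": f"{name}[{suffix}]" if suffix else name,
                    "estimate": float(pt[idx]),
                    "lower": float(lo[idx]),
                    "upper": float(hi[idx]),
                    "level": fs.level,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    data: TimeSeries,
    out_dir: str | Path,
    seed: int | None = None,
) -> PipelineResult:
    """Execute the full workflow on ``data`` and write the artifact bundle.

    Writes ``imputed.csv`` (+ sidecar), ``posterior.nc`` (Bayesian runs),
    ``summary.csv`` / ``summary.json``, ``stability.json`` and
    ``provenance.json`` under ``out_dir``.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.resolved_seed(seed))
    outputs: dict[str, str] = {}

    # --- impute ---------------------------------------------------------
    try:
        if data.has_missing:
            fit = gp_fit(
                data,
                kernel=config.impute.kernel,
                n_restarts=config.impute.n_restarts,
                seed=seeds["impute"],
                log1p=config.impute.log1p,
            )
            imputed = impute(data, fit)
        else:
            imputed = data.copy()
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise PipelineError("impute", exc) from exc
    write_timeseries(imputed, out_dir / "imputed.csv")
    outputs["imputed"] = str(out_dir / "imputed.csv")

    # --- normalize ------------------------------------------------------
    work = imputed
    if config.normalize:
        try:
            work = to_relative_abundance(imputed)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("normalize", exc) from exc

    # --- infer ----------------------------------------------------------
    posterior: PosteriorSamples | None = None
    try:
        priors = (
            config.infer.priors.to_prior_spec()
            if config.infer.priors is not None
            else None
        )
        mcmc = config.infer.mcmc.to_settings()
        if config.infer.method == "linear":
            if config.model != "var":
                raise ValueError(
                    "linear inference is implemented for the VAR model"
                )
            summary = infer_var_linear(work, level=config.infer.level)
        else:
            if config.model == "mvar":
                posterior = infer_mvar_bayes(
                    work, priors=priors, mcmc=mcmc, seed=seeds["infer"]
                )
            elif config.model == "var":
                posterior = infer_var_bayes(
                    work, priors=priors, mcmc=mcmc, seed=seeds["infer"]
                )
            else:
                raise ValueError(
                    f"pipeline inference supports var/mvar, not {config.model!r}"
                )
            summary = posterior_summary(posterior, level=config.infer.level)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("infer", exc) from exc

    atomic_write_text(
        out_dir / "summary.csv", _summary_frame(summary).to_csv(index=False)
    )
    summary.to_json(out_dir / "summary.json")
    outputs["summary"] = str(out_dir / "summary.csv")
    if posterior is not None:
        nc_path = out_dir / "posterior.nc"
        try:
            posterior.to_netcdf(nc_path)
            outputs["posterior"] = str(nc_path)
        except Exception:  # noqa: BLE001 - backend-dependent; CSV fallback
            flat = out_dir / "posterior_draws.csv"
            _draws_frame(posterior).to_csv(flat, index=False)
            outputs["posterior"] = str(flat)

    # --- stability ------------------------------------------------------
    report: StabilityReport | None = None
    try:
        if posterior is not None:
            report = posterior_stability(
                posterior,
                matrix_name=config.stability.matrix,
                threshold=config.stability.threshold,
            )
            payload = report.to_dict()
        else:
            res = stability_eigen(
                summary.point_estimates[config.stability.matrix],
                threshold=config.stability.threshold,
            )
            payload = {
                "matrix": config.stability.matrix,
                "threshold": res.threshold,
                "spectral_radius": res.spectral_radius,
                "is_stable": res.is_stable,
                "eigenvalues": [
                    {"re": float(z.real), "im": float(z.imag)}
                    for z in res.eigenvalues
                ],
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stability", exc) from exc
    atomic_write_text(out_dir / "stability.json", json.dumps(payload, indent=2))
    outputs["stability"] = str(out_dir / "stability.json")

    # --- provenance -----------------------------------------------------
    cfg_json = json.dumps(config.model_dump(), sort_keys=True, default=str)
    provenance = {
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": seeds,
        "versions": {
            "microdyn": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "outputs": outputs,
    }
    atomic_write_text(
        out_dir / "provenance.json", json.dumps(provenance, indent=2, default=str)
    )
    outputs["provenance"] = str(out_dir / "provenance.json")

    return PipelineResult(
        imputed=imputed,
        posterior=posterior,
        summary=summary,
        stability=report,
        seeds=seeds,
        outputs=outputs,
    )


def _draws_frame(post: PosteriorSamples) -> pd.DataFrame:
    cols = {}
    for name in post.parameter_names:
        draws = post.stacked(name)
        flat = draws.reshape(draws.shape[0], -1)
        shape = draws.shape[1:]
        for k in range(flat.shape[1]):
            idx = np.unravel_index(k, shape) if shape else ()
            suffix = "_".join(str(i) for i in idx)
            cols[f"{name}[{suffix}]" if suffix else name] = flat[:, k]
    return pd.DataFrame(cols)
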