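"""Eigenvalue stability of discrete-time interaction matrices.

A lag-1 linear recursion ``X_t = A X_{t-1}`` contracts from any initial
state iff every eigenvalue of A has modulus strictly below 1 (spectral
radius < 1).  Applied to an inferred interaction matrix this gives a
dynamical read on the community: a stable matrix predicts perturbations die
out, an unstable one predicts runaway growth along some mode.

Two levels of analysis are provided: a single matrix
(:func:`stability_eigen`) and a whole posterior (:func:`posterior_stability`),
which classifies every MCMC draw of the matrix and, separately, the
element-wise posterior-median matrix.  The two classifications are
deliberately independent — the median matrix can be stable while a sizeable
fraction of draws is not, which is a statement about posterior uncertainty,
not a contradiction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class StabilityError(ValueError):
    pass


@dataclass
class EigenResult:
    eigenvalues: np.ndarray
    spectral_radius: float
    is_stable: bool
    threshold: float = 1.0


@dataclass
class StabilityReport:
    """Posterior-wide stability summary.

    ``fraction_stable`` is a percentage in [0, 100] over pooled posterior
    draws; ``median_matrix_stable`` classifies the element-wise posterior
    median separately.
    """

    matrix_name: str
    threshold: float
    n_draws: int
    n_stable: int
    fraction_stable: float
    per_draw_stable: np.ndarray
    per_draw_spectral_radius: np.ndarray
    median_matrix: np.ndarray
    median_matrix_eigenvalues: np.ndarray
    median_matrix_spectral_radius: float
    median_matrix_stable: bool

    def to_dict(self) -> dict:
        ev = self.median_matrix_eigenvalues
        return {
            "matrix": self.matrix_name,
            "threshold": self.threshold,
            "n_draws": self.n_draws,
            "n_stable": self.n_stable,
            "fraction_stable_percent": self.fraction_stable,
            "median_matrix": self.median_matrix.tolist(),
            "median_matrix_eigenvalues": [
                {"re": float(z.real), "im": float(z.imag)} for z in ev
            ],
            "median_matrix_spectral_radius": self.median_matrix_spectral_radius,
            "median_matrix_stable": self.median_matrix_stable,
        }


def stability_eigen(A, threshold: float = 1.0) -> EigenResult:
    """Full spectrum and the strict ``|lambda| < threshold`` verdict.

    A matrix with spectral radius exactly at the threshold is classified
    unstable (the criterion is strict).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise StabilityError(f"matrix must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise StabilityError("matrix contains non-finite entries")
    ev = np.linalg.eigvals(A)
    rho = float(np.max(np.abs(ev))) if ev.size else 0.0
    return EigenResult(
        eigenvalues=ev,
        spectral_radius=rho,
        is_stable=bool(rho < threshold),
        threshold=float(threshold),
    )


def matrix_stability(
    draws: np.ndarray, matrix_name: str = "A", threshold: float = 1.0
) -> StabilityReport:
    """Classify a stack of matrix draws of shape (n_draws, n, n)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[1] != draws.shape[2]:
        raise StabilityError(
            f"expected (n_draws, n, n) draws, got shape {draws.shape}"
        )
    radii = np.array(
        [np.max(np.abs(np.linalg.eigvals(d))) for d in draws], dtype=float
    )
    stable = radii < threshold
    median = np.median(draws, axis=0)
    med = stability_eigen(median, threshold=threshold)
    n = draws.shape[0]
    return StabilityReport(
        matrix_name=matrix_name,
        threshold=float(threshold),
        n_draws=n,
        n_stable=int(stable.sum()),
        fraction_stable=100.0 * float(stable.sum()) / n,
        per_draw_stable=stable,
        per_draw_spectral_radius=radii,
        median_matrix=median,
        median_matrix_eigenvalues=med.eigenvalues,
        median_matrix_spectral_radius=med.spectral_radius,
        median_matrix_stable=med.is_stable,
    )


def posterior_stability(
    post, matrix_name: str = "A", threshold: float = 1.0
) -> StabilityReport:
    """Stability analysis across all pooled posterior draws of a matrix.

    ``post`` is a :class:`~microdyn.inference.PosteriorSamples` (or any
    object exposing ``stacked(name) -> (n_draws, n, n)`` array).  Chains are
    pooled before computing the stable fraction.
    """
    try:
        draws = post.stacked(matrix_name)
    except KeyError as exc:
        raise KeyError(
            f"posterior has no matrix named {matrix_name!r}"
        ) from exc
    draws = np.asarray(draws)
    if draws.ndim != 3:
        raise StabilityError(
            f"{matrix_name!r} draws are not matrices (shape {draws.shape})"
        )
    return matrix_stability(draws, matrix_name=matrix_name, threshold=threshold)
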