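"""Forward simulators for microbial community dynamics.

Four generative families are supported:

* **VAR** — discrete-time lag-1 vector autoregression,
  ``X_t = A X_{t-1} + c + eps_t`` with Gaussian noise.  A purely statistical
  model: "abundances" may go negative (an optional clip exists, default off).
* **MVAR** — the two-equation species/metabolite coupling
  ``X_t = A dX_{t-1} + c_x + eps_x`` and ``S_t = B dX_{t-1} + c_s + eps_y``
  where ``dX_{t-1} = X_{t-1} - X_{t-2}`` is the lagged abundance change.
* **gLV** — generalized Lotka-Volterra ODEs,
  ``dx_i/dt = x_i (mu_i + sum_j M_ij x_j)``.
* **CR** — MacArthur consumer-resource ODEs with linear uptake.

VAR/MVAR live on an integer (unit-lag) time grid; gLV/CR on real-valued
times.  All stochastic operations take an explicit seed and are
bit-reproducible.  :func:`generate_fixture` draws random parameters and
simulates, providing reproducible synthetic datasets for the inference and
stability modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .timeseries import METABOLITE, TAXON, TimeSeries, TimeSeriesError


class DynamicsError(ValueError):
    """Invalid dynamics parameters."""


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the failing time when known."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


def _as_square(A, name: str) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[0] != A.shape[1]:
        raise DynamicsError(f"{name} must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise DynamicsError(f"{name} contains non-finite entries")
    return A


def _as_vector(v, n: int, name: str, default: float | None = None) -> np.ndarray:
    if v is None:
        if default is None:
            raise DynamicsError(f"{name} is required")
        return np.full(n, float(default))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if v.size == 1:
        v = np.full(n, v.item())
    if v.shape != (n,):
        raise DynamicsError(f"{name} must have length {n}, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise DynamicsError(f"{name} contains non-finite entries")
    return v


# ----------------------------------------------------------------------
# Parameter containers
# ----------------------------------------------------------------------

@dataclass
class VARParams:
    """Lag-1 VAR coefficients: matrix A, intercept c, noise scale(s)."""

    A: np.ndarray
    intercept: np.ndarray | float = 0.0
    noise_sd: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.A = _as_square(self.A, "A")
        n = self.A.shape[0]
        self.intercept = _as_vector(self.intercept, n, "intercept")
        self.noise_sd = _as_vector(self.noise_sd, n, "noise_sd")
        if np.any(self.noise_sd < 0):
            raise DynamicsError("noise_sd must be nonnegative")

    @property
    def n_vars(self) -> int:
        return self.A.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))


@dataclass
class MVARParams:
    """Species/metabolite coupling: A (taxa->taxa), B (taxa changes->metabolites)."""

    A: np.ndarray
    B: np.ndarray
    intercept_x: np.ndarray | float = 0.0
    intercept_s: np.ndarray | float = 0.0
    noise_sd_x: np.ndarray | float = 1.0
    noise_sd_s: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.A = _as_square(self.A, "A")
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.B.shape[1] != self.A.shape[0]:
            raise DynamicsError(
                f"B must have {self.A.shape[0]} columns (one per taxon), "
                f"got shape {self.B.shape}"
            )
        if not np.all(np.isfinite(self.B)):
            raise DynamicsError("B contains non-finite entries")
        nx, ns = self.A.shape[0], self.B.shape[0]
        self.intercept_x = _as_vector(self.intercept_x, nx, "intercept_x")
        self.intercept_s = _as_vector(self.intercept_s, ns, "intercept_s")
        self.noise_sd_x = _as_vector(self.noise_sd_x, nx, "noise_sd_x")
        self.noise_sd_s = _as_vector(self.noise_sd_s, ns, "noise_sd_s")
        if np.any(self.noise_sd_x < 0) or np.any(self.noise_sd_s < 0):
            raise DynamicsError("noise scales must be nonnegative")

    @property
    def n_taxa(self) -> int:
        return self.A.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.B.shape[0]


@dataclass
class GLVParams:
    """Generalized Lotka-Volterra: growth rates mu (1/time) and interaction
    matrix M (per-capita effect of column species on row species)."""

    mu: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = _as_square(self.M, "M")
        self.mu = _as_vector(self.mu, self.M.shape[0], "mu")

    @property
    def n_species(self) -> int:
        return self.M.shape[0]


@dataclass
class CRParams:
    """MacArthur consumer-resource parameters.

    Species i grows at ``x_i (sum_k yield_ik * uptake_ik * R_k - death_i)``;
    resource k obeys ``supply_k - dilution * R_k - sum_i uptake_ik x_i R_k``.
    """

    growth_yield: np.ndarray
    uptake_rate: np.ndarray
    death_rate: np.ndarray | float = 0.0
    resource_supply: np.ndarray | float = 0.0
    resource_dilution: float = 0.0

    def __post_init__(self) -> None:
        self.growth_yield = np.atleast_2d(np.asarray(self.growth_yield, float))
        self.uptake_rate = np.atleast_2d(np.asarray(self.uptake_rate, float))
        if self.uptake_rate.shape != self.growth_yield.shape:
            raise DynamicsError("uptake_rate and growth_yield shapes differ")
        if np.any(self.uptake_rate < 0):
            raise DynamicsError("uptake_rate must be nonnegative")
        ns, nr = self.growth_yield.shape
        self.death_rate = _as_vector(self.death_rate, ns, "death_rate")
        self.resource_supply = _as_vector(
            self.resource_supply, nr, "resource_supply"
        )
        if np.any(self.death_rate < 0) or np.any(self.resource_supply < 0):
            raise DynamicsError("death_rate and resource_supply must be >= 0")
        self.resource_dilution = float(self.resource_dilution)
        if self.resource_dilution < 0:
            raise DynamicsError("resource_dilution must be nonnegative")

    @property
    def n_species(self) -> int:
        return self.growth_yield.shape[0]

    @property
    def n_resources(self) -> int:
        return self.growth_yield.shape[1]


# ----------------------------------------------------------------------
# Discrete-time simulators
# ----------------------------------------------------------------------

def simulate_var(
    params: VARParams,
    n_steps: int,
    x0,
    seed: int,
    clip_negative: bool = False,
) -> TimeSeries:
    """Simulate ``X_t = A X_{t-1} + c + eps_t`` for ``n_steps`` transitions.

    Returns ``n_steps + 1`` rows on the integer grid 0..n_steps; row 0 is
    ``x0``.  Noise is Gaussian with per-variable scale ``params.noise_sd``
    drawn from a generator seeded with ``seed``; with zero noise the linear
    recursion is exact.  ``clip_negative`` floors the state at 0 (off by
    default: the model is statistical, not mechanistic).
    """
    if n_steps < 1:
        raise DynamicsError("n_steps must be >= 1")
    n = params.n_vars
    x0 = _as_vector(x0, n, "x0")
    rng = np.random.default_rng(seed)
    X = np.empty((n_steps + 1, n))
    X[0] = x0
    eps = rng.normal(0.0, 1.0, size=(n_steps, n)) * params.noise_sd
    for t in range(1, n_steps + 1):
        X[t] = params.A @ X[t - 1] + params.intercept + eps[t - 1]
        if clip_negative:
            np.maximum(X[t], 0.0, out=X[t])
    return TimeSeries(
        times=np.arange(n_steps + 1, dtype=float),
        values=X,
        names=[f"taxon_{i}" for i in range(n)],
        kinds=[TAXON] * n,
        meta={"model": "var", "seed": seed},
    )


def simulate_mvar(
    params: MVARParams,
    n_steps: int,
    x0,
    x1,
    s_init,
    seed: int,
    response: Literal["level", "difference"] = "level",
) -> TimeSeries:
    """Simulate the coupled abundance/metabolite recursion.

    For t >= 2 the abundance row is ``A (X_{t-1} - X_{t-2}) + c_x + eps_x``
    and the metabolite row is ``B (X_{t-1} - X_{t-2}) + c_s + eps_y``.  Two
    initial abundance rows (``x0``, ``x1``) are required because the lagged
    difference needs one step of history; metabolite rows 0 and 1 are both
    set to ``s_init``.  Returns ``n_steps + 2`` rows with taxon columns
    followed by metabolite columns, tagged by kind.

    ``response="difference"`` switches the abundance equation's left side to
    the change ``dX_t`` (i.e. ``X_t = X_{t-1} + A dX_{t-1} + ...``), a
    documented variant; the default simulates the level form exactly as
    written above.
    """
    if n_steps < 1:
        raise DynamicsError("n_steps must be >= 1")
    if response not in ("level", "difference"):
        raise DynamicsError(f"unknown response form {response!r}")
    nx, ns = params.n_taxa, params.n_metabolites
    x0 = _as_vector(x0, nx, "x0")
    x1 = _as_vector(x1, nx, "x1")
    s_init = _as_vector(s_init, ns, "s_init")
    rng = np.random.default_rng(seed)
    T = n_steps + 2
    X = np.empty((T, nx))
    S = np.empty((T, ns))
    X[0], X[1] = x0, x1
    S[0] = S[1] = s_init
    eps_x = rng.normal(0.0, 1.0, size=(T, nx)) * params.noise_sd_x
    eps_s = rng.normal(0.0, 1.0, size=(T, ns)) * params.noise_sd_s
    for t in range(2, T):
        dx = X[t - 1] - X[t - 2]
        drive = params.A @ dx + params.intercept_x + eps_x[t]
        X[t] = X[t - 1] + drive if response == "difference" else drive
        S[t] = params.B @ dx + params.intercept_s + eps_s[t]
    names = [f"taxon_{i}" for i in range(nx)] + [f"metabolite_{j}" for j in range(ns)]
    return TimeSeries(
        times=np.arange(T, dtype=float),
        values=np.hstack([X, S]),
        names=names,
        kinds=[TAXON] * nx + [METABOLITE] * ns,
        meta={"model": "mvar", "seed": seed, "response": response},
    )


# ----------------------------------------------------------------------
# Continuous-time simulators
# ----------------------------------------------------------------------

_RTOL, _ATOL = 1e-8, 1e-10


def _integrate(rhs, times: np.ndarray, y0: np.ndarray, label: str) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or not np.all(np.diff(times) > 0):
        raise TimeSeriesError(f"{label}: times must be increasing, length >= 2")
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0, t_eval=times,
        method="RK45", rtol=_RTOL, atol=_ATOL,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise IntegrationError(
            f"{label} integration failed near t={t_fail:g}: {sol.message}",
            time=t_fail,
        )
    return sol.y.T


def simulate_glv(
    params: GLVParams,
    times,
    x0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TimeSeries:
    """Integrate ``dx_i/dt = x_i (mu_i + sum_j M_ij x_j)`` at ``times``.

    ``noise_sd`` adds multiplicative log-normal measurement noise per
    observation (the latent trajectory stays deterministic); abundances are
    clipped at zero against tiny negative integrator overshoot.
    """
    n = params.n_species
    x0 = _as_vector(x0, n, "x0")
    if np.any(x0 < 0):
        raise DynamicsError("gLV initial abundances must be nonnegative")

    def rhs(_t, x):
        x = np.maximum(x, 0.0)
        return x * (params.mu + params.M @ x)

    traj = np.maximum(_integrate(rhs, times, x0, "gLV"), 0.0)
    if noise_sd and noise_sd > 0:
        rng = np.random.default_rng(seed)
        traj = traj * np.exp(rng.normal(0.0, noise_sd, size=traj.shape))
    return TimeSeries(
        times=np.asarray(times, dtype=float),
        values=traj,
        names=[f"taxon_{i}" for i in range(n)],
        kinds=[TAXON] * n,
        meta={"model": "glv", "seed": seed, "noise_sd": noise_sd},
    )


def simulate_cr(
    params: CRParams,
    times,
    x0,
    r0,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> TimeSeries:
    """Integrate MacArthur consumer-resource dynamics at ``times``.

    Species columns are tagged taxon; resource columns metabolite.  Optional
    multiplicative log-normal measurement noise as in :func:`simulate_glv`.
    """
    ns, nr = params.n_species, params.n_resources
    x0 = _as_vector(x0, ns, "x0")
    r0 = _as_vector(r0, nr, "r0")
    if np.any(x0 < 0) or np.any(r0 < 0):
        raise DynamicsError("CR initial species and resources must be >= 0")
    yu = params.growth_yield * params.uptake_rate  # per-resource growth gain

    def rhs(_t, y):
        x = np.maximum(y[:ns], 0.0)
        R = np.maximum(y[ns:], 0.0)
        dx = x * (yu @ R - params.death_rate)
        dR = (
            params.resource_supply
            - params.resource_dilution * R
            - (params.uptake_rate.T @ x) * R
        )
        return np.concatenate([dx, dR])

    traj = np.maximum(_integrate(rhs, times, np.concatenate([x0, r0]), "CR"), 0.0)
    if noise_sd and noise_sd > 0:
        rng = np.random.default_rng(seed)
        traj = traj * np.exp(rng.normal(0.0, noise_sd, size=traj.shape))
    names = [f"taxon_{i}" for i in range(ns)] + [f"resource_{k}" for k in range(nr)]
    return TimeSeries(
        times=np.asarray(times, dtype=float),
        values=traj,
        names=names,
        kinds=[TAXON] * ns + [METABOLITE] * nr,
        meta={"model": "cr", "seed": seed},
    )


# ----------------------------------------------------------------------
# Random fixtures
# ----------------------------------------------------------------------

_STABLE_RADIUS = 0.8
_UNSTABLE_RADIUS = 1.25
_MAX_REJECTIONS = 1000


class GeneratorError(RuntimeError):
    """Rejection sampling could not satisfy the requested stability class."""


def _draw_var_matrix(
    rng: np.random.Generator, n: int, stability: str
) -> np.ndarray:
    """Entries ~ Normal(0, 0.3); rescaled to a target spectral radius when a
    stability class is requested (0.8 stable, 1.25 unstable)."""
    for _ in range(_MAX_REJECTIONS):
        A = rng.normal(0.0, 0.3, size=(n, n))
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
        if rho == 0.0:
            continue  # cannot rescale a nilpotent draw to a target radius
        if stability == "stable":
            return A * (_STABLE_RADIUS / rho)
        if stability == "unstable":
            return A * (_UNSTABLE_RADIUS / rho)
        return A
    raise GeneratorError(
        f"could not draw a {stability} matrix in {_MAX_REJECTIONS} attempts"
    )


def generate_fixture(
    model: Literal["var", "mvar", "glv", "cr"],
    n_vars: int,
    n_steps: int,
    seed: int,
    noise_sd: float = 1.5,
    stability: Literal["stable", "unstable", "any"] = "stable",
    n_metabolites: int | None = None,
):
    """Draw random parameters for ``model`` and simulate a synthetic series.

    Fully reproducible from ``seed``.  The default noise scale (sd 1.5)
    matches the package's canonical VAR simulation study.  For ``mvar`` the
    stability class applies to the taxa matrix A; ``n_metabolites`` defaults
    to ``n_vars``.  Returns ``(params, TimeSeries)``.
    """
    if n_vars < 1:
        raise DynamicsError("n_vars must be >= 1")
    if stability not in ("stable", "unstable", "any"):
        raise DynamicsError(f"unknown stability class {stability!r}")
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(0, 2**31 - 1))

    if model == "var":
        A = _draw_var_matrix(rng, n_vars, stability)
        params = VARParams(A=A, intercept=0.0, noise_sd=noise_sd)
        x0 = rng.normal(0.0, max(noise_sd, 1.0), size=n_vars)
        return params, simulate_var(params, n_steps, x0, seed=sim_seed)

    if model == "mvar":
        nm = n_vars if n_metabolites is None else int(n_metabolites)
        # The level-form recursion X_t = A dX_{t-1} + eps is a lag-2 system
        # with companion matrix [[A, -A], [I, 0]]; rho(A) < 1 does not bound
        # it, so a stable fixture also rejects on the companion radius.
        for attempt in range(_MAX_REJECTIONS):
            A = _draw_var_matrix(rng, n_vars, stability)
            if stability != "stable":
                break
            companion = np.block([
                [A, -A],
                [np.eye(n_vars), np.zeros((n_vars, n_vars))],
            ])
            if np.max(np.abs(np.linalg.eigvals(companion))) < 1.0:
                break
        else:
            raise GeneratorError(
                "could not draw an MVAR matrix with bounded level-form "
                f"dynamics in {_MAX_REJECTIONS} attempts"
            )
        B = rng.normal(0.0, 0.5, size=(nm, n_vars))
        params = MVARParams(
            A=A, B=B,
            intercept_x=rng.normal(0.0, 0.5, size=n_vars),
            intercept_s=rng.normal(0.0, 0.5, size=nm),
            noise_sd_x=noise_sd, noise_sd_s=noise_sd,
        )
        x0 = rng.normal(0.0, 1.0, size=n_vars)
        x1 = x0 + rng.normal(0.0, 1.0, size=n_vars)
        s0 = rng.normal(0.0, 1.0, size=nm)
        return params, simulate_mvar(
            params, n_steps, x0, x1, s0, seed=sim_seed
        )

    if model == "glv":
        mu = rng.uniform(0.3, 1.0, size=n_vars)
        M = rng.normal(0.0, 0.1, size=(n_vars, n_vars))
        np.fill_diagonal(M, -rng.uniform(0.8, 1.2, size=n_vars))  # self-limitation
        params = GLVParams(mu=mu, M=M)
        x0 = rng.uniform(0.05, 0.5, size=n_vars)
        times = np.linspace(0.0, 10.0, n_steps + 1)
        return params, simulate_glv(
            params, times, x0, noise_sd=noise_sd, seed=sim_seed
        )

    if model == "cr":
        nr = n_vars if n_metabolites is None else int(n_metabolites)
        params = CRParams(
            growth_yield=rng.uniform(0.2, 0.8, size=(n_vars, nr)),
            uptake_rate=rng.uniform(0.1, 1.0, size=(n_vars, nr)),
            death_rate=rng.uniform(0.05, 0.2, size=n_vars),
            resource_supply=rng.uniform(0.5, 1.5, size=nr),
            resource_dilution=0.1,
        )
        x0 = rng.uniform(0.05, 0.5, size=n_vars)
        r0 = rng.uniform(0.5, 1.5, size=nr)
        times = np.linspace(0.0, 20.0, n_steps + 1)
        return params, simulate_cr(params, times, x0, r0, seed=sim_seed,
                                   noise_sd=noise_sd)

    raise DynamicsError(f"unknown model {model!r}")
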