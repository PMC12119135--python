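"""Simulator correctness: hand-iterated recursions, closed forms, and an
independent fine-step Euler oracle for the ODE models."""

import numpy as np
import pytest

from microdyn import (
    CRParams,
    DynamicsError,
    GLVParams,
    MVARParams,
    VARParams,
    generate_fixture,
    simulate_cr,
    simulate_glv,
    simulate_mvar,
    simulate_var,
)


def euler_oracle(rhs, times, y0, dt=1e-4):
    """Brute-force explicit Euler on a fine grid, sampled at `times`."""
    times = np.asarray(times, float)
    grid_out = [np.asarray(y0, float)]
    y = np.asarray(y0, float).copy()
    t = times[0]
    for t_next in times[1:]:
        n_sub = max(int(np.ceil((t_next - t) / dt)), 1)
        h = (t_next - t) / n_sub
        for _ in range(n_sub):
            y = y + h * rhs(t, y)
        t = t_next
        grid_out.append(y.copy())
    return np.array(grid_out)


class TestSimulateVar:
    def test_geometric_contraction(self):
        p = VARParams(A=[[0.5]], intercept=0.0, noise_sd=0.0)
        ts = simulate_var(p, 3, [1.0], seed=0)
        assert np.allclose(ts.values.ravel(), [1, 0.5, 0.25, 0.125])

    def test_identity_fixed_point(self):
        p = VARParams(A=np.eye(2), noise_sd=0.0)
        ts = simulate_var(p, 5, [2.0, 3.0], seed=0)
        assert np.allclose(ts.values, np.tile([2.0, 3.0], (6, 1)))

    def test_swap_matrix_alternates(self):
        p = VARParams(A=[[0, 1], [1, 0]], noise_sd=0.0)
        ts = simulate_var(p, 3, [1.0, 2.0], seed=0)
        assert np.allclose(ts.values, [[1, 2], [2, 1], [1, 2], [2, 1]])

    def test_zero_noise_residuals_machine_zero(self, rng):
        A = rng.normal(0, 0.3, size=(3, 3))
        c = rng.normal(size=3)
        p = VARParams(A=A, intercept=c, noise_sd=0.0)
        ts = simulate_var(p, 50, rng.normal(size=3), seed=1)
        X = ts.values
        resid = X[1:] - X[:-1] @ A.T - c
        assert np.max(np.abs(resid)) < 1e-14

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DynamicsError):
            VARParams(A=[[0.5, 0.1]])
        with pytest.raises(DynamicsError):
            simulate_var(VARParams(A=[[0.5]]), 3, [1.0, 2.0], seed=0)

    def test_nonfinite_params_rejected(self):
        with pytest.raises(DynamicsError):
            VARParams(A=[[np.inf]])

    def test_spectral_radius_governs_zero_noise_limit(self, rng):
        A = rng.normal(0, 0.4, size=(3, 3))
        rho = np.max(np.abs(np.linalg.eigvals(A)))
        x0 = rng.normal(size=3)
        contract = VARParams(A=A * (0.8 / rho), noise_sd=0.0)
        expand = VARParams(A=A * (1.2 / rho), noise_sd=0.0)
        down = simulate_var(contract, 200, x0, seed=0).values
        up = simulate_var(expand, 200, x0, seed=0).values
        assert np.max(np.abs(down[-1])) < 1e-6
        assert np.max(np.abs(up[-1])) > np.max(np.abs(x0))


class TestSimulateMvar:
    def test_null_coupling_gives_constant_metabolite(self):
        p = MVARParams(A=[[0.5]], B=[[0.0]], intercept_s=[4.0],
                       noise_sd_x=0.0, noise_sd_s=0.0)
        ts = simulate_mvar(p, 10, [1.0], [2.0], [4.0], seed=0)
        met = ts.values[:, ts.metabolite_indices[0]]
        assert np.allclose(met, 4.0)

    def test_hand_iterated_recursion(self):
        p = MVARParams(A=[[1.0]], B=[[2.0]], noise_sd_x=0.0, noise_sd_s=0.0)
        ts = simulate_mvar(p, 1, [1.0], [3.0], [0.0], seed=0)
        # row 2: X2 = 1*(3-1) = 2, S2 = 2*(3-1) = 4
        assert ts.values[2, 0] == pytest.approx(2.0)
        assert ts.values[2, 1] == pytest.approx(4.0)

    def test_zero_difference_collapses_to_intercepts(self):
        p = MVARParams(A=[[0.7]], B=[[1.3]], intercept_x=[0.2],
                       intercept_s=[-0.4], noise_sd_x=0.0, noise_sd_s=0.0)
        ts = simulate_mvar(p, 5, [2.0], [2.0], [9.0], seed=0)
        # x1 == x0 so dX = 0 at t=2: X2 = 0.2; then dX alternates per recursion
        assert ts.values[2, 0] == pytest.approx(0.2)
        assert ts.values[2, 1] == pytest.approx(-0.4)

    def test_difference_response_variant(self):
        p = MVARParams(A=[[0.5]], B=[[1.0]], noise_sd_x=0.0, noise_sd_s=0.0)
        ts = simulate_mvar(p, 1, [1.0], [2.0], [0.0], seed=0,
                           response="difference")
        # X2 = X1 + 0.5*(X1-X0) = 2.5
        assert ts.values[2, 0] == pytest.approx(2.5)

    def test_kind_tags_partition_columns(self):
        p = MVARParams(A=np.eye(2) * 0.3, B=np.ones((3, 2)),
                       noise_sd_x=0.0, noise_sd_s=0.0)
        ts = simulate_mvar(p, 3, [1, 1], [1, 1], [0, 0, 0], seed=0)
        assert len(ts.taxon_indices) == 2
        assert len(ts.metabolite_indices) == 3


class TestSimulateGlv:
    def test_exponential_closed_form(self):
        r, c = 0.7, 0.3
        times = np.linspace(0, 5, 40)
        ts = simulate_glv(GLVParams(mu=[r], M=[[0.0]]), times, [c])
        assert np.allclose(ts.values[:, 0], c * np.exp(r * times), rtol=1e-6)

    def test_logistic_carrying_capacity(self):
        ts = simulate_glv(GLVParams(mu=[1.0], M=[[-1.0]]),
                          np.linspace(0, 20, 50), [0.01])
        assert ts.values[-1, 0] == pytest.approx(1.0, abs=1e-4)

    def test_two_species_competition_matches_euler_oracle(self):
        mu = np.array([1.0, 1.0])
        M = np.array([[-1.0, -0.5], [-0.5, -1.0]])
        times = np.linspace(0, 5, 26)
        x0 = np.array([0.2, 0.1])
        ts = simulate_glv(GLVParams(mu=mu, M=M), times, x0)
        oracle = euler_oracle(lambda t, x: x * (mu + M @ x), times, x0)
        rel = np.abs(ts.values - oracle) / np.maximum(np.abs(oracle), 1e-12)
        assert rel.max() < 1e-3

    def test_nonnegativity_preserved(self, rng):
        params = GLVParams(mu=rng.uniform(0.2, 1.0, 3),
                           M=-np.eye(3) + rng.normal(0, 0.1, (3, 3)))
        ts = simulate_glv(params, np.linspace(0, 10, 30),
                          rng.uniform(0.01, 0.5, 3))
        assert (ts.values >= 0).all()

    def test_negative_x0_rejected(self):
        with pytest.raises(DynamicsError):
            simulate_glv(GLVParams(mu=[1.0], M=[[-1.0]]), [0, 1], [-0.1])


class TestSimulateCr:
    def test_decoupled_system(self):
        p = CRParams(growth_yield=[[0.5]], uptake_rate=[[0.0]],
                     death_rate=[0.0], resource_supply=[2.0],
                     resource_dilution=0.5)
        ts = simulate_cr(p, np.linspace(0, 30, 60), [0.7], [0.1])
        assert np.allclose(ts.values[:, 0], 0.7, atol=1e-6)   # species constant
        assert ts.values[-1, 1] == pytest.approx(4.0, rel=1e-3)  # supply/dilution

    def test_single_pair_matches_euler_oracle(self):
        p = CRParams(growth_yield=[[0.5]], uptake_rate=[[1.0]],
                     death_rate=[0.1], resource_supply=[1.0],
                     resource_dilution=0.1)
        times = np.linspace(0, 10, 21)
        y0 = np.array([0.1, 1.0])

        def rhs(t, y):
            x, R = y
            return np.array([
                x * (0.5 * 1.0 * R - 0.1),
                1.0 - 0.1 * R - 1.0 * x * R,
            ])

        ts = simulate_cr(p, times, [0.1], [1.0])
        oracle = euler_oracle(rhs, times, y0)
        rel = np.abs(ts.values - oracle) / np.maximum(np.abs(oracle), 1e-12)
        assert rel.max() < 1e-3

    def test_sink_only_resources_non_increasing(self):
        p = CRParams(growth_yield=[[0.4]], uptake_rate=[[0.8]],
                     death_rate=[0.0], resource_supply=[0.0],
                     resource_dilution=0.0)
        ts = simulate_cr(p, np.linspace(0, 10, 40), [0.5], [1.0])
        res = ts.values[:, 1]
        assert np.all(np.diff(res) <= 1e-9)

    def test_resources_tagged_metabolite(self):
        p = CRParams(growth_yield=[[0.4]], uptake_rate=[[0.8]])
        ts = simulate_cr(p, [0, 1, 2], [0.5], [1.0])
        assert ts.kinds == ["taxon", "metabolite"]


class TestGenerateFixture:
    def test_stable_var_has_contracting_matrix(self):
        params, _ = generate_fixture("var", 4, 20, seed=7, stability="stable")
        assert params.spectral_radius < 1.0

    def test_unstable_var_has_expanding_matrix(self):
        params, _ = generate_fixture("var", 3, 5, seed=7, stability="unstable")
        assert params.spectral_radius > 1.0

    def test_same_seed_is_bit_reproducible(self):
        p1, s1 = generate_fixture("var", 3, 50, seed=42)
        p2, s2 = generate_fixture("var", 3, 50, seed=42)
        assert np.array_equal(p1.A, p2.A)
        assert np.array_equal(s1.values, s2.values)

    def test_different_seeds_differ(self):
        p1, _ = generate_fixture("var", 3, 10, seed=1)
        p2, _ = generate_fixture("var", 3, 10, seed=2)
        assert not np.allclose(p1.A, p2.A)

    def test_var_residual_sd_matches_requested_noise(self):
        params, series = generate_fixture(
            "var", 3, 500, seed=11, noise_sd=1.5, stability="stable"
        )
        X = series.values
        resid = X[1:] - X[:-1] @ params.A.T - params.intercept
        sd = resid.std()
        assert 1.35 <= sd <= 1.65  # within 10% of the nominal 1.5

    @pytest.mark.parametrize("model", ["var", "mvar", "glv", "cr"])
    def test_all_models_produce_finite_series(self, model):
        noise = 1.5 if model in ("var", "mvar") else 0.05
        params, series = generate_fixture(model, 2, 30, seed=3, noise_sd=noise)
        assert np.isfinite(series.values).all()

    def test_mvar_level_dynamics_bounded(self):
        _, series = generate_fixture("mvar", 3, 300, seed=5, noise_sd=0.5)
        assert np.abs(series.values).max() < 100.0
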