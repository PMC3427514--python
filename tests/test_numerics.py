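import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

import svzsim as sv
from svzsim.geometry import Box, build_aux_fields, single_box_grid
from svzsim.model import FieldState
from svzsim.numerics import (NumericsConfig, System, assemble_rhs, integrate,
                             laplacian_zero_flux, taxis_divergence, van_leer)


@pytest.fixture(scope="module")
def box_grid():
    return single_box_grid(Box(0, 2, 0, 1), 0.1)


class TestVanLeerLimiter:
    @given(st.floats(-1e6, 1e6, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_bounds(self, r):
        phi = van_leer(r)
        assert 0.0 <= phi <= 2.0
        if r <= 0:
            assert phi == 0.0

    def test_unit_ratio_and_symmetry_point(self):
        assert van_leer(1.0) == pytest.approx(1.0)
        assert van_leer(np.array([0.5]))[0] == pytest.approx(2 * 0.5 / 1.5)


class TestLaplacian:
    def test_constant_field_zero(self, box_grid):
        out = laplacian_zero_flux(np.full(box_grid.n_active, 3.7), box_grid)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_discrete_conservation(self, box_grid):
        rng = np.random.default_rng(0)
        u = rng.random(box_grid.n_active)
        out = laplacian_zero_flux(u, box_grid)
        assert out.sum() == pytest.approx(0.0, abs=1e-10)

    def test_exact_on_quadratic_interior(self, box_grid):
        """Second-order stencil differentiates x^2 exactly away from the
        reflecting boundary closure."""
        x = box_grid.xy[:, 0]
        out = laplacian_zero_flux(x ** 2, box_grid)
        interior = ((x > 0.15) & (x < 1.85)
                    & (box_grid.xy[:, 1] > 0.15)
                    & (box_grid.xy[:, 1] < 0.85))
        assert np.allclose(out[interior], 2.0, atol=1e-9)

    def test_second_order_convergence_on_manufactured_solution(self):
        """Observed order of accuracy >= 1.9 under h -> h/2 -> h/4 for a
        smooth Gaussian on a single box."""
        errs, hs = [], [0.05, 0.025, 0.0125]
        for h in hs:
            g = single_box_grid(Box(0, 1, 0, 1), h)
            x, y = g.xy[:, 0], g.xy[:, 1]
            r2 = (x - 0.5) ** 2 + (y - 0.5) ** 2
            w2 = 0.3 ** 2
            u = np.exp(-r2 / w2)
            exact = u * (4 * r2 / w2 ** 2 - 4 / w2)
            num = laplacian_zero_flux(u, g)
            interior = (np.abs(x - 0.5) < 0.3) & (np.abs(y - 0.5) < 0.3)
            errs.append(np.abs(num - exact)[interior].max())
        order1 = np.log2(errs[0] / errs[1])
        order2 = np.log2(errs[1] / errs[2])
        assert order1 >= 1.9 and order2 >= 1.9


class TestTaxis:
    def test_constant_potential_zero(self, box_grid):
        rng = np.random.default_rng(1)
        u = rng.random(box_grid.n_active)
        out = taxis_divergence(u, np.full_like(u, 2.0), 1.5, "attract",
                               box_grid)
        assert np.allclose(out, 0.0, atol=1e-14)

    def test_zero_density_zero(self, box_grid):
        pot = box_grid.xy[:, 0]
        out = taxis_divergence(np.zeros(box_grid.n_active), pot, 1.0,
                               "attract", box_grid)
        assert not out.any()

    def test_discrete_conservation_random_fields(self, box_grid):
        rng = np.random.default_rng(2)
        u = rng.random(box_grid.n_active)
        pot = rng.random(box_grid.n_active)
        for sign in ("attract", "repel"):
            out = taxis_divergence(u, pot, 2.3, sign, box_grid)
            assert out.sum() == pytest.approx(0.0, abs=1e-10)

    def test_step_density_matches_first_order_upwind_at_discontinuity(self):
        """On a 1-D ramp potential with a step density the limiter
        returns 0 at the extremum cells, reducing to first-order upwind;
        in smooth monotone regions it recovers the central flux."""
        g = single_box_grid(Box(0, 2, 0, 0.1), 0.1)   # 20x1 line of cells
        order = np.argsort(g.xy[:, 0])
        x = g.xy[order, 0]
        u = np.where(x < 1.0, 1.0, 0.0)[np.argsort(order)]
        pot = g.xy[:, 0].copy()            # unit velocity to the right
        out = taxis_divergence(u, pot, 1.0, "attract", g)

        # first-order upwind oracle on the 1-D line
        h = 0.1
        uo = u[order]
        flux = np.zeros(len(x) + 1)        # face j between cells j-1, j
        flux[1:-1] = uo[:-1]               # v = +1 -> take left cell
        oracle = -(flux[1:] - flux[:-1]) / h
        assert np.allclose(out[order], oracle, atol=1e-12)

    def test_smooth_monotone_region_recovers_central_flux(self):
        g = single_box_grid(Box(0, 2, 0, 0.1), 0.1)
        order = np.argsort(g.xy[:, 0])
        x = g.xy[:, 0]
        u = 1.0 + 0.3 * x                   # linear -> limiter ratio 1
        pot = x.copy()
        out = taxis_divergence(u, pot, 1.0, "attract", g)
        # central flux: face value = mean of neighbours; divergence of
        # 0.3*x slope field = -0.3 in the interior
        interior = (x > 0.25) & (x < 1.75)
        assert np.allclose(out[interior], -0.3, atol=1e-10)

    def test_nonfinite_potential_rejected(self, box_grid):
        pot = np.full(box_grid.n_active, np.nan)
        with pytest.raises(FloatingPointError):
            taxis_divergence(np.ones(box_grid.n_active), pot, 1.0,
                             "attract", box_grid)


class TestAssembleRhs:
    def test_zero_state_only_attractant_source(self, coarse_grid,
                                               ref_params):
        aux = build_aux_fields(coarse_grid, ref_params)
        state = FieldState.zeros(coarse_grid.n_active)
        rate = assemble_rhs(state, ref_params, aux, coarse_grid)
        assert np.array_equal(rate.f_A, aux.q)
        for f in ("n_B", "n_C", "n_A", "n_N"):
            assert not getattr(rate, f).any()

    def test_uniform_state_equals_pointwise_kinetics(self, ref_params):
        """Uniform fields with uniform auxiliaries have no gradients, so
        transport vanishes and assemble_rhs equals reaction_rhs."""
        from svzsim.model import reaction_rhs

        g = single_box_grid(Box(0, 1, 0, 1), 0.1)
        p = ref_params.replace(a_1=0.0, a_4=0.0, d=0.0)  # uniform aux
        aux = build_aux_fields(g, p)
        state = FieldState(*(np.full(g.n_active, v)
                             for v in (0.0, 0.0, 0.4, 0.2, 0.6)))
        full = assemble_rhs(state, p, aux, g)
        react = reaction_rhs(state, aux, p, g)
        for f in FieldState.FIELDS:
            assert np.allclose(getattr(full, f), getattr(react, f),
                               atol=1e-12)

    def test_equals_sum_of_parts(self, coarse_grid, ref_params):
        from svzsim.model import reaction_rhs

        aux = build_aux_fields(coarse_grid, ref_params)
        rng = np.random.default_rng(4)
        n = coarse_grid.n_active
        state = FieldState(*(0.1 * rng.random(n) for _ in range(5)))
        state.n_B *= coarse_grid.masks["svz"]
        state.n_C *= coarse_grid.masks["svz"]
        full = assemble_rhs(state, ref_params, aux, coarse_grid)
        react = reaction_rhs(state, aux, ref_params, coarse_grid)
        p = ref_params
        nA_expect = (react.n_A
                     + p.delta_A * laplacian_zero_flux(state.n_A, coarse_grid)
                     + taxis_divergence(state.n_A, state.f_A, p.eta_A,
                                        "attract", coarse_grid))
        nN_expect = (react.n_N
                     + p.delta_N * laplacian_zero_flux(state.n_N, coarse_grid)
                     + taxis_divergence(state.n_N, aux.g, p.eta_N, "repel",
                                        coarse_grid))
        fA_expect = react.f_A + p.delta_fA * laplacian_zero_flux(
            state.f_A, coarse_grid)
        assert np.allclose(full.n_A, nA_expect, atol=1e-12)
        assert np.allclose(full.n_N, nN_expect, atol=1e-12)
        assert np.allclose(full.f_A, fA_expect, atol=1e-12)
        assert np.allclose(full.n_B, react.n_B)
        assert np.allclose(full.n_C, react.n_C)

    def test_compiled_kernel_matches_numpy_reference(self, coarse_grid,
                                                     coarse_system,
                                                     ref_params):
        aux = build_aux_fields(coarse_grid, ref_params)
        f_ref = coarse_system.rhs(ref_params, aux, compiled=False)
        f_fast = coarse_system.rhs(ref_params, aux, compiled=True)
        rng = np.random.default_rng(5)
        y = rng.random(coarse_system.ndof)
        assert np.allclose(f_ref(0.0, y), f_fast(0.0, y),
                           rtol=1e-13, atol=1e-13)


class TestIntegrate:
    def test_scalar_exponential_decay(self):
        cfg = NumericsConfig(tolerance=1e-6, t_final=1.0, save_every=0.5)
        res = integrate(lambda t, y: -y, np.array([1.0]), (0.0, 1.0), cfg)
        assert res.success
        assert res.states[-1, 0] == pytest.approx(np.exp(-1.0),
                                                  abs=10 * 1e-6)

    def test_stiff_pair_matches_matrix_exponential(self):
        A = np.array([[-1.0, 0.5], [0.0, -1000.0]])
        y0 = np.array([1.0, 1.0])
        cfg = NumericsConfig(tolerance=1e-6, t_final=2.0, save_every=0.1)
        res = integrate(lambda t, y: A @ y, y0, (0.0, 2.0), cfg)
        assert res.success
        exact = expm(2.0 * A) @ y0
        assert np.allclose(res.states[-1], exact, atol=1e-4)
        # no oscillation: the fast component decays monotonically
        assert (np.diff(res.states[:, 1]) <= 1e-12).all()

    def test_tolerance_controls_error_monotonically(self):
        A = np.array([[-1.0, 0.5], [0.0, -1000.0]])
        y0 = np.array([1.0, 1.0])
        ref = expm(1.0 * A) @ y0
        errs = []
        for tol in (1e-4, 1e-6, 1e-8):
            cfg = NumericsConfig(tolerance=tol, t_final=1.0, save_every=0.5)
            res = integrate(lambda t, y: A @ y, y0, (0.0, 1.0), cfg)
            errs.append(np.abs(res.states[-1] - ref).max())
        assert errs[2] <= errs[0]

    def test_budget_exhaustion_flags_failure(self):
        cfg = NumericsConfig(t_final=10.0, save_every=1.0, max_nfev=50)
        res = integrate(lambda t, y: np.array([np.sin(t) * 100]),
                        np.array([0.0]), (0.0, 10.0), cfg)
        assert not res.success
        assert "budget" in res.message

    def test_blowup_terminates_early(self):
        cfg = NumericsConfig(t_final=50.0, save_every=1.0,
                             blowup_factor=1e3)
        res = integrate(lambda t, y: y, np.array([1.0]), (0.0, 50.0), cfg)
        assert not res.success
        assert res.blew_up
        assert res.times[-1] < 50.0
        assert len(res.times) > 2        # partial trajectory retained

    def test_transport_only_conserves_mass(self, coarse_grid, coarse_system,
                                           ref_params):
        """With all reactions off, each field's total is conserved."""
        p = ref_params.replace(
            beta_B=0, beta_C=0, beta_Ai=0, beta_Ao=0, alpha_C=0, alpha_A=0,
            gamma_B=0, gamma_C=0, gamma_A=0, gamma_N=0, kappa_A=0,
            kappa_B=0, kappa_C=0, kappa_D=0, lam=0, a_1=0, d=0)
        aux = build_aux_fields(coarse_grid, p)
        f = coarse_system.rhs(p, aux)
        state = FieldState.zeros(coarse_grid.n_active)
        state.n_A = sv.gaussian_field(coarse_grid, (1.0, 1.0), 1.0, 0.4)
        state.n_N = sv.gaussian_field(coarse_grid, (3.0, 1.0), 1.0, 0.4)
        state.f_A = sv.gaussian_field(coarse_grid, (2.0, 1.0), 1.0, 0.8)
        y0 = coarse_system.pack_state(state)
        cfg = NumericsConfig(tolerance=1e-6, t_final=5.0, save_every=1.0)
        res = integrate(f, y0, (0.0, 5.0), cfg,
                        jac=coarse_system.jac_fd(f))
        assert res.success
        traj = coarse_system.unpack_trajectory(res.states)
        for k in (2, 3, 4):
            totals = traj[:, k, :].sum(axis=1)
            assert np.allclose(totals, totals[0], atol=1e-3 * max(
                totals[0], 1.0))

    def test_positivity_on_reference_run(self, ref_run_coarse):
        states = ref_run_coarse.states
        for k in range(5):
            fmax = states[:, k, :].max()
            assert states[:, k, :].min() >= -1e-8 * fmax
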