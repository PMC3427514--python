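import numpy as np
import pytest

import svzsim as sv
from svzsim.model import ModelParameters
from svzsim.simulation import SimulationResult, TimeSeries
from svzsim.sloppiness import (MetricSample, MetricSurface, eigen_spectrum,
                               fit_surface, hessian, hessian_at,
                               validate_surface, zeta_squared)


def toy_result(grid, times, fields, params, config):
    """Hand-built SimulationResult with prescribed field frames."""
    states = np.asarray(fields, dtype=float)
    readouts = {"ob_signal": TimeSeries(times, states[:, 2, :].sum(axis=1),
                                        "ob_signal")}
    return SimulationResult(times=np.asarray(times, float), states=states,
                            readouts=readouts, solver_stats={},
                            failure_flag=False, params_used=params,
                            grid=grid, config=config)


@pytest.fixture(scope="module")
def toy_grid():
    from svzsim.geometry import Box, single_box_grid

    return single_box_grid(Box(0, 0.6, 0, 0.6), 0.1)   # 6x6 cells


@pytest.fixture(scope="module")
def toy_config():
    return sv.NumericsConfig(t_final=10.0, save_every=1.0)


class TestZetaSquared:
    def test_identical_trajectories_give_zero(self, toy_grid, ref_params,
                                              toy_config):
        times = np.linspace(0, 10, 11)
        rng = np.random.default_rng(0)
        fields = rng.random((11, 5, toy_grid.n_active))
        a = toy_result(toy_grid, times, fields, ref_params, toy_config)
        b = toy_result(toy_grid, times, fields.copy(), ref_params,
                       toy_config)
        assert zeta_squared(a, b) == 0.0

    def test_symmetric_in_arguments(self, toy_grid, ref_params, toy_config):
        times = np.linspace(0, 10, 11)
        rng = np.random.default_rng(1)
        fa = rng.random((11, 5, toy_grid.n_active))
        fb = rng.random((11, 5, toy_grid.n_active))
        a = toy_result(toy_grid, times, fa, ref_params, toy_config)
        b = toy_result(toy_grid, times, fb, ref_params, toy_config)
        assert zeta_squared(a, b) == pytest.approx(zeta_squared(b, a),
                                                   rel=1e-14)

    def test_constant_offset_closed_form(self, toy_grid, ref_params,
                                         toy_config):
        """Two constant trajectories differing by c in one species:
        zeta^2 = c^2 * X_b * Y_b * T_c / (2 T_c N_s) up to the half-cell
        rim the cell-centred trapezoid omits."""
        times = np.linspace(0, 10, 11)
        base = np.zeros((11, 5, toy_grid.n_active))
        other = base.copy()
        c = 0.7
        other[:, 2, :] = c
        a = toy_result(toy_grid, times, base, ref_params, toy_config)
        b = toy_result(toy_grid, times, other, ref_params, toy_config)
        T_c, Ns = 10.0, 5
        exact = c ** 2 * 0.6 * 0.6 * T_c / (2 * T_c * Ns)
        covered = c ** 2 * 0.5 ** 2 * T_c / (2 * T_c * Ns)  # trapezoid span
        val = zeta_squared(a, b)
        assert val == pytest.approx(covered, rel=1e-12)
        assert val == pytest.approx(exact, rel=0.4)

    def test_agrees_with_riemann_sum_oracle(self, toy_grid, ref_params,
                                            toy_config):
        """Successive-trapezoid evaluation within 5% of a flat Riemann
        sum on a smooth 6x6-cell, 10-frame toy pair."""
        times = np.linspace(0, 10, 10)
        x, y = toy_grid.xy[:, 0], toy_grid.xy[:, 1]
        # smooth bumps vanishing at the rim, like the interior-supported
        # PDE fields (both quadratures then approximate the same mass)
        bump = np.exp(-((x - 0.3) ** 2 + (y - 0.3) ** 2) / 0.1 ** 2)
        fa = np.zeros((10, 5, toy_grid.n_active))
        fb = np.zeros_like(fa)
        for k, t in enumerate(times):
            fb[k, 0, :] = bump * np.exp(-t / 30)
            fb[k, 3, :] = bump * (0.25 + 0.05 * t / 10)
        a = toy_result(toy_grid, times, fa, ref_params, toy_config)
        b = toy_result(toy_grid, times, fb, ref_params, toy_config)
        val = zeta_squared(a, b)
        h2 = toy_grid.cell_area
        dt = times[1] - times[0]
        diff2 = (fb - fa) ** 2
        # flat Riemann: h^2 per cell, left-endpoint rule over the 9
        # time intervals
        riemann = diff2[:-1].sum() * h2 * dt / (2 * 10.0 * 5)
        assert val == pytest.approx(riemann, rel=0.05)

    def test_species_relabelling_invariance(self, toy_grid, ref_params,
                                            toy_config):
        times = np.linspace(0, 10, 6)
        rng = np.random.default_rng(2)
        fa = rng.random((6, 5, toy_grid.n_active))
        fb = rng.random((6, 5, toy_grid.n_active))
        perm = [4, 0, 3, 1, 2]
        a1 = toy_result(toy_grid, times, fa, ref_params, toy_config)
        b1 = toy_result(toy_grid, times, fb, ref_params, toy_config)
        a2 = toy_result(toy_grid, times, fa[:, perm], ref_params, toy_config)
        b2 = toy_result(toy_grid, times, fb[:, perm], ref_params, toy_config)
        assert zeta_squared(a1, b1) == pytest.approx(
            zeta_squared(a2, b2), rel=1e-14)

    def test_mismatched_times_rejected(self, toy_grid, ref_params,
                                       toy_config):
        a = toy_result(toy_grid, np.linspace(0, 10, 6),
                       np.zeros((6, 5, toy_grid.n_active)), ref_params,
                       toy_config)
        b = toy_result(toy_grid, np.linspace(0, 10, 7),
                       np.zeros((7, 5, toy_grid.n_active)), ref_params,
                       toy_config)
        with pytest.raises(ValueError):
            zeta_squared(a, b)


def quad_samples(ref, n, seed, c=(3.0, 0.5)):
    """Synthetic quadratic-bowl metric over (beta_B, beta_C)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        db, dc = rng.uniform(-1, 1, 2)
        p = ref.replace(beta_B=ref.beta_B + db, beta_C=ref.beta_C + dc)
        out.append(MetricSample(p, c[0] * db ** 2 + c[1] * dc ** 2))
    return out


class TestFitSurface:
    @pytest.mark.parametrize("method", ["obtuse-angle", "idw", "rbf"])
    def test_exact_at_training_points(self, ref_params, method):
        samples = quad_samples(ref_params, 30, seed=3)
        surf = fit_surface(samples, method=method)
        for s in samples[::5]:
            assert surf(s.theta.as_array()) == pytest.approx(s.zeta2,
                                                             abs=1e-8)

    def test_single_sample_constant_fallback(self, ref_params):
        surf = fit_surface([MetricSample(ref_params, 2.5)])
        probe = ref_params.replace(beta_B=9.0)
        assert surf(probe.as_array()) == 2.5

    def test_duplicates_deduplicated_with_warning(self, ref_params):
        samples = quad_samples(ref_params, 10, seed=4)
        with pytest.warns(UserWarning, match="duplicate"):
            surf = fit_surface(samples + [samples[0]])
        assert len(surf.values) == 10

    def test_quadratic_bowl_interpolation_error(self, ref_params):
        """Default backend reconstructs a 2-parameter quadratic bowl to
        <20% mean relative error from 50 scattered samples."""
        samples = quad_samples(ref_params, 50, seed=5)
        surf = fit_surface(samples)
        rng = np.random.default_rng(6)
        rel = []
        for _ in range(40):
            db, dc = rng.uniform(-0.8, 0.8, 2)
            true = 3.0 * db ** 2 + 0.5 * dc ** 2
            if true < 0.05:        # relative error undefined near the pit
                continue
            p = ref_params.replace(beta_B=ref_params.beta_B + db,
                                   beta_C=ref_params.beta_C + dc)
            rel.append(abs(surf(p.as_array()) - true) / true)
        assert np.mean(rel) < 0.20

    def test_validate_surface_holdout_statistic(self, ref_params):
        surf = fit_surface(quad_samples(ref_params, 50, seed=7))
        fresh = quad_samples(ref_params, 10, seed=8)
        m = validate_surface(surf, fresh)
        assert surf.holdout_n == 10
        assert 0 <= m < 1.0


class TestHessian:
    def test_exact_on_diagonal_quadratic(self):
        c = np.array([2.0, 5.0, 0.5])
        f = lambda x: float((c * x ** 2).sum())   # noqa: E731
        H = hessian(f, np.array([1.0, 2.0, 3.0]), rel_step=1e-3)
        assert np.allclose(np.diag(H), 2 * c, rtol=1e-6)
        off = H - np.diag(np.diag(H))
        assert np.abs(off).max() < 1e-6

    def test_symmetric_by_construction(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(4, 4))
        f = lambda x: float(np.sin(x @ A @ x) + (x ** 4).sum())  # noqa: E731
        H = hessian(f, np.array([0.3, -0.2, 0.5, 0.1]), rel_step=1e-3)
        assert np.array_equal(H, H.T)

    def test_rosenbrock_quartic_matches_analytic(self):
        """f = 100(y - x^2)^2 + (1 - x)^2 at (1.2, 1.0)."""
        def f(v):
            x, y = v
            return 100 * (y - x * x) ** 2 + (1 - x) ** 2

        x0 = np.array([1.2, 1.0])
        H = hessian(f, x0, rel_step=1e-3)
        x, y = x0
        exact = np.array([[1200 * x ** 2 - 400 * y + 2, -400 * x],
                          [-400 * x, 200.0]])
        assert np.allclose(H, exact, rtol=1e-2)

    def test_nonfinite_evaluation_reported(self):
        f = lambda x: float("nan")    # noqa: E731
        with pytest.raises(FloatingPointError):
            hessian(f, np.array([1.0, 2.0]), rel_step=1e-3)

    def test_hessian_at_subset(self, ref_params):
        surf = fit_surface(quad_samples(ref_params, 50, seed=10))
        H = hessian_at(surf, ref_params, names=["beta_B", "beta_C"],
                       rel_step=1e-2)
        assert H.shape == (2, 2)
        assert H[0, 0] > H[1, 1] > 0     # bowl is stiffer along beta_B


class TestEigenSpectrum:
    def test_identity_not_sloppy(self):
        rep = eigen_spectrum(np.eye(5))
        assert rep.span_orders == 0.0
        assert rep.axis_ratio == 1.0
        assert not rep.sloppy

    def test_two_scale_diagonal(self):
        rep = eigen_spectrum(np.diag([1.0, 1e-10]))
        assert rep.span_orders == pytest.approx(10.0)
        assert rep.axis_ratio == pytest.approx(1e5)
        # 10 orders in one jump: wide but sharply gapped, so not sloppy
        assert rep.max_gap_orders == pytest.approx(10.0)
        assert not rep.sloppy

    def test_spread_ladder_is_sloppy(self):
        lam = 10.0 ** -np.arange(6)          # 1, 0.1, ..., 1e-5
        rep = eigen_spectrum(np.diag(lam))
        assert rep.sloppy
        assert rep.span_orders == pytest.approx(5.0)
        assert np.allclose(rep.normalized_spectrum, lam)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(6, 6))
        H = A @ np.diag(10.0 ** -np.arange(6)) @ A.T
        r1 = eigen_spectrum(H)
        r2 = eigen_spectrum(137.0 * H)
        assert np.allclose(r1.normalized_spectrum, r2.normalized_spectrum)
        assert r1.span_orders == pytest.approx(r2.span_orders)
        assert r1.axis_ratio == pytest.approx(r2.axis_ratio)
        assert r1.sloppy == r2.sloppy

    def test_asymmetric_rejected(self):
        M = np.array([[1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            eigen_spectrum(M)

    def test_span_axis_ratio_relation(self):
        rng = np.random.default_rng(12)
        A = rng.normal(size=(5, 5))
        rep = eigen_spectrum(A + A.T)
        assert rep.span_orders == pytest.approx(
            2 * np.log10(rep.axis_ratio), rel=1e-10)
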