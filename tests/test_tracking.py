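import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from elastrack import (
    AdaptiveEps,
    DisplacementField,
    PoissonMap,
    SolverError,
    TrackingParams,
    adaptive_eps,
    assemble_unmixed_system,
    assemble_system,
    evaluate_cost,
    mixed_stencil,
    preset,
    smooth_abs,
    solve_increment,
    track,
    update_poisson,
    warp_and_residual,
)
from elastrack.exceptions import ParameterError
from elastrack.initialization import IntegerDisplacementField
from elastrack.tracking import LinearSystem
import scipy.sparse as sp


def random_state(m=8, n=8, seed=0):
    """Small random frames + displacement state shared by assembly tests."""
    rng = np.random.default_rng(seed)
    I1 = rng.standard_normal((m, n))
    I2 = rng.standard_normal((m, n))
    disp = DisplacementField(
        0.1 * rng.standard_normal((m, n)), 0.1 * rng.standard_normal((m, n))
    )
    nu = PoissonMap(np.full((m, n), 0.49))
    eps = adaptive_eps(disp, 3)
    return I1, I2, disp, nu, eps


class TestSmoothAbs:
    def test_value_and_weight_at_zero(self):
        value, weight = smooth_abs(0.0, 0.01)
        assert value == pytest.approx(0.01)
        assert weight == pytest.approx(100.0)

    def test_approaches_absolute_value(self):
        value, _ = smooth_abs(3.0, 1e-8)
        assert value == pytest.approx(3.0, abs=1e-8)

    def test_derivative_vanishes_at_kink(self):
        h = 1e-7
        d = (smooth_abs(h, 1e-3)[0] - smooth_abs(-h, 1e-3)[0]) / (2 * h)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ParameterError):
            smooth_abs(1.0, 0.0)


class TestWarpAndResidual:
    def test_zero_disp_identical_frames(self):
        rng = np.random.default_rng(1)
        I = rng.standard_normal((16, 12))
        mu, _, _ = warp_and_residual(I, I, DisplacementField(np.zeros((16, 12)), np.zeros((16, 12))))
        np.testing.assert_allclose(mu, 0.0, atol=1e-10)

    def test_gradients_exact_on_linear_image(self):
        m, n, c1, c2 = 14, 11, 1.7, -0.6
        i = np.arange(m)[:, None] * np.ones((1, n))
        j = np.ones((m, 1)) * np.arange(n)[None, :]
        I2 = c1 * i + c2 * j
        rng = np.random.default_rng(2)
        disp = DisplacementField(
            0.3 * rng.random((m, n)), 0.3 * rng.random((m, n))
        )
        mu, ga, gl = warp_and_residual(np.zeros((m, n)), I2, disp)
        interior = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(ga[interior], c1, atol=1e-8)
        np.testing.assert_allclose(gl[interior], c2, atol=1e-8)

    def test_subsample_shift_consistency(self):
        """I2 = I1 shifted by half a sample; warping by a = -0.5 must
        nearly cancel the residual on the interior."""
        rng = np.random.default_rng(3)
        I1 = gaussian_filter(rng.standard_normal((80, 20)), 1.5)
        ii, jj = np.meshgrid(np.arange(80), np.arange(20), indexing="ij")
        I2 = map_coordinates(I1, [ii + 0.5, jj], order=3, mode="nearest")
        disp = DisplacementField(np.full((80, 20), -0.5), np.zeros((80, 20)))
        mu, _, _ = warp_and_residual(I1, I2, disp)
        interior = (slice(4, -4), slice(2, -2))
        assert np.abs(mu[interior]).max() < 0.01 * np.ptp(I1)


class TestAdaptiveEps:
    def test_zero_field_gives_zero_eps(self):
        init = IntegerDisplacementField.zeros((20, 10))
        eps = adaptive_eps(init, 5)
        for name in ("eps_aa", "eps_al", "eps_la", "eps_ll"):
            np.testing.assert_array_equal(getattr(eps, name), 0.0)

    def test_uniform_compression_gives_constant_eps(self):
        m, n = 40, 12
        a = -0.02 * np.arange(m)[:, None] * np.ones((1, n))
        disp = DisplacementField(a, np.zeros((m, n)))
        eps = adaptive_eps(disp, 5)
        np.testing.assert_allclose(eps.eps_aa, -0.02, atol=1e-12)
        np.testing.assert_allclose(eps.eps_al, 0.0, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((15, 9))
        l = rng.standard_normal((15, 9))
        window = 3
        eps = adaptive_eps(DisplacementField(a, l), window)

        def backward(f, axis):
            d = np.diff(f, axis=axis)
            first = np.take(d, [0], axis=axis)
            return np.concatenate([first, d], axis=axis)

        def loop_mean(f):
            m, n = f.shape
            h = window // 2
            out = np.empty_like(f)
            for i in range(m):
                for j in range(n):
                    acc = 0.0
                    for di in range(-h, h + 1):
                        for dj in range(-h, h + 1):
                            # "nearest" edge handling
                            ci = min(max(i + di, 0), m - 1)
                            cj = min(max(j + dj, 0), n - 1)
                            acc += f[ci, cj]
                    out[i, j] = acc / window**2
            return out

        np.testing.assert_allclose(
            eps.eps_aa, loop_mean(backward(a, 0)), atol=1e-12
        )
        np.testing.assert_allclose(
            eps.eps_ll, loop_mean(backward(l, 1)), atol=1e-12
        )


class TestMixedStencil:
    def test_bilinear_coefficient(self):
        f = np.fromfunction(lambda i, j: i * j, (6, 6))
        for i in range(1, 6):
            for j in range(1, 6):
                assert mixed_stencil(f, i, j) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "f",
        [np.full((5, 5), 3.7), np.fromfunction(lambda i, j: i**2 + j**2, (5, 5))],
    )
    def test_zero_on_constant_and_pure_quadratic(self, f):
        for i in range(1, 5):
            for j in range(1, 5):
                assert mixed_stencil(f, i, j) == pytest.approx(0.0)

    def test_two_by_two_patch(self):
        assert mixed_stencil(np.array([[0.0, 0.0], [0.0, 1.0]]), 1, 1) == 1.0

    def test_border_rejected(self):
        with pytest.raises(ParameterError):
            mixed_stencil(np.zeros((4, 4)), 0, 2)


class TestAssembly:
    def test_perfect_fit_no_regularization_gives_zero_increment(self):
        rng = np.random.default_rng(5)
        I = rng.standard_normal((10, 8))
        disp = DisplacementField(np.zeros((10, 8)), np.zeros((10, 8)))
        params = TrackingParams(
            wf=0.0, ws=0.0, alpha1s=0.0, alpha2s=0.0, alpha3s=0.0,
            alpha_mix=0.0, beta1s=0.0, beta2s=0.0, beta_mix=0.0,
        )
        system = assemble_system(
            I, I, disp, PoissonMap(np.full((10, 8), 0.49)),
            AdaptiveEps.zeros((10, 8)), params,
        )
        np.testing.assert_allclose(system.rhs, 0.0, atol=1e-10)
        da, dl = solve_increment(system)
        np.testing.assert_array_equal(da, 0.0)
        np.testing.assert_array_equal(dl, 0.0)

    def test_reduction_to_unmixed_baseline_is_bit_identical(self):
        I1, I2, disp, nu, eps = random_state(seed=6)
        params = preset("simulated")
        via_zeroed = assemble_system(I1, I2, disp, nu, eps, params.without_mixed())
        baseline = assemble_unmixed_system(I1, I2, disp, nu, eps, params)
        assert (via_zeroed.A != baseline.A).nnz == 0
        np.testing.assert_array_equal(via_zeroed.rhs, baseline.rhs)

    def test_matrix_symmetric_positive_definite(self):
        I1, I2, disp, nu, eps = random_state(seed=7)
        system = assemble_system(I1, I2, disp, nu, eps, preset("simulated"))
        asym = abs(system.A - system.A.T).max()
        assert asym == 0.0
        eigmin = np.linalg.eigvalsh(system.A.toarray()).min()
        assert eigmin > 0.0


class TestSolveIncrement:
    def test_order8_matches_dense_oracle(self):
        rng = np.random.default_rng(8)
        # hand-built SPD system of order 8 = 2*(2x2 grid)
        B = rng.standard_normal((8, 8))
        A = sp.csr_matrix(B @ B.T + 8 * np.eye(8))
        rhs = rng.standard_normal(8)
        system = LinearSystem(A=A, rhs=rhs, shape=(2, 2))
        da, dl = solve_increment(system)
        x = np.empty(8)
        x[0::2] = da.ravel(order="F")
        x[1::2] = dl.ravel(order="F")
        np.testing.assert_allclose(x, np.linalg.solve(A.toarray(), rhs), atol=1e-10)

    def test_residual_contract_on_random_assemblies(self):
        for seed in range(3):
            I1, I2, disp, nu, eps = random_state(seed=seed)
            system = assemble_system(I1, I2, disp, nu, eps, preset("simulated"))
            da, dl = solve_increment(system, tol=1e-8)
            x = np.empty(system.rhs.size)
            x[0::2] = da.ravel(order="F")
            x[1::2] = dl.ravel(order="F")
            res = np.linalg.norm(system.A @ x - system.rhs)
            assert res <= 1e-8 * np.linalg.norm(system.rhs)

    def test_singular_system_raises_solver_error(self):
        A = sp.csr_matrix(np.zeros((4, 4)))
        with pytest.raises(SolverError):
            solve_increment(LinearSystem(A=A, rhs=np.ones(4), shape=(1, 2)))


class TestUpdatePoisson:
    params = preset("simulated")

    def test_uniform_strain_ratio(self):
        m, n = 30, 20
        a = -0.02 * np.arange(m)[:, None] * np.ones((1, n))
        l = 0.0098 * (np.arange(n)[None, :] - n / 2) * np.ones((m, 1))
        disp = DisplacementField(a, l)
        prev = PoissonMap(np.full((m, n), 0.3))
        out = update_poisson(disp, prev, self.params)
        np.testing.assert_allclose(out.nu, 0.49, atol=1e-10)

    def test_floor_keeps_previous_value(self):
        disp = DisplacementField(np.zeros((10, 8)), np.zeros((10, 8)))
        prev = PoissonMap(np.full((10, 8), 0.37))
        out = update_poisson(disp, prev, self.params)
        np.testing.assert_allclose(out.nu, 0.37)

    def test_ratio_clamped_to_bounds(self):
        m, n = 20, 16
        a = -0.01 * np.arange(m)[:, None] * np.ones((1, n))
        l = 0.008 * np.arange(n)[None, :] * np.ones((m, 1))  # raw ratio 0.8
        out = update_poisson(
            DisplacementField(a, l), PoissonMap(np.full((m, n), 0.49)), self.params
        )
        np.testing.assert_allclose(out.nu, 0.5, atol=1e-12)


class TestEvaluateCost:
    def test_zero_state_cost_is_delta_floor_sum(self):
        rng = np.random.default_rng(9)
        I = rng.standard_normal((10, 8))
        m, n = I.shape
        disp = DisplacementField(np.zeros((m, n)), np.zeros((m, n)))
        nu = PoissonMap(np.full((m, n), 0.49))
        params = preset("simulated")
        cost = evaluate_cost(I, I, disp, nu, AdaptiveEps.zeros((m, n)), params)
        d = params.l1_delta
        first = params.wf * (
            params.alpha1s * (m - 1) * n
            + params.alpha2s * m * (n - 1)
            + params.beta1s * (m - 1) * n
            + params.beta2s * m * (n - 1)
        )
        second = params.ws * (
            params.alpha1s * (m - 2) * n
            + params.alpha2s * m * (n - 2)
            + params.beta1s * (m - 2) * n
            + params.beta2s * m * (n - 2)
        )
        mixed = params.ws * (params.alpha_mix + params.beta_mix) * (m - 1) * (n - 1)
        mech = params.alpha3s * (m - 1) * (n - 1)
        assert cost == pytest.approx(d * (first + second + mixed + mech), rel=1e-12)

    def test_reduction_equals_unmixed_objective(self):
        I1, I2, disp, nu, eps = random_state(seed=10)
        params = preset("simulated")
        full = evaluate_cost(I1, I2, disp, nu, eps, params.without_mixed())
        d = params.l1_delta
        # removing the mixed penalty exactly accounts for the difference
        mixed_a = (
            disp.a[1:, 1:] - disp.a[1:, :-1] - disp.a[:-1, 1:] + disp.a[:-1, :-1]
        )
        mixed_l = (
            disp.l[1:, 1:] - disp.l[1:, :-1] - disp.l[:-1, 1:] + disp.l[:-1, :-1]
        )
        expected_gap = params.ws * (
            params.alpha_mix * np.sqrt(mixed_a**2 + d * d).sum()
            + params.beta_mix * np.sqrt(mixed_l**2 + d * d).sum()
        )
        with_mixed = evaluate_cost(I1, I2, disp, nu, eps, params)
        assert with_mixed - full == pytest.approx(expected_gap, rel=1e-10)


class TestTrack:
    def test_identical_frames_converge_immediately(self):
        rng = np.random.default_rng(11)
        I = gaussian_filter(rng.standard_normal((40, 16)), 1.0)
        init = IntegerDisplacementField.zeros((40, 16))
        params = preset("simulated").replace(n_outer_iters=5)
        disp, _, log = track(I, I, init, params)
        assert np.abs(disp.a).max() < 1e-3
        assert np.abs(disp.l).max() < 1e-3
        assert log[-1].get("converged", False)
        assert log[-1]["iteration"] <= 2
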