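"""Block solver: prox operator, KKT-certified solves, solver agreement."""

import numpy as np
import pytest
import scipy.fft as spfft

from cacs.operators import lambda_max, make_operator, spectrum_weights
from cacs.optics import make_system_psf
from cacs.solver import SolveConfig, soft_threshold, solve_block, upsample_passthrough


class TestSoftThreshold:
    def test_real_shrinkage(self):
        assert soft_threshold(3.0, 1.0) == pytest.approx(2.0)
        assert soft_threshold(-3.0, 1.0) == pytest.approx(-2.0)

    def test_below_threshold_is_exact_zero(self):
        z = np.array([0.5 + 0.2j, -0.1j, 0.0])
        out = soft_threshold(z, 1.0)
        assert np.all(out == 0)

    def test_phase_preserved(self, rng):
        z = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        out = soft_threshold(z, 0.3)
        nz = out != 0
        np.testing.assert_allclose(np.angle(out[nz]), np.angle(z[nz]), atol=1e-12)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


def positive_otf_psf():
    # narrow Gaussian: strictly positive OTF on a 16^3 grid
    return make_system_psf("gaussian", {"sigma_xy": 0.45, "sigma_z": 0.45}, 1.0)


class TestSolveBlock:
    def test_lam_zero_s1_matches_inverse_filter(self, rng):
        # with s = 1 and a strictly positive OTF, the lam -> 0 solution is
        # plain Fourier-division deconvolution (computed independently)
        psf = positive_otf_psf()
        op = make_operator(psf, (16, 16, 16), factor=1)
        truth = rng.random((16, 16, 16))
        y = op.forward_spatial(truth)
        res = solve_block(y, op, 0.0, SolveConfig(max_iter=4000, tol=1e-14, nonneg="none",
                                                  continuation=False))
        otf = op.otf_full()
        assert np.abs(otf).min() > 1e-3
        direct = spfft.ifftn(spfft.fftn(y) / otf).real
        assert np.linalg.norm(res.spatial - direct) / np.linalg.norm(direct) < 1e-6

    def test_objective_matches_long_run_proximal_oracle(self, small_psf, rng):
        # independent oracle: plain (unaccelerated) proximal gradient with a
        # conservative step, run to high accuracy on an 8^3 instance
        op = make_operator(small_psf, (8, 8, 8), factor=2)
        y = rng.random((4, 4, 4))
        lam = 0.2 * lambda_max(y, op)
        res = solve_block(y, op, lam, SolveConfig(max_iter=3000, tol=1e-12, nonneg="none",
                                                  continuation=False))
        L = 2.0 * op.norm_sq(seed=0)
        step = 0.5 / L
        x = np.zeros_like(op.adjoint_half(y))
        for _ in range(20000):
            g = 2.0 * op.adjoint_half(op.forward_half(x) - y)
            x = soft_threshold(x - step * g, step * lam)
        w = spectrum_weights(op.hr_shape)
        r = op.forward_half(x) - y
        oracle = float(np.vdot(r, r).real) + lam * float(np.sum(w * np.abs(x)))
        assert res.objective == pytest.approx(oracle, rel=1e-6)

    def test_kkt_certificate_on_converged_solve(self, small_psf, rng):
        op = make_operator(small_psf, (8, 8, 8), factor=2)
        y = rng.random((4, 4, 4))
        lam = 0.3 * lambda_max(y, op)
        res = solve_block(y, op, lam, SolveConfig(max_iter=3000, tol=1e-12, nonneg="none"))
        assert res.converged
        assert res.kkt_residual <= 1e-3

    def test_solver_agreement_fista_vs_interior_point(self, small_psf, rng):
        # convexity: both routes must land on the same objective value
        op = make_operator(small_psf, (8, 8, 8), factor=2)
        worst = 0.0
        for _ in range(20):
            y = rng.random((4, 4, 4))
            lam = (0.1 + 0.4 * rng.random()) * lambda_max(y, op)
            r1 = solve_block(y, op, lam, SolveConfig(max_iter=3000, tol=1e-12, nonneg="none"))
            r2 = solve_block(y, op, lam, SolveConfig(method="interior-point", nonneg="none"))
            worst = max(worst, abs(r1.objective - r2.objective) / abs(r2.objective))
        assert worst < 1e-4

    def test_monotone_shrinkage_in_lambda(self, small_psf, rng):
        op = make_operator(small_psf, (8, 8, 8), factor=2)
        y = rng.random((4, 4, 4))
        lmax = lambda_max(y, op)
        l1s = []
        for frac in (0.01, 0.05, 0.2, 0.5, 0.9):
            res = solve_block(y, op, frac * lmax,
                              SolveConfig(max_iter=2000, tol=1e-12, nonneg="none"))
            l1s.append(res.coefficients.l1())
        assert all(a >= b - 1e-8 * max(abs(a), 1.0) for a, b in zip(l1s, l1s[1:]))

    def test_data_consistency_at_small_lambda(self, small_psf, rng):
        # noiseless block, lam -> 0+: the fit explains the data
        op = make_operator(small_psf, (16, 16, 16), factor=2)
        truth = np.clip(rng.standard_normal((16, 16, 16)), 0, None)
        y = op.forward_spatial(truth)
        lam = 1e-6 * lambda_max(y, op)
        res = solve_block(y, op, lam, SolveConfig(max_iter=3000, tol=1e-13, nonneg="none"))
        resid = np.linalg.norm(op.forward_half(res.coefficients.half) - y)
        assert resid / np.linalg.norm(y) <= 1e-3

    def test_objective_trace_non_increasing(self, small_psf, rng):
        op = make_operator(small_psf, (8, 8, 8), factor=2)
        y = rng.random((4, 4, 4))
        res = solve_block(y, op, 0.1 * lambda_max(y, op),
                          SolveConfig(max_iter=300, nonneg="none"))
        assert np.all(np.diff(res.objective_trace) <= 0)

    def test_nonconvergence_flagged_not_raised(self, small_psf, rng):
        op = make_operator(small_psf, (8, 8, 8), factor=2)
        y = rng.random((4, 4, 4))
        res = solve_block(y, op, 0.01 * lambda_max(y, op),
                          SolveConfig(max_iter=2, nonneg="none", continuation=False))
        assert res.converged is False
        assert res.iterations == 2

    def test_negative_lambda_rejected(self, small_psf):
        op = make_operator(small_psf, (8, 8, 8), factor=2)
        with pytest.raises(ValueError):
            solve_block(np.zeros((4, 4, 4)), op, -1.0)

    def test_nonneg_constraint_yields_nonnegative_spatial(self, small_psf, rng):
        op = make_operator(small_psf, (16, 16, 16), factor=2)
        y = rng.random((8, 8, 8))
        res = solve_block(y, op, 0.01 * lambda_max(y, op),
                          SolveConfig(max_iter=100, nonneg="constraint"))
        assert res.spatial.min() >= 0


class TestUpsamplePassthrough:
    def test_constant_preserved(self):
        block = np.full((4, 4, 4), 2.5)
        out = upsample_passthrough(block, 2)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_factor_one_identity(self, rng):
        block = rng.random((5, 5, 5))
        np.testing.assert_array_equal(upsample_passthrough(block, 1), block)

    def test_linear_ramp_reproduced(self):
        z, y, x = np.mgrid[0:6, 0:6, 0:6].astype(float)
        ramp = 1.0 + 0.5 * z - 0.25 * y + 2.0 * x
        out = upsample_passthrough(ramp, 4)
        zz, yy, xx = np.mgrid[0:24, 0:24, 0:24]
        fine = 1.0 + 0.5 * ((zz + 0.5) / 4 - 0.5) - 0.25 * ((yy + 0.5) / 4 - 0.5) + 2.0 * (
            (xx + 0.5) / 4 - 0.5
        )
        np.testing.assert_allclose(out, fine, atol=1e-6)

    def test_mean_preserved_for_smooth_block(self, rng):
        from scipy.ndimage import gaussian_filter

        block = gaussian_filter(rng.random((12, 12, 12)), 2.0)
        out = upsample_passthrough(block, 4)
        assert out.mean() == pytest.approx(block.mean(), rel=0.01)
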