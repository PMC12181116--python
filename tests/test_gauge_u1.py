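import math

import numpy as np
import pytest

from cortexfield.fields_core import ScalarField2p1, laplacian
from cortexfield.gauge_u1 import (GaugePotentialU1, continuity_residual,
                                  covariant_derivative, evolve_coupled,
                                  field_strength, gauge_transform,
                                  gauss_solve, hebbian_rate,
                                  lagrangian_density, noether_current)
from cortexfield.single_layer import evolve_kg


def make_A(nx, ny, eps=0.01, smooth=True):
    A = GaugePotentialU1.zeros(nx, ny, eps)
    if smooth:
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        A.A_x = 0.05 * np.sin(2 * math.pi * Y / ny)
        A.A_y = 0.05 * np.cos(2 * math.pi * X / nx)
    return A


class TestGaugeTransform:
    def test_constant_theta(self, smooth_field):
        A = make_A(*smooth_field.shape)
        theta = np.full(smooth_field.shape, 0.7)
        f2, A2 = gauge_transform(smooth_field, A, theta)
        np.testing.assert_allclose(f2.values, np.exp(0.7j) * smooth_field.values)
        np.testing.assert_array_equal(A2.A_x, A.A_x)
        np.testing.assert_array_equal(A2.A_y, A.A_y)

    def test_linear_theta_shifts_A_x(self, smooth_field):
        nx, ny = smooth_field.shape
        eps = 0.01
        A = GaugePotentialU1.zeros(nx, ny, eps)
        lam = 2 * math.pi * 2 / nx   # periodic-compatible slope
        X, _ = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny), indexing="ij")
        f2, A2 = gauge_transform(smooth_field, A, lam * X)
        np.testing.assert_allclose(A2.A_x[:-1], lam / eps, rtol=1e-12)
        np.testing.assert_array_equal(A2.A_y, A.A_y)
        np.testing.assert_allclose(np.abs(f2.values), np.abs(smooth_field.values))

    def test_epsilon_zero_rejected(self, smooth_field):
        A = GaugePotentialU1.zeros(*smooth_field.shape, epsilon=0.0)
        A.epsilon = 0.0
        with pytest.raises(ValueError, match="epsilon"):
            gauge_transform(smooth_field, A, np.zeros(smooth_field.shape))

    def test_lagrangian_density_invariant(self, smooth_field, weak_params):
        nx, ny = smooth_field.shape
        A = make_A(nx, ny)
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        theta = 0.8 * np.sin(2 * math.pi * X / nx) * np.cos(4 * math.pi * Y / ny)
        f2, A2 = gauge_transform(smooth_field, A, theta)
        L1 = lagrangian_density(smooth_field, A, weak_params)
        L2 = lagrangian_density(f2, A2, weak_params)
        assert np.max(np.abs(L1 - L2)) <= 1e-10


class TestCovariantDerivative:
    def test_zero_A_is_plain_derivative(self, smooth_field):
        from cortexfield.fields_core import grad_centered
        A = GaugePotentialU1.zeros(*smooth_field.shape)
        d = covariant_derivative(smooth_field, A, "x")
        np.testing.assert_array_equal(d, grad_centered(smooth_field.values, 1.0, 0))

    def test_plane_wave_constant_A(self):
        nx = ny = 32
        eps = 0.3
        f = ScalarField2p1.plane_wave(nx, ny, 1.0, 3, 0)
        A = GaugePotentialU1.zeros(nx, ny, eps)
        A.A_x += 0.4
        k = 2 * math.pi * 3 / nx
        k_disc = math.sin(k)  # dx = 1
        d = covariant_derivative(f, A, "x")
        np.testing.assert_allclose(d, 1j * (k_disc - eps * 0.4) * f.values,
                                   atol=1e-12)

    def test_link_scheme_exact_covariance(self, smooth_field):
        """D_μ(e^{iθ}φ) with the transformed A equals e^{iθ}·D_μφ."""
        nx, ny = smooth_field.shape
        A = make_A(nx, ny)
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        theta = 1.1 * np.cos(2 * math.pi * X / nx) * np.sin(2 * math.pi * Y / ny)
        f2, A2 = gauge_transform(smooth_field, A, theta)
        for mu in ("x", "y"):
            lhs = covariant_derivative(f2, A2, mu, scheme="link")
            rhs = np.exp(1j * theta) * covariant_derivative(
                smooth_field, A, mu, scheme="link")
            assert np.max(np.abs(lhs - rhs)) <= 1e-8


class TestFieldStrength:
    def test_pure_gradient_gives_zero(self):
        nx = ny = 32
        eps = 0.05
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        theta = np.sin(2 * math.pi * X / nx) + np.cos(4 * math.pi * Y / ny)
        f = ScalarField2p1.zeros(nx, ny, 1.0)
        _, A = gauge_transform(f, GaugePotentialU1.zeros(nx, ny, eps), theta)
        F = field_strength(A, 1.0)
        assert np.max(np.abs(F["xy"])) <= 1e-12

    def test_rotational_potential(self):
        nx = ny = 32
        lam = 0.1
        X, Y = np.meshgrid(np.arange(nx, dtype=float),
                           np.arange(ny, dtype=float), indexing="ij")
        A = GaugePotentialU1(np.zeros((nx, ny)), -lam * Y, lam * X, 0.01)
        F = field_strength(A, 1.0)
        np.testing.assert_allclose(F["xy"][2:-2, 2:-2], 2 * lam, rtol=1e-12)

    def test_antisymmetry(self):
        A = make_A(16, 16)
        F = field_strength(A, 1.0, A_dot=(np.ones((16, 16)), np.zeros((16, 16))))
        for pair in (("xy", "yx"), ("tx", "xt"), ("ty", "yt")):
            np.testing.assert_array_equal(F[pair[0]], -F[pair[1]])


class TestEvolveCoupled:
    def test_decoupled_limit_matches_evolve_kg(self, smooth_field, weak_params):
        A = GaugePotentialU1.zeros(*smooth_field.shape)
        tg = evolve_coupled(smooth_field, A, weak_params, dt=0.05, n_steps=80,
                            couple_A=False, store_every=20)
        tk = evolve_kg(smooth_field, weak_params, dt=0.05, n_steps=80,
                       store_every=20)
        assert np.array_equal(tg.values, tk.values)

    def test_connectivity_dynamics_persist_without_field(self, weak_params):
        """A evolves under its free wave equation while φ stays 0."""
        f = ScalarField2p1.zeros(32, 32, 1.0)
        A = make_A(32, 32)
        traj = evolve_coupled(f, A, weak_params, dt=0.05, n_steps=200,
                              store_every=50)
        assert np.max(np.abs(traj.values)) == 0.0
        assert np.max(np.abs(traj.A_x - traj.A_x[0])) > 1e-4

    def test_gauge_equivalent_trajectories(self, smooth_field, weak_params):
        nx, ny = smooth_field.shape
        A = make_A(nx, ny)
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        theta = (0.7 * np.sin(2 * math.pi * X / nx) * np.cos(4 * math.pi * Y / ny)
                 + 2 * math.pi * 3 * X / nx)
        f2, A2 = gauge_transform(smooth_field, A, theta)
        t1 = evolve_coupled(smooth_field, A, weak_params, dt=0.05, n_steps=400,
                            store_every=100)
        t2 = evolve_coupled(f2, A2, weak_params, dt=0.05, n_steps=400,
                            store_every=100)
        dev = np.max(np.abs(np.abs(t2.values) - np.abs(t1.values)))
        assert dev <= 1e-6

    def test_charge_conservation(self, smooth_field, weak_params):
        A = make_A(*smooth_field.shape)
        traj = evolve_coupled(smooth_field, A, weak_params, dt=0.05,
                              n_steps=2000, store_every=500)
        Q = traj.charges
        assert np.max(np.abs(Q - Q[0])) / abs(Q[0]) <= 1e-6

    def test_continuity_equation(self, smooth_field, weak_params):
        A = make_A(*smooth_field.shape)
        traj = evolve_coupled(smooth_field, A, weak_params, dt=0.05,
                              n_steps=40, store_every=1)
        res, cur = continuity_residual(traj, weak_params)
        assert res <= 1e-6 * cur


class TestNoetherCurrent:
    def test_uniform_rotating_field(self):
        """φ = ρe^{−it}: J_t = −|φ|² in the weak-coupling limit."""
        rho = 1.7
        vals = np.full((8, 8), rho + 0j)
        f = ScalarField2p1(vals, 1.0, velocity=-1j * vals)
        A = GaugePotentialU1.zeros(8, 8, 0.01)
        j_t, j_x, j_y = noether_current(f, A, epsilon=0.0)
        np.testing.assert_allclose(j_t, -rho**2, rtol=1e-14)

    def test_real_static_field_spatial_current_zero(self, rng):
        vals = rng.standard_normal((8, 8)).astype(complex)
        f = ScalarField2p1(vals, 1.0)
        A = GaugePotentialU1.zeros(8, 8)
        _, j_x, j_y = noether_current(f, A)
        assert np.max(np.abs(j_x)) == 0.0 and np.max(np.abs(j_y)) == 0.0


class TestGaussSolve:
    def test_zero_source(self):
        assert np.all(gauss_solve(np.zeros((16, 16))) == 0.0)

    def test_negative_source_rejected(self):
        src = np.zeros((8, 8))
        src[0, 0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            gauss_solve(src)

    def test_discrete_laplacian_identity(self):
        n = 64
        src = np.zeros((n, n))
        src[n // 2, n // 2] = 1.0
        src[10, 50] = 0.3
        A_t = gauss_solve(src, 1.0)
        resid = laplacian(A_t, 1.0, boundary="dirichlet") + src
        assert np.sqrt(np.mean(resid**2)) <= 1e-6

    def test_direct_vs_dst_dual_route(self, rng):
        src = rng.random((40, 40))
        a1 = gauss_solve(src, 0.5, method="direct")
        a2 = gauss_solve(src, 0.5, method="dst")
        assert np.max(np.abs(a1 - a2)) < 1e-9

    def test_point_source_log_profile(self):
        """Interior potential differences follow −(q/2π)·log(r/r_ref); with
        the absorb_two_pi flag the 2π is folded into the kernel."""
        n = 128
        q = 2.0
        src = np.zeros((n, n))
        src[n // 2, n // 2] = q
        A_t = gauss_solve(src, 1.0)
        c = n // 2
        r_ref = 4
        for r in (8, 12, 16):
            got = A_t[c + r_ref, c] - A_t[c + r, c]
            want = -(q / (2 * math.pi)) * math.log(r_ref / r)
            assert got == pytest.approx(want, rel=0.05)
        A_p = gauss_solve(src, 1.0, absorb_two_pi=True)
        np.testing.assert_allclose(A_p, 2 * math.pi * A_t, rtol=1e-12)

    def test_superposition(self):
        n = 48
        s1 = np.zeros((n, n))
        s2 = np.zeros((n, n))
        s1[12, 12] = 1.0
        s2[30, 35] = 2.0
        combined = gauss_solve(s1 + s2, 1.0)
        assert np.max(np.abs(combined - gauss_solve(s1, 1.0)
                             - gauss_solve(s2, 1.0))) <= 1e-10


class TestHebbianRate:
    def test_zero_activity(self):
        assert np.all(hebbian_rate(np.zeros((8, 8))) == 0.0)

    def test_linear_case_matches_gauss_solve(self):
        n = 32
        mod2 = np.zeros((n, n))
        mod2[n // 2, n // 2] = 1.5
        np.testing.assert_array_equal(hebbian_rate(mod2), gauss_solve(mod2))

    def test_quartic_term_scaling(self):
        """With a2 = 1, doubling |φ| multiplies the |φ|⁴ source by 16."""
        n = 16
        mod2 = np.zeros((n, n))
        mod2[8, 8] = 0.3
        r1 = hebbian_rate(mod2, coeffs=(1.0,))
        r_quartic = r1 - hebbian_rate(mod2)      # isolate the |φ|⁴ part
        mod2_doubled = 4.0 * mod2                # |2φ|² = 4|φ|²
        r2 = hebbian_rate(mod2_doubled, coeffs=(1.0,))
        r2_quartic = r2 - hebbian_rate(mod2_doubled)
        np.testing.assert_allclose(r2_quartic, 16.0 * r_quartic, rtol=1e-10)
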