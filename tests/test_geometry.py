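import math

import numpy as np
import pytest
import sympy as sp

from cortexfield.fields_core import ScalarField2p1, grid_coordinates, laplacian
from cortexfield.geometry import (DiagonalMetric, Metric2p1, RWState,
                                  christoffel, christoffel_fd,
                                  einstein_tensor_rw, laplace_beltrami,
                                  ricci_scalar, ricci_scalar_fd, two_sphere)


class TestLaplaceBeltrami:
    def test_flat_reduces_to_laplacian_on_quadratic(self):
        nx = ny = 24
        dx = 0.5
        X, _ = grid_coordinates(nx, ny, dx)
        f = ScalarField2p1((X**2).astype(complex), dx)
        lb = laplace_beltrami(Metric2p1.flat(), f, boundary="dirichlet")
        np.testing.assert_allclose(lb[5:-5, 5:-5].real, 2.0, atol=1e-10)

    def test_flat_plane_wave_eigenvalue(self):
        nx = ny = 32
        dx = 0.7
        f = ScalarField2p1.plane_wave(nx, ny, dx, 4, 0)
        k = 2 * math.pi * 4 / (nx * dx)
        eig = 2.0 * (math.cos(k * dx) - 1.0) / dx**2
        lb = laplace_beltrami(Metric2p1.flat(), f)
        np.testing.assert_allclose(lb, eig * f.values, atol=1e-12)

    def test_rw_constant_scale(self):
        a0 = 2.5
        f = ScalarField2p1.plane_wave(32, 32, 1.0, 3, 2)
        lb_rw = laplace_beltrami(Metric2p1.robertson_walker(a0), f)
        lb_flat = laplace_beltrami(Metric2p1.flat(), f)
        np.testing.assert_allclose(lb_rw, lb_flat / a0**2, atol=1e-14)

    def test_flat_composition_equals_stencil_exactly(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        f = ScalarField2p1(vals, 1.3)
        lb = laplace_beltrami(Metric2p1.flat(), f)
        assert np.array_equal(lb, laplacian(vals, 1.3))

    def test_symbolic_oracle_on_smooth_metric(self):
        """Flux-form discrete operator matches the analytic
        (1/√g)∂_i(√g g^{ii}∂_i·) of a smoothly varying diagonal metric."""
        nx = ny = 128
        L = 2 * math.pi
        dx = L / nx
        x, y = sp.symbols("x y")
        gmag = 2 + sp.cos(x)             # |g_xx| = |g_yy|, periodic, positive
        phi_expr = sp.exp(sp.I * (sp.Integer(2) * x)) * sp.cos(y)
        w = gmag                          # √|g| for the diagonal pair
        lb_expr = (sp.diff(w * (1 / gmag) * sp.diff(phi_expr, x), x)
                   + sp.diff(w * (1 / gmag) * sp.diff(phi_expr, y), y)) / w
        lb_fn = sp.lambdify((x, y), sp.simplify(lb_expr), "numpy")
        phi_fn = sp.lambdify((x, y), phi_expr, "numpy")
        X, Y = grid_coordinates(nx, ny, dx)
        f = ScalarField2p1(phi_fn(X, Y), dx)
        metric = Metric2p1.general_diagonal(
            lambda xx, yy: -(2 + np.cos(xx)), lambda xx, yy: -(2 + np.cos(xx)))
        got = laplace_beltrami(metric, f)
        want = lb_fn(X, Y)
        scale = np.max(np.abs(want))
        assert np.max(np.abs(got - want)) / scale < 1e-3  # O(dx²), dx≈0.05

    def test_pseudo_metric_sign_enforced(self):
        f = ScalarField2p1.zeros(8, 8, 1.0)
        with pytest.raises(ValueError, match="negative"):
            laplace_beltrami(Metric2p1("general-diagonal", 1.0, -1.0), f)


class TestChristoffel:
    def test_flat_is_zero(self):
        t, x, y = sp.symbols("t x y")
        dm = DiagonalMetric([t, x, y], [1, -1, -1])
        np.testing.assert_allclose(christoffel(dm, [0.0, 1.0, 2.0]), 0.0)

    def test_two_sphere_component(self):
        rho, th = 1.7, 0.8
        gamma = christoffel(two_sphere(rho), [th, 0.3])
        assert gamma[0, 1, 1] == pytest.approx(-math.sin(th) * math.cos(th),
                                               rel=1e-12)

    def test_lower_index_symmetry(self):
        gamma = christoffel(two_sphere(1.0), [0.9, 0.2])
        np.testing.assert_allclose(gamma, np.swapaxes(gamma, 1, 2), atol=1e-14)

    def test_metric_compatibility_fd(self):
        """Covariant derivative of the metric vanishes: for the diagonal
        2-sphere metric, ∂_k g_ii = Γ^l_{ki} g_li + Γ^l_{ki} g_il at the
        test point, checked with finite differences."""
        rho = 1.3
        comps = [lambda th, ph: rho**2,
                 lambda th, ph: rho**2 * math.sin(th)**2]
        pt = np.array([0.7, 0.4])
        h = 1e-5
        gamma = christoffel_fd(comps, pt, h=1e-4)
        for k in range(2):
            for i in range(2):
                pp, pm = pt.copy(), pt.copy()
                pp[k] += h
                pm[k] -= h
                dg = (comps[i](*pp) - comps[i](*pm)) / (2 * h)
                # diagonal metric: nabla_k g_ii = dg - 2 Γ^i_{ki} g_ii
                resid = dg - 2.0 * gamma[i, k, i] * comps[i](*pt)
                assert abs(resid) < 1e-6


class TestRicci:
    def test_flat_scaled_is_zero(self):
        t, x, y = sp.symbols("t x y")
        for lam in (1.0, 0.3, 7.0):
            dm = DiagonalMetric([t, x, y], [1, -lam, -lam])
            assert abs(ricci_scalar(dm, [0.0, 0.5, 0.5])) <= 1e-8

    @pytest.mark.parametrize("rho", [0.5, 1.0, 2.0])
    def test_two_sphere_curvature(self, rho):
        assert ricci_scalar(two_sphere(rho), [1.1, 0.2]) == pytest.approx(
            2.0 / rho**2, rel=1e-10)

    def test_scaling_law(self):
        """g → λg implies R → R/λ."""
        th, ph = sp.symbols("theta phi")
        lam = 2.7
        base = two_sphere(1.0)
        scaled = DiagonalMetric([th, ph], [lam * c for c in base.components])
        r0 = ricci_scalar(base, [0.9, 0.1])
        r1 = ricci_scalar(scaled, [0.9, 0.1])
        assert r1 == pytest.approx(r0 / lam, rel=1e-10)

    def test_fd_second_order_convergence(self):
        """Finite-difference Ricci converges to 2/ρ² at second order in h
        on the 2-sphere test metric."""
        rho = 1.0
        comps = [lambda th, ph: rho**2,
                 lambda th, ph: rho**2 * math.sin(th)**2]
        errs = []
        for h in (0.08, 0.04, 0.02):
            r = ricci_scalar_fd(comps, [1.0, 0.3], h=h)
            errs.append(abs(r - 2.0 / rho**2))
        order1 = math.log(errs[0] / errs[1]) / math.log(2)
        order2 = math.log(errs[1] / errs[2]) / math.log(2)
        assert order1 > 1.6 and order2 > 1.6


class TestEinsteinTensorRW:
    def test_static_flat(self):
        g = einstein_tensor_rw(RWState(a=2.0, adot=0.0, k=0.0), r=0.3)
        assert g == (0.0, 0.0, 0.0)

    def test_linear_expansion(self):
        t0 = 2.0
        g_tt, g_rr, g_thth = einstein_tensor_rw(
            RWState(a=t0, adot=1.0, k=0.0), r=0.5, addot=0.0)
        assert g_tt == pytest.approx(1.0 / t0**2)
        assert g_rr == 0.0 and g_thth == 0.0

    def test_exponential_expansion_symbolic_oracle(self):
        """a(t) = e^{ht}: components checked against sympy differentiation
        of the printed closed forms."""
        h, t0, r = 0.4, 1.3, 0.5
        t = sp.symbols("t")
        a_expr = sp.exp(h * t)
        a = float(a_expr.subs(t, t0))
        adot = float(sp.diff(a_expr, t).subs(t, t0))
        addot = float(sp.diff(a_expr, t, 2).subs(t, t0))
        g_tt, g_rr, g_thth = einstein_tensor_rw(
            RWState(a=a, adot=adot, k=0.0), r=r, addot=addot)
        assert g_tt == pytest.approx(h**2, rel=1e-12)
        assert g_rr == pytest.approx(-a * addot, rel=1e-12)
        assert g_thth == pytest.approx(-(r**2) * a * addot, rel=1e-12)

    def test_coordinate_singularity(self):
        with pytest.raises(ValueError, match="singular"):
            einstein_tensor_rw(RWState(a=1.0, k=1.0), r=1.0)
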