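"""Metric machinery for the curved cortical surface.

The extrinsic connectivity defines an effective geometry on the sheet: wave
propagation is governed by a diagonal 2+1 pseudo-metric with ``g_tt = +1``
and negative spatial entries (mostly-minus signature).  This module provides
the discrete spatial Laplace-Beltrami operator used by the integrators, the
Christoffel/Ricci machinery (analytic via sympy for tagged metric forms,
finite differences otherwise), and the Robertson-Walker Einstein-tensor
components that drive metric learning.

Sign convention
---------------
The pseudo-metric has negative spatial diagonal entries; the exposed
``laplace_beltrami`` is defined with the *magnitudes* of the spatial
components,

    Δ_g φ = (1/√|g|) ∂_i( √|g| |g^{ii}| ∂_i φ ),

so that the flat metric diag(1, −1, −1) reduces to the ordinary Laplacian
+∇² and the wave equation is stepped as ∂²_t φ = −m²c⁴ φ + c² Δ_g φ.  This
fixes the d'Alembertian sign left open by the mostly-minus pseudo-metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import sympy as sp

from .fields_core import Boundary, ScalarField2p1, grid_coordinates, shift

__all__ = [
    "Metric2p1",
    "RWState",
    "DiagonalMetric",
    "two_sphere",
    "laplace_beltrami",
    "christoffel",
    "ricci_scalar",
    "christoffel_fd",
    "ricci_scalar_fd",
    "einstein_tensor_rw",
]

ComponentFn = Union[float, Callable[[np.ndarray, np.ndarray], np.ndarray]]


@dataclass(frozen=True)
class Metric2p1:
    """Diagonal 2+1 pseudo-metric on the sheet: fixed ``g_tt = 1`` and
    negative spatial components ``g_xx``, ``g_yy`` (constants or callables
    of the node coordinates)."""

    form: str
    g_xx: ComponentFn
    g_yy: ComponentFn
    a: Optional[float] = None
    k_curv: float = 0.0

    g_tt: float = 1.0

    @classmethod
    def flat(cls, scale: float = 1.0) -> "Metric2p1":
        """Flat metric diag(1, -scale, -scale)."""
        if scale <= 0:
            raise ValueError("flat-scaled metric needs a positive scale")
        return cls("flat-scaled", -scale, -scale)

    @classmethod
    def robertson_walker(cls, a: float, k_curv: float = 0.0) -> "Metric2p1":
        """Robertson-Walker surface metric with expansion factor ``a``.

        On the Cartesian grid only the spatially flat case (k = 0) is
        representable, where the spatial metric is −a² δ_ij; curved-k
        analytics live in :func:`einstein_tensor_rw`.
        """
        if a <= 0:
            raise ValueError("expansion factor a must be positive")
        if k_curv != 0.0:
            raise ValueError("grid evolution supports only k_curv = 0; "
                             "use einstein_tensor_rw for curved analytics")
        return cls("robertson-walker", -(a**2), -(a**2), a=a, k_curv=k_curv)

    @classmethod
    def general_diagonal(cls, g_xx: ComponentFn, g_yy: ComponentFn) -> "Metric2p1":
        return cls("general-diagonal", g_xx, g_yy)

    def spatial(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Covariant spatial components evaluated on coordinate arrays."""
        def ev(c: ComponentFn) -> np.ndarray:
            arr = c(X, Y) if callable(c) else np.full_like(X, float(c))
            return np.asarray(arr, dtype=float)
        gxx, gyy = ev(self.g_xx), ev(self.g_yy)
        if np.any(gxx >= 0) or np.any(gyy >= 0):
            bad = np.argwhere((gxx >= 0) | (gyy >= 0))[0]
            raise ValueError(
                f"pseudo-metric requires negative spatial entries; violated at node {tuple(bad)}")
        return gxx, gyy


@dataclass
class RWState:
    """Robertson-Walker expansion state: factor ``a(t)``, its rate ``adot``,
    curvature constant ``k`` and conserved density parameter ``rho0``."""

    a: float
    adot: float = 0.0
    k: float = 0.0
    rho0: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("expansion factor a must be positive")


# ---------------------------------------------------------------------------
# Laplace-Beltrami
# ---------------------------------------------------------------------------

def laplace_beltrami(metric: Metric2p1, field: ScalarField2p1,
                     boundary: Boundary = "periodic") -> np.ndarray:
    """Discrete spatial Laplace-Beltrami of ``field`` under ``metric``.

    Conservative flux form with metric coefficients sampled at cell faces;
    second-order accurate in ``dx`` and exactly self-adjoint with respect to
    the √|g|-weighted inner product (which is what makes the leapfrog shadow
    energy of the integrators an exact invariant).  For constant spatial
    metric −s the result is exactly (1/s)·(5-point Laplacian).
    """
    nx, ny = field.shape
    dx = field.dx
    if not callable(metric.g_xx) and not callable(metric.g_yy) \
            and float(metric.g_xx) == float(metric.g_yy):
        s = abs(float(metric.g_xx))
        if s <= 0:
            raise ValueError("pseudo-metric requires negative spatial entries")
        from .fields_core import laplacian
        lap = laplacian(field.values, dx, boundary)
        return lap if s == 1.0 else lap / s
    X, Y = grid_coordinates(nx, ny, dx)
    gxx, gyy = metric.spatial(X, Y)
    Xhx, Yhx = X + 0.5 * dx, Y
    Xhy, Yhy = X, Y + 0.5 * dx
    gxx_hx, _ = metric.spatial(Xhx, Yhx)
    _, gyy_hy = metric.spatial(Xhy, Yhy)
    gyy_hx = metric.spatial(Xhx, Yhx)[1]
    gxx_hy = metric.spatial(Xhy, Yhy)[0]

    w = np.sqrt(np.abs(gxx * gyy))
    if np.any(w <= 1e-300):
        bad = np.argwhere(w <= 1e-300)[0]
        raise ValueError(f"singular metric (|g| -> 0) at node {tuple(bad)}")
    w_hx = np.sqrt(np.abs(gxx_hx * gyy_hx))
    w_hy = np.sqrt(np.abs(gxx_hy * gyy_hy))

    v = field.values
    # face fluxes: F_{i+1/2} = w |g^{xx}| D+ phi
    fx = w_hx * (1.0 / np.abs(gxx_hx)) * (shift(v, 1, 0, boundary) - v) / dx
    fy = w_hy * (1.0 / np.abs(gyy_hy)) * (shift(v, 1, 1, boundary) - v) / dx
    div = (fx - shift(fx, -1, 0, boundary)) / dx + (fy - shift(fy, -1, 1, boundary)) / dx
    return div / w


# ---------------------------------------------------------------------------
# symbolic diagonal metrics: Christoffel symbols and Ricci scalar
# ---------------------------------------------------------------------------


class DiagonalMetric:
    """Diagonal metric with sympy component expressions in given coordinates.

    Derivatives are taken analytically, so Christoffel symbols and the Ricci
    scalar are exact at any evaluation point (up to float rounding).  Used
    both for the 2+1 sheet metrics and for pure test geometries such as the
    2-sphere.
    """

    def __init__(self, coords: Sequence[sp.Symbol],
                 components: Sequence[Union[sp.Expr, float]]) -> None:
        if len(coords) != len(components):
            raise ValueError("one diagonal component per coordinate required")
        self.coords = list(coords)
        self.components = [sp.sympify(c) for c in components]
        self.dim = len(coords)
        self._gamma_fn = None
        self._ricci_fn = None

    # -- symbolic builders ---------------------------------------------------
    def _gamma_expr(self) -> list:
        g = self.components
        ginv = [1 / c for c in g]
        x = self.coords
        n = self.dim
        gamma = [[[sp.S.Zero] * n for _ in range(n)] for _ in range(n)]
        for rho in range(n):
            for mu in range(n):
                for nu in range(n):
                    expr = sp.S.Zero
                    # diagonal metric: lambda = rho only
                    if rho == mu:
                        expr += sp.diff(g[rho], x[nu])
                    if rho == nu:
                        expr += sp.diff(g[rho], x[mu])
                    if mu == nu:
                        expr -= sp.diff(g[mu], x[rho])
                    gamma[rho][mu][nu] = sp.simplify(ginv[rho] * expr / 2)
        return gamma

    def _ricci_expr(self) -> sp.Expr:
        x = self.coords
        n = self.dim
        gamma = self._gamma_expr()
        ricci = [[sp.S.Zero] * n for _ in range(n)]
        for sig in range(n):
            for nu in range(n):
                expr = sp.S.Zero
                for lam in range(n):
                    expr += sp.diff(gamma[lam][nu][sig], x[lam])
                    expr -= sp.diff(gamma[lam][lam][sig], x[nu])
                    for eta in range(n):
                        expr += gamma[lam][lam][eta] * gamma[eta][nu][sig]
                        expr -= gamma[lam][nu][eta] * gamma[eta][lam][sig]
                ricci[sig][nu] = expr
        scalar = sum((1 / self.components[m]) * ricci[m][m] for m in range(n))
        return sp.simplify(scalar)

    # -- evaluation ----------------------------------------------------------
    def christoffel_at(self, point: Sequence[float]) -> np.ndarray:
        if self._gamma_fn is None:
            gamma = self._gamma_expr()
            flat = [gamma[r][m][n] for r in range(self.dim)
                    for m in range(self.dim) for n in range(self.dim)]
            self._gamma_fn = sp.lambdify(self.coords, flat, modules="numpy")
        vals = np.asarray(self._gamma_fn(*point), dtype=float)
        return vals.reshape(self.dim, self.dim, self.dim)

    def ricci_at(self, point: Sequence[float]) -> float:
        if self._ricci_fn is None:
            self._ricci_fn = sp.lambdify(self.coords, self._ricci_expr(),
                                         modules="numpy")
        return float(self._ricci_fn(*point))


def two_sphere(rho: float = 1.0) -> DiagonalMetric:
    """Round 2-sphere of radius rho: diag(ρ², ρ² sin²θ) in (θ, φ)."""
    th, ph = sp.symbols("theta phi")
    return DiagonalMetric([th, ph], [rho**2, rho**2 * sp.sin(th)**2])


def _as_diagonal(metric: Union[DiagonalMetric, Metric2p1]) -> DiagonalMetric:
    if isinstance(metric, DiagonalMetric):
        return metric
    t, x, y = sp.symbols("t x y")
    comps: list = [sp.S.One]
    for c in (metric.g_xx, metric.g_yy):
        if callable(c):
            raise TypeError("analytic Christoffel/Ricci needs a symbolic "
                            "DiagonalMetric; use christoffel_fd for callables")
        comps.append(sp.Float(float(c)))
    return DiagonalMetric([t, x, y], comps)


def christoffel(metric: Union[DiagonalMetric, Metric2p1],
                point: Sequence[float]) -> np.ndarray:
    """Christoffel symbols Γ^ρ_{μν} (array indexed [rho, mu, nu]) at ``point``.

    Symmetric in the lower indices by construction.  Tagged/symbolic metrics
    use analytic derivatives; callable-valued metrics go through
    :func:`christoffel_fd`.
    """
    dm = _as_diagonal(metric)
    if any(sp.simplify(c) == 0 for c in dm.components):
        raise ValueError("non-invertible metric: zero diagonal component")
    return dm.christoffel_at(point)


def ricci_scalar(metric: Union[DiagonalMetric, Metric2p1],
                 point: Sequence[float]) -> float:
    """Ricci scalar curvature at ``point`` (Γ → Riemann → contraction)."""
    dm = _as_diagonal(metric)
    return dm.ricci_at(point)


# ---------------------------------------------------------------------------
# finite-difference path (for metrics given only as callables)
# ---------------------------------------------------------------------------

def christoffel_fd(component_funcs: Sequence[Callable[..., float]],
                   point: Sequence[float], h: float = 1e-4) -> np.ndarray:
    """Second-order finite-difference Christoffel symbols for a diagonal
    metric supplied as plain Python callables g_ii(*coords)."""
    n = len(component_funcs)
    point = np.asarray(point, float)

    def dg(i: int, k: int) -> float:
        p_plus, p_minus = point.copy(), point.copy()
        p_plus[k] += h
        p_minus[k] -= h
        return (component_funcs[i](*p_plus) - component_funcs[i](*p_minus)) / (2 * h)

    g = np.array([f(*point) for f in component_funcs], float)
    gamma = np.zeros((n, n, n))
    for rho in range(n):
        for mu in range(n):
            for nu in range(n):
                val = 0.0
                if rho == mu:
                    val += dg(rho, nu)
                if rho == nu:
                    val += dg(rho, mu)
                if mu == nu:
                    val -= dg(mu, rho)
                gamma[rho, mu, nu] = 0.5 * val / g[rho]
    return gamma


def ricci_scalar_fd(component_funcs: Sequence[Callable[..., float]],
                    point: Sequence[float], h: float = 1e-3) -> float:
    """Finite-difference Ricci scalar (second-order; converges as h² on
    smooth metrics)."""
    n = len(component_funcs)
    point = np.asarray(point, float)

    def gamma_at(p: np.ndarray) -> np.ndarray:
        return christoffel_fd(component_funcs, p, h)

    gamma0 = gamma_at(point)
    dgamma = np.zeros((n, n, n, n))  # [k, rho, mu, nu] = d_k Gamma^rho_{mu nu}
    for k in range(n):
        pp, pm = point.copy(), point.copy()
        pp[k] += h
        pm[k] -= h
        dgamma[k] = (gamma_at(pp) - gamma_at(pm)) / (2 * h)

    g = np.array([f(*point) for f in component_funcs], float)
    scalar = 0.0
    for sig in range(n):
        nu = sig
        r = 0.0
        for lam in range(n):
            r += dgamma[lam, lam, nu, sig] - dgamma[nu, lam, lam, sig]
            for eta in range(n):
                r += gamma0[lam, lam, eta] * gamma0[eta, nu, sig]
                r -= gamma0[lam, nu, eta] * gamma0[eta, lam, sig]
        scalar += r / g[sig]
    return scalar


# ---------------------------------------------------------------------------
# Robertson-Walker Einstein tensor
# ---------------------------------------------------------------------------

def einstein_tensor_rw(state: RWState, r: float,
                       addot: float = 0.0) -> tuple[float, float, float]:
    """Einstein-tensor components of the 2+1 Robertson-Walker surface metric
    in polar coordinates:

        G_tt = k/a² + a′²/a²
        G_rr = −a a″ / (1 − k r²)
        G_θθ = −r² a a″

    ``addot`` is the second time derivative a″ (zero for coasting states).
    """
    a, adot, k = state.a, state.adot, state.k
    denom = 1.0 - k * r**2
    if denom <= 0:
        raise ValueError(f"coordinate singularity: 1 - k r² = {denom} <= 0")
    g_tt = k / a**2 + adot**2 / a**2
    g_rr = -a * addot / denom
    g_thth = -(r**2) * a * addot
    return g_tt, g_rr, g_thth
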