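"""Abelian connectivity field coupled to the neural field.

A space/time-dependent modulation e^{iθ} of the intrinsic connection gain is
absorbed into a connectivity potential A_μ with coupling ε.  The neural
field then obeys a gauge-covariant Klein-Gordon equation, the connectivity
field obeys sourced wave equations, and the phase symmetry implies a
conserved current whose temporal component −|φ|² sources a Gauss-law
(Poisson) equation — the origin of the (non-linear) Hebbian rate.

Discretization notes
--------------------
* ``covariant_derivative`` uses centered differences by default, the
  convention under which a plane wave with constant A has the closed-form
  eigenvalue i(k_disc − εA); ``scheme="link"`` switches to the forward
  lattice-gauge difference, which is *exactly* covariant under lattice gauge
  transformations.
* ``evolve_coupled`` uses compact link variables e^{−iε dx A_i} throughout
  (the standard lattice-gauge discretization).  This makes gauge covariance,
  the discrete continuity equation and total-charge conservation hold to
  machine precision rather than to stencil accuracy.
* Current normalization: J_μ = −(i/2)(φ*∂_μφ − ∂_μφ*φ) − εA_μ|φ|², the
  convention under which a uniform oscillation φ = ρe^{−it} carries
  J_t = −|φ|² (the Hebbian source).
* Gauge-shift sign: covariance of D_μ = ∂_μ − iεA_μ fixes
  A → A + ∂θ/ε under φ → e^{iθ}φ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional

import numpy as np
import scipy.fft
import scipy.sparse
import scipy.sparse.linalg

from .fields_core import (Boundary, KGParams, ScalarField2p1, grad_centered,
                          laplacian, shift)

__all__ = [
    "GaugePotentialU1",
    "gauge_transform",
    "covariant_derivative",
    "field_strength",
    "lagrangian_density",
    "evolve_coupled",
    "noether_current",
    "lattice_charge",
    "continuity_residual",
    "gauss_solve",
    "hebbian_rate",
    "GaugeTrajectory",
]


@dataclass
class GaugePotentialU1:
    """Abelian connectivity potential on the grid.

    ``A_t`` is node-centered; ``A_x[i, j]`` / ``A_y[i, j]`` are associated
    with the forward links (i,j)→(i+1,j) and (i,j)→(i,j+1) respectively
    (node-centered readings are fine wherever A varies slowly).  ``epsilon``
    is the neural-connectivity coupling.
    """

    A_t: np.ndarray
    A_x: np.ndarray
    A_y: np.ndarray
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        self.A_t = np.asarray(self.A_t, dtype=float)
        self.A_x = np.asarray(self.A_x, dtype=float)
        self.A_y = np.asarray(self.A_y, dtype=float)
        for name, comp in (("A_t", self.A_t), ("A_x", self.A_x), ("A_y", self.A_y)):
            if not np.all(np.isfinite(comp)):
                raise ValueError(f"{name} must be real and finite")
        if self.A_t.shape != self.A_x.shape or self.A_x.shape != self.A_y.shape:
            raise ValueError("gauge components must share one grid shape")

    @classmethod
    def zeros(cls, nx: int, ny: int, epsilon: float = 0.01) -> "GaugePotentialU1":
        z = np.zeros((nx, ny))
        return cls(z.copy(), z.copy(), z.copy(), epsilon)

    def copy(self) -> "GaugePotentialU1":
        return GaugePotentialU1(self.A_t.copy(), self.A_x.copy(),
                                self.A_y.copy(), self.epsilon)


def gauge_transform(field: ScalarField2p1, A: GaugePotentialU1,
                    theta: np.ndarray) -> tuple[ScalarField2p1, GaugePotentialU1]:
    """Joint local phase transformation φ → e^{iθ}φ, A_i → A_i + ∂_iθ/ε.

    θ is a static real scalar grid field; spatial gradients are taken as
    forward lattice differences on the links so that the transformation is
    an exact symmetry of the link-variable dynamics.  |φ| is pointwise
    unchanged and A_t is unchanged (static θ).
    """
    if A.epsilon == 0:
        raise ValueError("epsilon = 0: the gauge shift ∂θ/ε is undefined")
    theta = np.asarray(theta, dtype=float)
    dx = field.dx
    phase = np.exp(1j * theta)
    new_field = ScalarField2p1(phase * field.values, dx, field.time,
                               phase * field.velocity)
    new_A = A.copy()
    new_A.A_x = A.A_x + (shift(theta, 1, 0) - theta) / (A.epsilon * dx)
    new_A.A_y = A.A_y + (shift(theta, 1, 1) - theta) / (A.epsilon * dx)
    return new_field, new_A


def covariant_derivative(field: ScalarField2p1, A: GaugePotentialU1,
                         direction: Literal["t", "x", "y"],
                         scheme: Literal["centered", "link"] = "centered",
                         boundary: Boundary = "periodic") -> np.ndarray:
    """Gauge-covariant derivative D_μφ = ∂_μφ − iεA_μφ.

    ``centered`` (default) uses second-order centered differences, for which
    a plane wave e^{ikx} with constant A_x satisfies
    D_xφ = i(sin(k dx)/dx − εA_x)φ.  ``link`` uses the forward lattice-gauge
    difference (e^{−iε dx A}φ(x+1) − φ(x))/dx, which transforms exactly
    covariantly under :func:`gauge_transform`.
    """
    eps = A.epsilon
    v, dx = field.values, field.dx
    if direction == "t":
        return field.velocity - 1j * eps * A.A_t * v
    axis = 0 if direction == "x" else 1
    comp = A.A_x if direction == "x" else A.A_y
    if scheme == "centered":
        return grad_centered(v, dx, axis, boundary) - 1j * eps * comp * v
    link = np.exp(-1j * eps * dx * comp)
    return (link * shift(v, 1, axis, boundary) - v) / dx


def field_strength(A: GaugePotentialU1, dx: float,
                   A_dot: Optional[tuple[np.ndarray, np.ndarray]] = None,
                   boundary: Boundary = "periodic") -> dict:
    """Antisymmetric field strength F_{μν} = ∂_μA_ν − ∂_νA_μ.

    Spatial curl uses the link (plaquette) differences, under which a pure
    lattice gradient gives F ≡ 0 exactly.  Returns a dict with key ``"xy"``
    always, plus ``"tx"``/``"ty"`` when the time derivatives of the spatial
    components are supplied.  F_{νμ} = −F_{μν} by construction.
    """
    fxy = ((shift(A.A_y, 1, 0, boundary) - A.A_y)
           - (shift(A.A_x, 1, 1, boundary) - A.A_x)) / dx
    out = {"xy": fxy, "yx": -fxy}
    if A_dot is not None:
        adx, ady = A_dot
        out["tx"] = adx - grad_centered(A.A_t, dx, 0, boundary)
        out["xt"] = -out["tx"]
        out["ty"] = ady - grad_centered(A.A_t, dx, 1, boundary)
        out["yt"] = -out["ty"]
    return out


def _covariant_laplacian(values: np.ndarray, A: GaugePotentialU1, dx: float,
                         boundary: Boundary = "periodic") -> np.ndarray:
    """Link-variable covariant Laplacian Σ_i D_i†D_i φ (Hermitian; exactly
    gauge covariant; reduces to the 5-point stencil when A = 0)."""
    eps = A.epsilon
    out = -4.0 * values
    for axis, comp in ((0, A.A_x), (1, A.A_y)):
        link = np.exp(-1j * eps * dx * comp)
        out = out + link * shift(values, 1, axis, boundary)
        back = np.conj(shift(link, -1, axis, boundary))
        out = out + back * shift(values, -1, axis, boundary)
    return out / dx**2


def lagrangian_density(field: ScalarField2p1, A: GaugePotentialU1,
                       params: KGParams, boundary: Boundary = "periodic",
                       A_dot: Optional[tuple[np.ndarray, np.ndarray]] = None) -> np.ndarray:
    """Gauge-invariant Lagrangian density of the coupled system,

        L = |D_tφ|² − c² Σ_i |D_iφ|² − m²c⁴|φ|² − ½(F_tx² + F_ty²) + ½F_xy²,

    with link-scheme covariant derivatives so the density is exactly
    invariant (to rounding) under :func:`gauge_transform`.
    """
    dx = field.dx
    dt_phi = covariant_derivative(field, A, "t")
    dx_phi = covariant_derivative(field, A, "x", scheme="link", boundary=boundary)
    dy_phi = covariant_derivative(field, A, "y", scheme="link", boundary=boundary)
    dens = (np.abs(dt_phi) ** 2
            - np.asarray(params.c2) * (np.abs(dx_phi) ** 2 + np.abs(dy_phi) ** 2)
            - np.asarray(params.mass2c4) * np.abs(field.values) ** 2)
    F = field_strength(A, dx, A_dot, boundary)
    dens = dens + 0.5 * F["xy"] ** 2
    if A_dot is not None:
        dens = dens - 0.5 * (F["tx"] ** 2 + F["ty"] ** 2)
    return dens


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def noether_current(field: ScalarField2p1, A: GaugePotentialU1,
                    epsilon: Optional[float] = None,
                    boundary: Boundary = "periodic") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conserved U(1) current of the phase symmetry,

        J_μ = −(i/2)(φ*∂_μφ − ∂_μφ*·φ) − εA_μ|φ|²,

    normalized so a uniform oscillation φ = ρe^{−it} carries J_t = −|φ|².
    Spatial derivatives are centered.
    """
    eps = A.epsilon if epsilon is None else epsilon
    v = field.values
    mod2 = np.abs(v) ** 2
    j_t = np.imag(np.conj(v) * field.velocity) - eps * A.A_t * mod2
    j_x = np.imag(np.conj(v) * grad_centered(v, field.dx, 0, boundary)) - eps * A.A_x * mod2
    j_y = np.imag(np.conj(v) * grad_centered(v, field.dx, 1, boundary)) - eps * A.A_y * mod2
    return j_t, j_x, j_y


def _link_current(values: np.ndarray, A: GaugePotentialU1, dx: float, c2,
                  boundary: Boundary = "periodic") -> tuple[np.ndarray, np.ndarray]:
    """Exact lattice spatial current of the link scheme: the flux through the
    forward link in each direction, J_i = −c² Im(φ*(x) U_i φ(x+î))/dx."""
    out = []
    for axis, comp in ((0, A.A_x), (1, A.A_y)):
        link = np.exp(-1j * A.epsilon * dx * comp)
        s = np.imag(np.conj(values) * link * shift(values, 1, axis, boundary))
        out.append(-np.asarray(c2) * s / dx)
    return out[0], out[1]


def lattice_charge(phi_prev: np.ndarray, phi_next: np.ndarray, dt: float,
                   dx: float) -> float:
    """Total charge Σ J_t dx² with the midpoint density
    ρ^{n+1/2} = Im(φ^n* φ^{n+1})/dt — the form the leapfrog link scheme
    conserves exactly."""
    return float(np.sum(np.imag(np.conj(phi_prev) * phi_next)) / dt * dx**2)


# ---------------------------------------------------------------------------
# coupled evolution
# ---------------------------------------------------------------------------


@dataclass
class GaugeTrajectory:
    times: np.ndarray
    values: np.ndarray          # (n_snap, nx, ny) complex
    velocities: np.ndarray
    A_x: np.ndarray             # (n_snap, nx, ny)
    A_y: np.ndarray
    charges: np.ndarray         # midpoint total charge per step (n_steps,)
    dx: float
    dt: float
    epsilon: float
    snap_steps: np.ndarray = dc_field(default=None)  # step index per snapshot


def evolve_coupled(field: ScalarField2p1, A: GaugePotentialU1,
                   params: KGParams, dt: float, n_steps: int,
                   couple_A: bool = True, source_scale: Optional[float] = None,
                   A_velocity: Optional[tuple[np.ndarray, np.ndarray]] = None,
                   store_every: Optional[int] = None,
                   boundary: Boundary = "periodic") -> GaugeTrajectory:
    """Leapfrog evolution of the coupled neural/connectivity system.

    Temporal gauge (A_t = 0 in the dynamics; the Gauss-law potential is
    available separately via :func:`gauss_solve`):

        ∂²_t φ  = −m²c⁴ φ + c² D²_A φ          (link covariant Laplacian)
        ∂²_t A_i = c² (∇²A_i − ∂_i ∂_jA_j) + s·J_i   (s = source_scale, default ε)

    With ``couple_A=False`` and A = 0 this reduces *exactly* to
    :func:`single_layer.evolve_kg` on the same grid.  The connectivity field
    evolves even when φ = 0 (one-way decoupling), and the midpoint total
    charge is conserved to rounding along the run.
    """
    from .single_layer import _check_stability
    _check_stability(params, field.dx, dt, None)
    if store_every is None:
        store_every = max(1, n_steps // 100)
    dx = field.dx
    eps = A.epsilon
    s_scale = eps if source_scale is None else source_scale
    c2 = params.c2

    phi = field.values.copy()
    vel = field.velocity.copy()
    ax, ay = A.A_x.copy(), A.A_y.copy()
    if A_velocity is None:
        vax, vay = np.zeros_like(ax), np.zeros_like(ay)
    else:
        vax, vay = A_velocity[0].copy(), A_velocity[1].copy()

    def acc_phi(p, a_x, a_y):
        Acur = GaugePotentialU1(np.zeros_like(a_x), a_x, a_y, eps)
        return (np.asarray(c2) * _covariant_laplacian(p, Acur, dx, boundary)
                - np.asarray(params.mass2c4) * p)

    def acc_A(p, a_x, a_y):
        if not couple_A:
            return np.zeros_like(a_x), np.zeros_like(a_y)
        div = ((a_x - shift(a_x, -1, 0, boundary))
               + (a_y - shift(a_y, -1, 1, boundary))) / dx
        gdx = (shift(div, 1, 0, boundary) - div) / dx
        gdy = (shift(div, 1, 1, boundary) - div) / dx
        Acur = GaugePotentialU1(np.zeros_like(a_x), a_x, a_y, eps)
        jx, jy = _link_current(p, Acur, dx, c2, boundary)
        lap_ax = laplacian(a_x, dx, boundary)
        lap_ay = laplacian(a_y, dx, boundary)
        cc = float(np.max(np.asarray(c2))) if np.ndim(c2) else float(c2)
        return (cc * (lap_ax - gdx) + s_scale * jx,
                cc * (lap_ay - gdy) + s_scale * jy)

    times, vals, vels, axs, ays, snaps = [], [], [], [], [], []
    charges = np.empty(n_steps)

    def record(step: int) -> None:
        times.append(field.time + step * dt)
        vals.append(phi.copy())
        vels.append(vel.copy())
        axs.append(ax.copy())
        ays.append(ay.copy())
        snaps.append(step)

    record(0)
    ap = acc_phi(phi, ax, ay)
    aax, aay = acc_A(phi, ax, ay)
    norm0 = float(np.sum(np.abs(phi) ** 2) + np.sum(np.abs(vel) ** 2)) + 1e-300
    for step in range(1, n_steps + 1):
        vel = vel + 0.5 * dt * ap
        vax = vax + 0.5 * dt * aax
        vay = vay + 0.5 * dt * aay
        phi_prev = phi
        phi = phi + dt * vel
        ax = ax + dt * vax
        ay = ay + dt * vay
        charges[step - 1] = lattice_charge(phi_prev, phi, dt, dx)
        ap = acc_phi(phi, ax, ay)
        aax, aay = acc_A(phi, ax, ay)
        vel = vel + 0.5 * dt * ap
        vax = vax + 0.5 * dt * aax
        vay = vay + 0.5 * dt * aay
        if step % store_every == 0 or step == n_steps:
            norm = float(np.sum(np.abs(phi) ** 2) + np.sum(np.abs(vel) ** 2))
            if not np.isfinite(norm) or norm > 1e6 * norm0 + 1e6:
                raise RuntimeError(
                    f"instability detected at step {step}: state norm {norm:.3g}")
            record(step)
    return GaugeTrajectory(np.array(times), np.array(vals), np.array(vels),
                           np.array(axs), np.array(ays), charges, dx, dt, eps,
                           np.array(snaps))


def continuity_residual(traj: GaugeTrajectory, params: KGParams,
                        boundary: Boundary = "periodic") -> tuple[float, float]:
    """RMS of the discrete continuity equation ∂_tJ_t + ∇·J along stored
    consecutive snapshot triples, and the RMS of the current itself.

    Uses the exact lattice current of the link scheme; for the leapfrog
    integrator the residual is at rounding level.  Requires the trajectory
    to have been stored every step over at least three steps
    (``store_every=1``).
    """
    if traj.snap_steps is None or np.any(np.diff(traj.snap_steps) != 1):
        raise ValueError("continuity_residual needs store_every=1 trajectories")
    dt, dx, eps = traj.dt, traj.dx, traj.epsilon
    res_sq, cur_sq, count = 0.0, 0.0, 0
    for n in range(1, traj.values.shape[0] - 1):
        phi_m, phi_0, phi_p = traj.values[n - 1], traj.values[n], traj.values[n + 1]
        rho_plus = np.imag(np.conj(phi_0) * phi_p) / dt
        rho_minus = np.imag(np.conj(phi_m) * phi_0) / dt
        Acur = GaugePotentialU1(np.zeros_like(traj.A_x[n]), traj.A_x[n],
                                traj.A_y[n], eps)
        jx, jy = _link_current(phi_0, Acur, dx, params.c2, boundary)
        div = ((jx - shift(jx, -1, 0, boundary))
               + (jy - shift(jy, -1, 1, boundary))) / dx
        res = (rho_plus - rho_minus) / dt + div
        res_sq += float(np.mean(res**2))
        cur_sq += float(np.mean(rho_plus**2 + jx**2 + jy**2))
        count += 1
    return math.sqrt(res_sq / count), math.sqrt(cur_sq / count)


# ---------------------------------------------------------------------------
# Gauss law and the Hebbian rate
# ---------------------------------------------------------------------------

def _dirichlet_laplacian_matrix(nx: int, ny: int, dx: float) -> scipy.sparse.spmatrix:
    ex = np.ones(nx)
    ey = np.ones(ny)
    lx = scipy.sparse.diags([ex[:-1], -2 * ex, ex[:-1]], [-1, 0, 1])
    ly = scipy.sparse.diags([ey[:-1], -2 * ey, ey[:-1]], [-1, 0, 1])
    ix = scipy.sparse.identity(nx)
    iy = scipy.sparse.identity(ny)
    return (scipy.sparse.kron(lx, iy) + scipy.sparse.kron(ix, ly)) / dx**2


def gauss_solve(source: np.ndarray, dx: float = 1.0,
                method: Literal["direct", "dst", "greens"] = "direct",
                absorb_two_pi: bool = False) -> np.ndarray:
    """Solve the 2-D Gauss-law Poisson equation ∂²_i A_t = −source.

    The default is a sparse direct solve of the Dirichlet problem (zero
    exterior potential), under which the discrete Laplacian of the result
    reproduces −source to rounding at *every* node.  ``dst`` is the
    fast-sine-transform solver of the identical Dirichlet problem (used as
    an independent cross-check), and ``greens`` convolves with the free-space
    kernel −log(r)/(2π) (log-accurate away from boundaries; the self-cell is
    assigned the kernel's cell average).

    For a point source of mass q at the grid interior the profile is
    A_t(r) − A_t(r_ref) ≈ −(q/2π)·log(r/r_ref).  With
    ``absorb_two_pi=True`` the result is scaled by 2π to match the
    −log(r)·q convention in which the Green's-function 1/(2π) is absorbed.
    """
    source = np.asarray(source, dtype=float)
    if source.ndim != 2:
        raise ValueError("source must be a 2-D grid field")
    if np.any(source < 0):
        raise ValueError("source (an activity power) must be nonnegative")
    nx, ny = source.shape
    if not np.any(source):
        return np.zeros_like(source)
    if method == "direct":
        L = _dirichlet_laplacian_matrix(nx, ny, dx).tocsc()
        out = scipy.sparse.linalg.spsolve(L, -source.ravel()).reshape(nx, ny)
    elif method == "dst":
        s = scipy.fft.dstn(-source, type=1)
        kx = np.pi * np.arange(1, nx + 1) / (nx + 1)
        ky = np.pi * np.arange(1, ny + 1) / (ny + 1)
        eig = ((2 * np.cos(kx) - 2)[:, None] + (2 * np.cos(ky) - 2)[None, :]) / dx**2
        out = scipy.fft.idstn(s / eig, type=1)
    elif method == "greens":
        pad_x, pad_y = 2 * nx, 2 * ny
        ix = np.minimum(np.arange(pad_x), pad_x - np.arange(pad_x))
        iy = np.minimum(np.arange(pad_y), pad_y - np.arange(pad_y))
        r = dx * np.hypot(ix[:, None], iy[None, :])
        with np.errstate(divide="ignore"):
            g = -np.log(r) / (2 * np.pi)
        g[0, 0] = -(math.log(dx) - 1.5) / (2 * np.pi)  # cell-average self term
        src_pad = np.zeros((pad_x, pad_y))
        src_pad[:nx, :ny] = source * dx**2
        out = np.real(np.fft.ifft2(np.fft.fft2(g) * np.fft.fft2(src_pad)))[:nx, :ny]
    else:
        raise ValueError(f"unknown method {method!r}")
    if absorb_two_pi:
        out = 2.0 * math.pi * out
    return out


def hebbian_rate(phi_mod2: np.ndarray, coeffs: tuple[float, ...] = (),
                 dx: float = 1.0,
                 method: Literal["direct", "dst", "greens"] = "direct",
                 absorb_two_pi: bool = False) -> np.ndarray:
    """Connection-gain rate ∂_t f from the (non-linear) Hebbian source.

    The Gauss-law source is the sigmoid-expansion polynomial
    |φ|² + a₂|φ|⁴ + a₃|φ|⁶ + …, with ``coeffs = (a2, a3, ...)``.  Empty
    coefficients give the linear Hebbian case: the rate at distance r from a
    point of activity falls off as −q·log(r)/(2π).
    """
    phi_mod2 = np.asarray(phi_mod2, dtype=float)
    if np.any(phi_mod2 < 0):
        raise ValueError("phi_mod2 must be nonnegative")
    src = phi_mod2.copy()
    power = phi_mod2.copy()
    for a_k in coeffs:
        power = power * phi_mod2
        src = src + a_k * power
    return gauss_solve(src, dx, method=method,
                       absorb_two_pi=absorb_two_pi)
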