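"""Extrinsic-connectivity learning as metric dynamics.

The stress-energy of the neural field sources the curvature of the
effective surface metric (G_μν = κ T_μν in model units, κ = 1 by default).
Under the Robertson-Walker ansatz the surface is characterized by one
expansion factor a(t), which obeys a Friedmann-like pair

    a′²/a² + k/a² = A(ρ)          (density equation)
    a″/a = −B(p)                  (acceleration equation)

together with the conservation law d(a²ρ)/dt + p·d(a²)/dt = 0.  In the
high-mass limit the density equation collapses to the learning rule
da/dt ≈ ±m|φ|: connection-gain growth proportional to activity strength —
Hebbian dynamics carried by the metric.

Naming: ``kappa_coupling`` is the curvature-stress coupling of G = κT
(set to 1 in model units); ``k_curv`` / ``RWState.k`` is the spatial
curvature constant of the Robertson-Walker metric.  They are unrelated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import scipy.optimize

from .fields_core import Boundary, KGParams, ScalarField2p1, grad_centered
from .geometry import Metric2p1, RWState
from .single_layer import evolve_kg

__all__ = [
    "stress_energy",
    "evolve_expansion",
    "learning_rate",
    "delta_response_experiment",
    "fit_expansion",
    "RWTrajectory",
    "DeltaResponse",
    "DEFAULT_LEARNING_PARAMS",
]

DensityFn = Union[float, Callable[[float, float], float]]


def stress_energy(field: ScalarField2p1, metric: Metric2p1,
                  mass2: float, boundary: Boundary = "periodic"
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonal stress-energy components of the direction-free scalar field:

        T_tt = −√|g| g_tt (g^{ii} ∂_iφ* ∂_iφ − m²|φ|²)
        T_ii = −g_ii B,   B = √|g| (g^{tt}|∂_tφ|² + g^{jj} ∂_jφ*∂_jφ − m²|φ|²)

    For a uniform static field on a flat metric this reduces to the energy
    density T_tt = √|g| m²|φ|², and T_xx/g_xx = T_yy/g_yy = −B by
    construction (isotropy).
    """
    from .fields_core import grid_coordinates
    nx, ny = field.shape
    X, Y = grid_coordinates(nx, ny, field.dx)
    gxx, gyy = metric.spatial(X, Y)
    w = np.sqrt(np.abs(gxx * gyy))
    dphi_x = grad_centered(field.values, field.dx, 0, boundary)
    dphi_y = grad_centered(field.values, field.dx, 1, boundary)
    grad_term = (1.0 / gxx) * np.abs(dphi_x) ** 2 + (1.0 / gyy) * np.abs(dphi_y) ** 2
    mod2 = np.abs(field.values) ** 2
    t_tt = -w * metric.g_tt * (grad_term - mass2 * mod2)
    B = w * (np.abs(field.velocity) ** 2 + grad_term - mass2 * mod2)
    t_xx = -gxx * B
    t_yy = -gyy * B
    return t_tt, t_xx, t_yy


# ---------------------------------------------------------------------------
# Friedmann-like expansion dynamics
# ---------------------------------------------------------------------------


@dataclass
class RWTrajectory:
    times: np.ndarray
    a: np.ndarray
    adot: np.ndarray
    # diagnostics (max absolute residuals along the run)
    density_eq_residual: float
    acceleration_eq_residual: float
    conservation_residual: float


def _as_fn(f: DensityFn) -> Callable[[float, float], float]:
    if callable(f):
        return f
    return lambda a, t, _v=float(f): _v


def evolve_expansion(state: RWState, density: DensityFn, pressure: DensityFn,
                     dt: float, n_steps: int, branch: int = +1) -> RWTrajectory:
    """Integrate the expansion factor and cross-check the Friedmann-like pair.

    The first-order (density) equation a′ = ±√(A·a² − k) is stepped with
    classical RK4; ``density``/``pressure`` are constants or callables
    A(a, t), B(a, t).  Along the trajectory the acceleration equation
    a″ + B·a = 0 and the conservation law d(a²ρ)/dt + p·d(a²)/dt = 0 are
    evaluated by centered differences and their maximum residuals returned —
    for a (ρ, p) pair consistent with the conservation law both stay at
    integration accuracy.
    """
    A_fn, B_fn = _as_fn(density), _as_fn(pressure)
    sgn = 1.0 if branch >= 0 else -1.0

    def rhs(a: float, t: float) -> float:
        val = A_fn(a, t) * a * a - state.k
        if val < -1e-12:
            raise ValueError(
                f"square-root domain violation at t={t:.6g}: A·a² − k = {val:.3g} < 0")
        return sgn * math.sqrt(max(val, 0.0))

    times = np.arange(n_steps + 1) * dt
    a_traj = np.empty(n_steps + 1)
    a_traj[0] = state.a
    for n in range(n_steps):
        t, a = times[n], a_traj[n]
        k1 = rhs(a, t)
        k2 = rhs(a + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = rhs(a + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = rhs(a + dt * k3, t + dt)
        a_traj[n + 1] = a + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    adot = np.array([rhs(a_traj[n], times[n]) for n in range(n_steps + 1)])

    dens_res = float(np.max(np.abs(adot**2 - (np.array(
        [A_fn(a_traj[n], times[n]) for n in range(n_steps + 1)]) * a_traj**2
        - state.k))))
    # centered second difference for a''
    if n_steps >= 2:
        addot = (a_traj[2:] - 2 * a_traj[1:-1] + a_traj[:-2]) / dt**2
        B_mid = np.array([B_fn(a_traj[n], times[n]) for n in range(1, n_steps)])
        acc_res = float(np.max(np.abs(addot + B_mid * a_traj[1:-1])))
        rho = np.array([A_fn(a_traj[n], times[n]) for n in range(n_steps + 1)])
        p = np.array([B_fn(a_traj[n], times[n]) for n in range(n_steps + 1)])
        a2rho = a_traj**2 * rho
        a2 = a_traj**2
        d_a2rho = (a2rho[2:] - a2rho[:-2]) / (2 * dt)
        d_a2 = (a2[2:] - a2[:-2]) / (2 * dt)
        cons_res = float(np.max(np.abs(d_a2rho + p[1:-1] * d_a2)))
    else:
        acc_res = cons_res = float("nan")
    return RWTrajectory(times, a_traj, adot, dens_res, acc_res, cons_res)


def learning_rate(m: float, phi_mod: Union[float, np.ndarray],
                  sign: int = +1) -> Union[float, np.ndarray]:
    """High-mass-limit metric learning rule da/dt = ±m|φ| (default +)."""
    if m < 0:
        raise ValueError("mass must be nonnegative")
    sgn = 1.0 if sign >= 0 else -1.0
    return sgn * m * np.abs(phi_mod)


def fit_expansion(times: np.ndarray, a_traj: np.ndarray,
                  density_model: str = "stiff",
                  x0: tuple[float, float] = (1.0, 0.0)) -> tuple[float, float]:
    """Least-squares refit of (ρ0, k) from an expansion trajectory a(t).

    ``density_model``: "stiff" uses ρ = ρ0/a⁴ with p = ρ (a pair satisfying
    the conservation law and making ρ0 and k separately identifiable);
    "matter2d" uses ρ = ρ0/a², whose coasting trajectories identify only the
    combination ρ0 − k.
    """
    a0 = float(a_traj[0])
    dt = float(times[1] - times[0])
    n_steps = times.size - 1

    def model(params: np.ndarray) -> np.ndarray:
        rho0, k = params
        if density_model == "stiff":
            dens = lambda a, t: rho0 / a**4
            pres = lambda a, t: rho0 / a**4
        elif density_model == "matter2d":
            dens = lambda a, t: rho0 / a**2
            pres = 0.0
        else:
            raise ValueError(f"unknown density model {density_model!r}")
        st = RWState(a=a0, k=k, rho0=rho0)
        return evolve_expansion(st, dens, pres, dt, n_steps).a

    res = scipy.optimize.least_squares(
        lambda p: model(p) - a_traj, x0=np.asarray(x0, float), xtol=1e-14,
        ftol=1e-14, gtol=1e-14)
    return float(res.x[0]), float(res.x[1])


# ---------------------------------------------------------------------------
# before/after learning delta-response experiment
# ---------------------------------------------------------------------------

DEFAULT_LEARNING_PARAMS = {
    "nx": 64, "ny": 64, "dx": 1.0,
    "mass2c4": 1.0 - 0.1 * math.pi,   # U = 0.1, R = 1 weak-branch values
    "c2": 0.025 * math.pi,
    "dt": 0.25, "n_steps": 240,
    "kick_width_cells": 2.0, "kick_amplitude": 1.0,
}


@dataclass
class DeltaResponse:
    times: np.ndarray
    probe_before: np.ndarray
    probe_after: np.ndarray
    amplitude_ratio: float
    area_ratio: float


def _delta_run(a: float, params: dict, probe: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    from .fields_core import grid_coordinates
    nx, ny, dx = params["nx"], params["ny"], params["dx"]
    X, Y = grid_coordinates(nx, ny, dx)
    cx, cy = (nx // 2) * dx, (ny // 2) * dx
    width = params["kick_width_cells"] * dx
    kick = params["kick_amplitude"] * np.exp(
        -((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * width**2))
    field = ScalarField2p1(np.zeros((nx, ny), complex), dx,
                           velocity=kick.astype(complex))
    metric = Metric2p1.robertson_walker(a)
    kg = KGParams(params["mass2c4"], params["c2"])
    traj = evolve_kg(field, kg, metric, params["dt"], params["n_steps"],
                     store_every=1)
    return traj.times, traj.values[:, probe[0], probe[1]]


def delta_response_experiment(a_before: float, a_after: float,
                              params: Optional[dict] = None,
                              probe: Optional[tuple[int, int]] = None) -> DeltaResponse:
    """Response to a narrow (delta-like) perturbation before/after learning.

    The perturbation is a Gaussian velocity kick of width 2·dx at the grid
    centre; the probe (default: the centre node) records the field under the
    pre- and post-learning metrics (flat Robertson-Walker with expansion
    factors ``a_before`` < ``a_after``).  Returns both probe series, the
    ratio of peak |φ| and the ratio of time-integrated |φ|; learning slows
    lateral propagation (effective speed c/a), so activity lingers near the
    perturbation and both ratios exceed 1 for the packaged defaults.
    """
    if a_after < a_before:
        raise ValueError("learning increases a: a_after must be >= a_before")
    p = dict(DEFAULT_LEARNING_PARAMS)
    if params:
        p.update(params)
    if probe is None:
        probe = (p["nx"] // 2, p["ny"] // 2)
    times, before = _delta_run(a_before, p, probe)
    _, after = _delta_run(a_after, p, probe)
    amp_ratio = float(np.max(np.abs(after)) / np.max(np.abs(before)))
    area_ratio = float(np.trapezoid(np.abs(after), times)
                       / np.trapezoid(np.abs(before), times))
    return DeltaResponse(times, before, after, amp_ratio, area_ratio)
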