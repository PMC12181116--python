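"""Single bi-layer neural field: connectivity → Klein-Gordon parameters,
wave evolution, and the strong-intrinsic-connection branch.

Weak connectivity
-----------------
For weak connection gain U over a disc with moments (a, b), the
long-wavelength reduction of the integral neural-field equation is a
Klein-Gordon equation

    ∂²_t φ = −m²c⁴ φ + c² ∇²_g φ,   m²c⁴ = 1 − U a − b ∂²U,   c² = U b.

The integro-differential form (retarded-time disc integral) is never
time-stepped directly: the PDE reduction is the computational object, with
the disc-kernel Taylor expansion assumed exact at the working wavelengths.

Strong intrinsic connectivity
-----------------------------
With a Dirac-like intrinsic connection the sheet supports non-zero
stationary states |φ0| and massless perturbation waves around them with
c² = 2Wβγb|φ0|².

The integrator is leapfrog (velocity Verlet): for the linear wave system it
conserves a shadow energy *exactly* (up to float rounding), which is the
quantity reported by :func:`discrete_energy`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .fields_core import (Boundary, ConnectivityKernel, KGParams,
                          NonWeakParams, ScalarField2p1, laplacian)
from .geometry import Metric2p1, laplace_beltrami

__all__ = [
    "kg_params",
    "evolve_kg",
    "stable_states",
    "perturbation_speed",
    "discrete_energy",
    "discrete_wavenumber_sq",
    "measure_mode_frequency",
    "KGTrajectory",
]


def kg_params(kernel: ConnectivityKernel) -> KGParams:
    """Map a connectivity kernel to Klein-Gordon coefficients.

    m²c⁴ = 1 − U·a − b·∂²U and c² = U·b.  A vanishing or negative mass term
    (massless boundary U·a + b·∂²U = 1 and beyond) is representable and
    flagged on the returned params, not rejected.
    """
    mass2c4 = 1.0 - kernel.U * kernel.a - kernel.b * kernel.lapU
    c2 = kernel.U * kernel.b
    return KGParams(mass2c4=mass2c4, c2=c2)


@dataclass
class KGTrajectory:
    """Stored snapshots of a wave run: values/velocities are stacked with a
    leading snapshot axis aligned with ``times``."""

    times: np.ndarray
    values: np.ndarray
    velocities: np.ndarray
    dx: float
    energies: np.ndarray = dc_field(default=None)

    @property
    def final(self) -> ScalarField2p1:
        return ScalarField2p1(self.values[-1], self.dx, float(self.times[-1]),
                              self.velocities[-1])


def _wave_operator(values: np.ndarray, params: KGParams,
                   metric: Optional[Metric2p1], dx: float,
                   boundary: Boundary) -> np.ndarray:
    """Apply M φ = m²c⁴ φ − c² Δ_g φ (the positive operator of the wave
    equation ∂²_t φ = −M φ)."""
    if metric is None:
        lap = laplacian(values, dx, boundary)
    else:
        lap = laplace_beltrami(metric, ScalarField2p1(values, dx), boundary)
    return np.asarray(params.mass2c4) * values - np.asarray(params.c2) * lap


def _metric_weight(metric: Optional[Metric2p1], shape: tuple[int, int],
                   dx: float) -> np.ndarray:
    if metric is None:
        return np.ones(shape)
    from .fields_core import grid_coordinates
    X, Y = grid_coordinates(shape[0], shape[1], dx)
    gxx, gyy = metric.spatial(X, Y)
    return np.sqrt(np.abs(gxx * gyy))


def discrete_energy(field: ScalarField2p1, params: KGParams,
                    metric: Optional[Metric2p1] = None, dt: float = 0.0,
                    boundary: Boundary = "periodic") -> float:
    """Leapfrog shadow energy of the linear wave system.

    E = Σ √|g| [ |φ̇|² + Re(φ* Mφ) − (dt²/4)|Mφ|² ] dx²  with
    M = m²c⁴ − c²Δ_g.  Because Δ_g is self-adjoint in the √|g|-weighted
    inner product, velocity-Verlet stepping conserves this quantity exactly
    for the linear system; with ``dt=0`` it reduces to the continuum energy.
    """
    w = _metric_weight(metric, field.shape, field.dx)
    mphi = _wave_operator(field.values, params, metric, field.dx, boundary)
    dens = (np.abs(field.velocity) ** 2
            + np.real(np.conj(field.values) * mphi)
            - 0.25 * dt**2 * np.abs(mphi) ** 2)
    return float(np.sum(w * dens) * field.dx**2)


def _check_stability(params: KGParams, dx: float, dt: float,
                     metric: Optional[Metric2p1]) -> None:
    c2_max = float(np.max(np.asarray(params.c2)))
    m2_max = float(np.max(np.abs(np.asarray(params.mass2c4))))
    scale = 1.0
    if metric is not None and not callable(metric.g_xx):
        scale = abs(float(metric.g_xx))  # constant spatial metric −s: c²_eff = c²/s
    c2_eff = c2_max / scale
    if c2_eff > 0 and dt > 0.5 * dx / math.sqrt(c2_eff):
        raise ValueError(
            f"unstable step: dt={dt} exceeds 0.5·dx/√c² = {0.5 * dx / math.sqrt(c2_eff):.4g}")
    omega_max = math.sqrt(m2_max + 8.0 * c2_eff / dx**2)
    if omega_max > 0 and dt > 1.0 / omega_max:
        raise ValueError(
            f"unstable step: dt={dt} exceeds 1/ω_max = {1.0 / omega_max:.4g}")


def evolve_kg(field: ScalarField2p1, params: KGParams,
              metric: Optional[Metric2p1] = None, dt: float = 0.01,
              n_steps: int = 100, store_every: Optional[int] = None,
              boundary: Boundary = "periodic") -> KGTrajectory:
    """Leapfrog (velocity Verlet) evolution of the Klein-Gordon field.

    The flat-metric path composes exactly with the 5-point stencil; curved
    metrics go through :func:`geometry.laplace_beltrami`.  Aborts with a
    diagnostic if the field norm grows beyond 1e6× its initial value
    (instability guard).
    """
    _check_stability(params, field.dx, dt, metric)
    if store_every is None:
        store_every = max(1, n_steps // 200)
    phi = field.values.copy()
    vel = field.velocity.copy()
    dx = field.dx
    t0 = field.time

    norm0 = float(np.sum(np.abs(phi) ** 2) + np.sum(np.abs(vel) ** 2)) + 1e-300
    times, vals, vels, energies = [], [], [], []

    def record(step: int) -> None:
        times.append(t0 + step * dt)
        vals.append(phi.copy())
        vels.append(vel.copy())
        energies.append(discrete_energy(
            ScalarField2p1(phi, dx, 0.0, vel), params, metric, dt, boundary))

    record(0)
    acc = -_wave_operator(phi, params, metric, dx, boundary)
    for step in range(1, n_steps + 1):
        vel = vel + 0.5 * dt * acc
        phi = phi + dt * vel
        acc = -_wave_operator(phi, params, metric, dx, boundary)
        vel = vel + 0.5 * dt * acc
        if step % store_every == 0 or step == n_steps:
            norm = float(np.sum(np.abs(phi) ** 2) + np.sum(np.abs(vel) ** 2))
            if not np.isfinite(norm) or norm > 1e6 * norm0 + 1e6:
                raise RuntimeError(
                    f"instability detected at step {step} (t={t0 + step * dt:.4g}): "
                    f"state norm {norm:.3g} vs initial {norm0:.3g}")
            record(step)
    return KGTrajectory(np.array(times), np.array(vals), np.array(vels), dx,
                        np.array(energies))


# ---------------------------------------------------------------------------
# strong intrinsic connectivity branch
# ---------------------------------------------------------------------------

def stable_states(params: NonWeakParams,
                  kernel: ConnectivityKernel) -> list[float]:
    """Stationary moduli |φ0| of the strong-connection sheet.

    The uniform stationary condition is 1 − α + aγ + β|φ0|² = 0, i.e.
    |φ0|² = (α − 1 − aγ)/β, kept when real and positive; |φ0| = 0 is always
    stationary and always included.
    """
    states = [0.0]
    remainder = 1.0 - params.alpha + kernel.a * params.gamma
    if params.beta == 0.0:
        if remainder != 0.0:
            raise ValueError(
                "beta = 0 with non-vanishing 1 - alpha + a*gamma: no uniform "
                "nontrivial stationary state exists")
        return states
    mod2 = -remainder / params.beta
    if mod2 > 0:
        states.append(math.sqrt(mod2))
    return states


def perturbation_speed(params: NonWeakParams,
                       kernel: ConnectivityKernel) -> float:
    """Squared propagation speed of massless perturbations around the
    nontrivial stationary state: c² = 2 W β γ b |φ0|².

    Downstream evolution uses ``KGParams(mass2c4=0, c2=this)``.
    """
    nontrivial = [s for s in stable_states(params, kernel) if s > 0]
    if params.phi0_mod2 is not None:
        phi0_mod2 = params.phi0_mod2
    elif nontrivial:
        phi0_mod2 = nontrivial[0] ** 2
    else:
        raise ValueError("no nontrivial stable state: massless branch undefined")
    return 2.0 * params.W * params.beta * params.gamma * kernel.b * phi0_mod2


# ---------------------------------------------------------------------------
# dispersion measurement helpers
# ---------------------------------------------------------------------------

def discrete_wavenumber_sq(mode_x: int, mode_y: int, nx: int, ny: int,
                           dx: float) -> float:
    """Eigenvalue −k²_disc of the 5-point Laplacian for the periodic plane
    wave with integer mode numbers: k²_disc = Σ 2(1 − cos(k_i dx))/dx²."""
    kx = 2.0 * math.pi * mode_x / (nx * dx)
    ky = 2.0 * math.pi * mode_y / (ny * dx)
    return (2.0 * (1.0 - math.cos(kx * dx)) + 2.0 * (1.0 - math.cos(ky * dx))) / dx**2


def measure_mode_frequency(traj: KGTrajectory, mode_x: int, mode_y: int) -> float:
    """Oscillation frequency of one spatial Fourier mode of a trajectory.

    Projects each stored snapshot onto the plane wave, then estimates ω from
    linearly interpolated zero crossings of the (co-sinusoidal) projection;
    accurate to far better than 0.1% for ≥ 3 stored periods.
    """
    n_snap, nx, ny = traj.values.shape
    kx = 2.0 * math.pi * mode_x / nx
    ky = 2.0 * math.pi * mode_y / ny
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    probe = np.exp(-1j * (kx * ix + ky * iy))
    series = np.real(np.tensordot(traj.values, probe, axes=([1, 2], [0, 1]))) / (nx * ny)

    sgn = np.sign(series)
    idx = np.where(sgn[:-1] * sgn[1:] < 0)[0]
    if idx.size < 2:
        raise ValueError("too few oscillations stored to measure a frequency; "
                         "extend the run or store more snapshots")
    t = traj.times
    crossings = t[idx] - series[idx] * (t[idx + 1] - t[idx]) / (series[idx + 1] - series[idx])
    return math.pi * (crossings.size - 1) / (crossings[-1] - crossings[0])
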