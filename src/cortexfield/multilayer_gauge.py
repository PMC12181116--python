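"""SU(2) multilayer sector: generators, conserved currents, connection-gain
rates and closed-form generalized oscillations.

With two interacting bi-layers the local invariance group of the field
dynamics is SU(2).  The generators are used exactly in their printed 2×2
form (the full Pauli matrices, not σ/2), so the structure constants are
computed numerically from commutators rather than assumed: for these
unnormalized generators [T¹, T²] = 2i·T³, i.e. f^{123} = 2.

The slowly varying connectivity field modulates the carrier oscillation
e^{±imt} with unitary layer rotations exp(∓iα^aT^a t) — "generalized
oscillations" transferring amplitude and phase between layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import scipy.integrate

__all__ = [
    "GeneratorSet",
    "LayeredField",
    "su2_generators",
    "structure_constants",
    "connectivity_from_current",
    "gain_rates",
    "generalized_oscillation",
    "evolve_su2_approx",
    "integrate_su2_ode",
]


@dataclass
class GeneratorSet:
    """Hermitian generators T^a with coupling ``g`` and structure constants
    f^{abc} satisfying [T^a, T^b] = i f^{abc} T^c (verified numerically)."""

    T: np.ndarray            # (n_gen, n, n) complex Hermitian
    g: float
    f: np.ndarray            # (n_gen, n_gen, n_gen) real

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=complex)
        for a, Ta in enumerate(self.T):
            if not np.allclose(Ta, Ta.conj().T, atol=1e-12):
                raise ValueError(f"generator T^{a + 1} is not Hermitian")
        n_gen = self.T.shape[0]
        for a in range(n_gen):
            for b in range(n_gen):
                comm = self.T[a] @ self.T[b] - self.T[b] @ self.T[a]
                recon = 1j * np.tensordot(self.f[a, b], self.T, axes=(0, 0))
                if not np.allclose(comm, recon, atol=1e-12):
                    raise ValueError(
                        f"structure constants do not close the algebra at (a,b)=({a},{b})")

    @property
    def n_layers(self) -> int:
        return self.T.shape[1]


@dataclass
class LayeredField:
    """n complex amplitudes per node, one per bi-layer (n in {1, 2, 3}).
    ``components`` has the layer axis first; per-node grids or bare layer
    vectors are both accepted."""

    components: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=complex)
        if self.components.shape[0] not in (1, 2, 3):
            raise ValueError("n_layers must be 1, 2 or 3")

    @property
    def n_layers(self) -> int:
        return self.components.shape[0]


def structure_constants(T: np.ndarray) -> np.ndarray:
    """f^{abc} from commutators via the trace inner product:
    f^{abc} = −i·tr([T^a, T^b] T^c)/tr(T^c T^c)."""
    T = np.asarray(T, complex)
    n_gen = T.shape[0]
    f = np.zeros((n_gen, n_gen, n_gen))
    norms = np.array([np.trace(T[c] @ T[c]).real for c in range(n_gen)])
    for a in range(n_gen):
        for b in range(n_gen):
            comm = T[a] @ T[b] - T[b] @ T[a]
            for c in range(n_gen):
                val = -1j * np.trace(comm @ T[c]) / norms[c]
                if abs(val.imag) > 1e-12:
                    raise ValueError("generators do not close under commutation")
                f[a, b, c] = val.real
    return f


def su2_generators(g: float = 1.0) -> GeneratorSet:
    """The three SU(2) generators in their 2×2 Pauli representation:
    T¹ = [[0,1],[1,0]], T² = [[0,−i],[i,0]], T³ = diag(1,−1)."""
    T = np.array([
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
        [[1, 0], [0, -1]],
    ], dtype=complex)
    return GeneratorSet(T=T, g=g, f=structure_constants(T))


def connectivity_from_current(phi: Union[LayeredField, np.ndarray],
                              gens: GeneratorSet) -> np.ndarray:
    """Temporal connectivity components estimated from the conserved SU(2)
    currents: A^a_t = −(φ† T^a φ)/(g·φ†φ), one real value per generator
    (per node for gridded fields)."""
    comp = phi.components if isinstance(phi, LayeredField) else np.asarray(phi, complex)
    n = comp.shape[0]
    if n != gens.n_layers:
        raise ValueError("layer count does not match generator dimension")
    norm = np.sum(np.abs(comp) ** 2, axis=0)
    if np.any(norm <= 0):
        bad = np.argwhere(np.atleast_1d(norm) <= 0)[:3]
        raise ValueError(f"zero field: A^a_t undefined at nodes {bad.tolist()}")
    out = []
    for Ta in gens.T:
        bilinear = np.einsum("i...,ij,j...->...", comp.conj(), Ta, comp)
        out.append(-np.real(bilinear) / (gens.g * norm))
    return np.array(out)


def gain_rates(phi1: Union[complex, np.ndarray], phi2: Union[complex, np.ndarray],
               g: float = 1.0) -> tuple:
    """Connection-gain rates of the three SU(2) channels,

        ∂_t f1 = (φ1*φ2 + φ2*φ1) / (g(|φ1|² + |φ2|²))   cross excit.-inhib.
        ∂_t f2 = (−iφ1*φ2 + iφ2*φ1) / (g(|φ1|² + |φ2|²)) cross excit.-excit.
        ∂_t f3 = (|φ1|² − |φ2|²) / (g(|φ1|² + |φ2|²))    within-layer

    All three are real for arbitrary complex activity (numerator Hermitian).
    """
    phi1 = np.asarray(phi1, complex)
    phi2 = np.asarray(phi2, complex)
    denom = g * (np.abs(phi1) ** 2 + np.abs(phi2) ** 2)
    if np.any(denom == 0):
        raise ValueError("zero total activity: gain rates undefined")
    f1 = np.real(np.conj(phi1) * phi2 + np.conj(phi2) * phi1) / denom
    f2 = np.real(-1j * np.conj(phi1) * phi2 + 1j * np.conj(phi2) * phi1) / denom
    f3 = (np.abs(phi1) ** 2 - np.abs(phi2) ** 2) / denom
    if np.ndim(f1) == 0:
        return float(f1), float(f2), float(f3)
    return f1, f2, f3


def generalized_oscillation(alpha: float, generator_index: int,
                            t: Union[float, np.ndarray]) -> np.ndarray:
    """Unitary layer rotation exp(−iαT^a t) = cos(αt)·I − i·sin(αt)·T^a.

    Closed form valid because the printed generators are involutory
    ((T^a)² = I).  For a = 3 this is diag(e^{−iαt}, e^{iαt}): pure phase
    modulation within each layer; a = 1, 2 transfer amplitude between layers.
    Output shape is (..., 2, 2) for array ``t``.
    """
    if generator_index not in (1, 2, 3):
        raise ValueError("generator index must be 1, 2 or 3")
    Ta = su2_generators().T[generator_index - 1]
    t = np.asarray(t, dtype=float)
    ang = alpha * t
    eye = np.eye(2, dtype=complex)
    out = (np.cos(ang)[..., None, None] * eye
           - 1j * np.sin(ang)[..., None, None] * Ta)
    return out


def evolve_su2_approx(phi0: Union[LayeredField, np.ndarray], m: float,
                      alphas: Sequence[float], t: np.ndarray,
                      sign: int = +1) -> np.ndarray:
    """Carrier-times-rotation approximate solution of the two-layer dynamics:

        φ(t) = e^{±imt} · exp(∓i Σ_a α^a T^a t) · φ0,

    valid for |α| ≪ m (warned otherwise, not enforced).  Both factors are
    unitary, so Σ|φ_i|² is conserved exactly.  Returns (len(t), 2).
    """
    comp = phi0.components if isinstance(phi0, LayeredField) else np.asarray(phi0, complex)
    if comp.shape != (2,):
        raise ValueError("evolve_su2_approx expects a 2-layer amplitude vector")
    alphas = np.asarray(alphas, float)
    if alphas.shape != (3,):
        raise ValueError("three rotation coefficients required (one per generator)")
    if np.max(np.abs(alphas)) > 0.2 * abs(m):
        import warnings
        warnings.warn("rotation rates are not small against the carrier mass; "
                      "the factorized solution degrades", stacklevel=2)
    sgn = 1.0 if sign >= 0 else -1.0
    gens = su2_generators()
    K = np.tensordot(alphas, gens.T, axes=(0, 0))  # Hermitian
    evals, evecs = np.linalg.eigh(K)
    t = np.asarray(t, float)
    carrier = np.exp(sgn * 1j * m * t)
    # exp(∓iKt) φ0 via the eigenbasis
    proj = evecs.conj().T @ comp
    modes = np.exp(-sgn * 1j * np.outer(t, evals)) * proj[None, :]
    rotated = (evecs @ modes.T).T  # (n_t, 2) back to the layer basis
    return carrier[:, None] * rotated


def integrate_su2_ode(phi0: np.ndarray, m: float, alphas: Sequence[float],
                      t: np.ndarray, sign: int = +1,
                      quadratic_shift: float = 0.0,
                      rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
    """Direct numerical integration of the approximate two-layer dynamics

        ∂²_t φ = −(m² + quadratic_shift)·φ + 2m Σ_a α^a T^a φ,

    the final printed approximation of the multilayer equation of motion
    (``quadratic_shift`` reinstates the otherwise dropped 3g²(A_t)² term as a
    constant mass shift).  Initial velocity is matched to the factorized
    closed form, ∂_tφ(0) = i·sign·(mI − Σα^aT^a)φ0.  Used as the independent
    oracle for :func:`evolve_su2_approx`.
    """
    phi0 = np.asarray(phi0, complex)
    alphas = np.asarray(alphas, float)
    gens = su2_generators()
    K = np.tensordot(alphas, gens.T, axes=(0, 0))
    sgn = 1.0 if sign >= 0 else -1.0
    M = (m**2 + quadratic_shift) * np.eye(2) - 2.0 * m * K

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        phi = y[:2] + 1j * y[2:4]
        vel = y[4:6] + 1j * y[6:8]
        acc = -M @ phi
        return np.concatenate([vel.real, vel.imag, acc.real, acc.imag])

    v0 = sgn * 1j * (m * np.eye(2) - K) @ phi0
    y0 = np.concatenate([phi0.real, phi0.imag, v0.real, v0.imag])
    sol = scipy.integrate.solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t,
                                    rtol=rtol, atol=atol, method="DOP853")
    if not sol.success:
        raise RuntimeError(f"SU(2) oracle integration failed: {sol.message}")
    return (sol.y[:2] + 1j * sol.y[2:4]).T
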