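"""Core types, grid stencils, file I/O and configuration.

The cortical sheet is modelled as a uniform rectangular grid carrying a
complex neural field ``phi`` (one complex amplitude per excitatory/inhibitory
bi-layer).  Everything downstream -- wave evolution, gauge coupling, metric
learning, LFP forward models -- builds on the containers and helpers here.

Grid conventions
----------------
Arrays are indexed ``[ix, iy]`` with coordinate ``x = ix * dx`` and
``y = iy * dx`` (square cells).  Boundaries are periodic by default, which
preserves the discrete conservation laws asserted by the test suite;
Dirichlet (zero exterior) boundaries are available via the ``boundary``
flag on the stencil helpers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

log = logging.getLogger("cortexfield")

Boundary = Literal["periodic", "dirichlet"]

__all__ = [
    "ScalarField2p1",
    "ConnectivityKernel",
    "KGParams",
    "NonWeakParams",
    "LFPRecord",
    "InversionResult",
    "SimulationConfig",
    "disc_moments",
    "load_config",
    "write_lfp",
    "read_lfp",
    "save_field",
    "load_field",
    "grid_coordinates",
    "shift",
    "laplacian",
    "grad_centered",
]


# ---------------------------------------------------------------------------
# disc moments
# ---------------------------------------------------------------------------

def disc_moments(R: float) -> tuple[float, float]:
    """Zeroth and second moments of the connectivity disc of radius ``R``.

    ``a`` is the disc area and ``b`` half the second radial moment::

        a = ∬_A dA        = π R²
        b = ½ ∬_A r² dA   = π R⁴ / 4

    These closed forms are what the long-wavelength Taylor expansion of the
    disc-integral connectivity produces; ``b/a = R²/4`` for every radius.
    """
    if R < 0:
        raise ValueError(f"disc radius must be nonnegative, got R={R}")
    a = math.pi * R**2
    b = math.pi * R**4 / 4.0
    return a, b


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ScalarField2p1:
    """Complex neural field on a 2-D grid with its time derivative.

    Attributes
    ----------
    values : complex ndarray (nx, ny)
        Field amplitude per node.
    dx : float
        Grid spacing in model length units.
    time : float
        Current simulation time.
    velocity : complex ndarray (nx, ny)
        Time derivative of the field (second-order evolution needs it).
    """

    values: np.ndarray
    dx: float
    time: float = 0.0
    velocity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.velocity is None:
            self.velocity = np.zeros_like(self.values)
        self.velocity = np.asarray(self.velocity, dtype=complex)
        if self.values.shape != self.velocity.shape:
            raise ValueError("values and velocity must have identical shape")
        if not (np.all(np.isfinite(self.values.view(float)))
                and np.all(np.isfinite(self.velocity.view(float)))):
            raise ValueError("field entries must be finite")
        if not self.dx > 0:
            raise ValueError(f"dx must be positive, got {self.dx}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ScalarField2p1":
        return ScalarField2p1(self.values.copy(), self.dx, self.time,
                              self.velocity.copy())

    @classmethod
    def zeros(cls, nx: int, ny: int, dx: float) -> "ScalarField2p1":
        return cls(np.zeros((nx, ny), complex), dx)

    @classmethod
    def plane_wave(cls, nx: int, ny: int, dx: float, mode_x: int = 1,
                   mode_y: int = 0, amplitude: complex = 1.0) -> "ScalarField2p1":
        """Periodic plane wave e^{i k·r} with k = 2π·mode / L per axis."""
        X, Y = grid_coordinates(nx, ny, dx)
        kx = 2.0 * math.pi * mode_x / (nx * dx)
        ky = 2.0 * math.pi * mode_y / (ny * dx)
        return cls(amplitude * np.exp(1j * (kx * X + ky * Y)), dx)


@dataclass(frozen=True)
class ConnectivityKernel:
    """Scalar connection gain ``U`` over a disc of radius ``R``.

    ``a`` and ``b`` are the disc moments (see :func:`disc_moments`);
    ``lapU`` is the spatial Laplacian of the gain, zero for a gain that is
    constant across the sheet (the default working assumption).
    """

    U: float
    R: float
    a: float
    b: float
    lapU: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("disc moments must be nonnegative")
        if not math.isclose(4.0 * self.b, self.a * self.R**2,
                            rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("disc moments inconsistent: 4b must equal a R²")

    @classmethod
    def from_gain(cls, U: float, R: float, lapU: float = 0.0) -> "ConnectivityKernel":
        a, b = disc_moments(R)
        return cls(U=U, R=R, a=a, b=b, lapU=lapU)


@dataclass(frozen=True)
class KGParams:
    """Klein-Gordon coefficients: ``mass2c4`` is the m²c⁴ term and ``c2``
    the c² coefficient of the spatial Laplacian.

    A negative ``mass2c4`` is representable (tachyonic sheet past the
    connectivity boundary U·a + b·∂²U = 1) and flagged via :attr:`flagged`,
    not rejected.  ``c2`` must be nonnegative for wave evolution.
    """

    mass2c4: Union[float, np.ndarray]
    c2: Union[float, np.ndarray]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.c2) < 0):
            raise ValueError("c2 must be nonnegative for wave evolution")

    @property
    def flagged(self) -> bool:
        """True when the mass term is zero or negative (massless boundary
        or unstable branch)."""
        return bool(np.any(np.asarray(self.mass2c4) <= 0))


@dataclass(frozen=True)
class NonWeakParams:
    """Sigmoid-expansion coefficients of the strong-intrinsic-connection
    branch: connection magnitude ``W = |W|`` and the α, β, γ expansion
    coefficients.  ``phi0_mod2`` caches a stationary modulus squared."""

    W: float
    alpha: float
    beta: float
    gamma: float
    phi0_mod2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.W < 0:
            raise ValueError("connectivity magnitude W = |W| must be >= 0")


@dataclass
class LFPRecord:
    """Laminar traces: ``traces[layer, sample]`` over ``times``.

    ``meta`` carries the generating parameters (mass, damping, rotation
    coefficients, stimulated layer, noise sd, seed, ...), preserved through
    the CSV round-trip via a JSON sidecar.
    """

    times: np.ndarray
    traces: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (n_layers, n_times) array")
        if self.traces.shape[1] != self.times.size:
            raise ValueError("traces column count must match times length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        n_layers = self.meta.get("n_layers")
        if n_layers is not None and int(n_layers) != self.traces.shape[0]:
            raise ValueError("declared n_layers does not match trace rows")

    @property
    def n_layers(self) -> int:
        return self.traces.shape[0]


@dataclass
class InversionResult:
    """Fitted parameters with Gauss-Newton uncertainties and diagnostics."""

    estimates: dict
    standard_errors: dict
    residual_norm: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if self.converged:
            for name, se in self.standard_errors.items():
                if not (np.isnan(se) or se >= 0):
                    raise ValueError(f"standard error for {name} is negative")


# ---------------------------------------------------------------------------
# stencils
# ---------------------------------------------------------------------------

def grid_coordinates(nx: int, ny: int, dx: float) -> tuple[np.ndarray, np.ndarray]:
    """Node coordinate arrays X, Y of shape (nx, ny)."""
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    return np.meshgrid(x, y, indexing="ij")


def shift(arr: np.ndarray, step: int, axis: int,
          boundary: Boundary = "periodic") -> np.ndarray:
    """Value of ``arr`` at the node ``step`` cells ahead along ``axis``.

    ``shift(a, +1, 0)[i, j] == a[i+1, j]`` with periodic wrap or zero fill.
    """
    out = np.roll(arr, -step, axis=axis)
    if boundary == "dirichlet":
        out = out.copy()
        idx = [slice(None)] * arr.ndim
        if step > 0:
            idx[axis] = slice(-step, None)
        else:
            idx[axis] = slice(None, -step)
        out[tuple(idx)] = 0.0
    return out


def laplacian(values: np.ndarray, dx: float,
              boundary: Boundary = "periodic") -> np.ndarray:
    """Standard 5-point Laplacian."""
    out = -4.0 * values
    for axis in (0, 1):
        out = out + shift(values, 1, axis, boundary) + shift(values, -1, axis, boundary)
    return out / dx**2


def grad_centered(values: np.ndarray, dx: float, axis: int,
                  boundary: Boundary = "periodic") -> np.ndarray:
    """Second-order centered difference along ``axis``."""
    return (shift(values, 1, axis, boundary) - shift(values, -1, axis, boundary)) / (2.0 * dx)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class SimulationConfig(BaseModel):
    """Validated simulation parameters.  Unknown keys are rejected and every
    field is range-checked individually; the fully resolved configuration is
    echoed to the package logger on load."""

    model_config = ConfigDict(extra="forbid")

    U: float = Field(0.1, description="connection gain (dimensionless)")
    R: float = Field(1.0, gt=0, description="connectivity disc radius")
    lapU: float = Field(0.0, description="spatial Laplacian of U")
    nx: int = Field(64, ge=4)
    ny: int = Field(64, ge=4)
    dx: float = Field(1.0, gt=0)
    dt: float = Field(0.05, gt=0)
    n_steps: int = Field(1000, ge=1)
    seed: int = Field(0, ge=0)
    epsilon: float = Field(0.01, gt=0, description="neural-connectivity coupling")
    boundary: Boundary = "periodic"
    metric_form: Literal["flat-scaled", "robertson-walker"] = "flat-scaled"
    metric_scale: float = Field(1.0, gt=0, description="expansion factor a")
    k_curv: float = Field(0.0, description="spatial curvature constant")
    kappa_coupling: float = Field(1.0, description="curvature-stress coupling")
    branch_sign: Literal[1, -1] = 1


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load and validate a JSON or YAML configuration file.

    JSON and YAML documents with identical content resolve to identical
    configurations (JSON is parsed by the YAML loader as well, so the two
    dialects share one code path after ``json``/``yaml`` dispatch).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    cfg = SimulationConfig(**data)
    log.info("resolved config: %s", cfg.model_dump_json())
    return cfg


# ---------------------------------------------------------------------------
# LFP trace I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "{:.17e}"


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_lfp(record: LFPRecord, path: Union[str, Path]) -> Path:
    """Write laminar traces as CSV plus a JSON metadata sidecar.

    Column order is fixed (``time,layer_1_re,layer_1_im,...``) and floats are
    written at full precision, so identical records produce byte-identical
    files.  Returns the CSV path.
    """
    path = Path(path)
    n_layers, n_times = record.traces.shape
    cols = ["time"]
    for k in range(1, n_layers + 1):
        cols += [f"layer_{k}_re", f"layer_{k}_im"]
    lines = [",".join(cols)]
    tr = np.asarray(record.traces, dtype=complex)
    for j in range(n_times):
        row = [_FLOAT_FMT.format(record.times[j])]
        for k in range(n_layers):
            row.append(_FLOAT_FMT.format(tr[k, j].real))
            row.append(_FLOAT_FMT.format(tr[k, j].imag))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")
    _meta_path(path).write_text(
        json.dumps(record.meta, sort_keys=True, indent=1, default=float) + "\n")
    return path


def read_lfp(path: Union[str, Path]) -> LFPRecord:
    """Read an LFP CSV written by :func:`write_lfp` (meta sidecar optional)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows: report the row index
        raise ValueError(f"malformed LFP CSV {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ValueError(
            f"empty LFP CSV {path}: missing columns "
            "'time' and 'layer_<k>_re/_im'") from exc
    if "time" not in df.columns:
        raise ValueError(f"LFP CSV {path} is missing the 'time' column")
    n_layers = 0
    while {f"layer_{n_layers + 1}_re", f"layer_{n_layers + 1}_im"} <= set(df.columns):
        n_layers += 1
    if n_layers == 0:
        raise ValueError(
            f"LFP CSV {path} is missing layer columns "
            "('layer_1_re', 'layer_1_im', ...)")
    if df.isna().any().any():
        bad = int(np.where(df.isna().any(axis=1))[0][0])
        raise ValueError(f"malformed LFP CSV {path}: missing value at data row {bad}")
    times = df["time"].to_numpy(float)
    traces = np.empty((n_layers, times.size), complex)
    for k in range(n_layers):
        traces[k] = (df[f"layer_{k + 1}_re"].to_numpy(float)
                     + 1j * df[f"layer_{k + 1}_im"].to_numpy(float))
    meta: dict = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    return LFPRecord(times=times, traces=traces, meta=meta)


# ---------------------------------------------------------------------------
# field snapshot I/O (HDF5 / NPZ)
# ---------------------------------------------------------------------------

def save_field(field: ScalarField2p1, path: Union[str, Path]) -> Path:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=field.values)
            f.create_dataset("velocity", data=field.velocity)
            f.attrs["dx"] = field.dx
            f.attrs["time"] = field.time
    else:
        np.savez(path, values=field.values, velocity=field.velocity,
                 dx=field.dx, time=field.time)
    return path


def load_field(path: Union[str, Path]) -> ScalarField2p1:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            return ScalarField2p1(f["values"][...], float(f.attrs["dx"]),
                                  float(f.attrs["time"]), f["velocity"][...])
    with np.load(path) as z:
        return ScalarField2p1(z["values"], float(z["dx"]), float(z["time"]),
                              z["velocity"])
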