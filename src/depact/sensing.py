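"""Transducer arrays, the sampling operator S, and measurement preprocessing.

The sampling operator maps the pressure field on the simulation grid to the
transducer channels (multilinear interpolation at the element positions)
followed by the acquisition low-pass filter (second-order Butterworth,
0.5 MHz cutoff by default).  Both pieces are linear with exact adjoints, so
the composed measurement model S*A and its transpose remain exact companions
during iterative reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .media import Grid


# --------------------------------------------------------------------------
# Arrays
# --------------------------------------------------------------------------

@dataclass
class SensorArray:
    """Point-detector array: N_m element positions in meters."""

    positions: np.ndarray
    radius: float | None = None
    description: str = ""

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("sensor positions must be finite")
        if self.radius is not None:
            r = np.linalg.norm(self.positions, axis=1)
            if np.any(np.abs(r - self.radius) > 1e-9):
                raise ValueError("canonical array points deviate from stated radius")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


def make_hemispherical_array(radius: float = 0.13, n_arcs: int = 4,
                             n_elements_per_arc: int = 128,
                             n_rotations: int = 100) -> SensorArray:
    """Hemispherical detection surface swept by rotating arc arrays.

    ``n_arcs`` arcs sit at equally spaced azimuths; rotating them through
    (360/n_arcs) degrees in ``n_rotations`` steps tiles the hemisphere.  Each
    arc holds ``n_elements_per_arc`` elements at equally spaced polar angles
    strictly inside (0, 90] degrees so that no two elements coincide.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    thetas = (np.arange(n_elements_per_arc) + 0.5) * (np.pi / 2) / n_elements_per_arc
    step = 2.0 * np.pi / n_arcs / n_rotations
    phis = np.array([
        2.0 * np.pi * a / n_arcs + k * step
        for a in range(n_arcs) for k in range(n_rotations)
    ])
    th, ph = np.meshgrid(thetas, phis, indexing="ij")
    pos = radius * np.stack([
        np.sin(th) * np.cos(ph),
        np.sin(th) * np.sin(ph),
        np.cos(th),
    ], axis=-1).reshape(-1, 3)
    return SensorArray(pos, radius=radius,
                       description=f"hemisphere r={radius} m, "
                                   f"{n_arcs}x{n_elements_per_arc}x{n_rotations}")


def make_circular_array(radius: float, n_elements: int,
                        center=(0.0, 0.0)) -> SensorArray:
    """Uniform full-view circular array (the 2D analogue of the hemisphere)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    ang = 2.0 * np.pi * np.arange(n_elements) / n_elements
    pos = radius * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    arr = SensorArray(pos, radius=radius,
                      description=f"circle r={radius} m, {n_elements} elements")
    arr.positions = arr.positions + np.asarray(center, dtype=float)
    return arr


# --------------------------------------------------------------------------
# Sensor data container
# --------------------------------------------------------------------------

@dataclass
class SensorData:
    """Multi-channel time series d (N_m x N_t) with sampling interval."""

    d: np.ndarray
    dt: float
    t0: float = 0.0
    meta: str = ""

    def __post_init__(self):
        self.d = np.ascontiguousarray(self.d, dtype=np.float64)
        if self.d.ndim != 2 or self.d.shape[1] < 2:
            raise ValueError("sensor data must be N_m x N_t with N_t >= 2")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("sensor data contains non-finite values")
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_channels(self) -> int:
        return self.d.shape[0]

    @property
    def n_samples(self) -> int:
        return self.d.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    def copy(self) -> "SensorData":
        return SensorData(self.d.copy(), self.dt, self.t0, self.meta)


# --------------------------------------------------------------------------
# Sampling operator S (interpolation part)
# --------------------------------------------------------------------------

class FieldSampler:
    """Multilinear interpolation from a grid to fixed positions, with its
    exact transpose (scatter).  Precomputes the 2^dim corner indices and
    weights once per (grid, positions) pair."""

    def __init__(self, grid: Grid, positions: np.ndarray):
        positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
        if positions.shape[1] != grid.dim:
            raise ValueError("position dimensionality does not match grid")
        frac_idx = grid.coord_to_index(positions)
        lo, hi = -1e-9, np.asarray(grid.shape) - 1 + 1e-9
        bad = np.any((frac_idx < lo) | (frac_idx > hi), axis=1)
        if bad.any():
            raise ValueError(
                f"positions outside grid bounds: channels {np.flatnonzero(bad).tolist()[:20]}"
            )
        base = np.clip(np.floor(frac_idx).astype(np.int64), 0,
                       np.asarray(grid.shape) - 2)
        frac = frac_idx - base
        dim = grid.dim
        n = positions.shape[0]
        corners = np.array(np.meshgrid(*([[0, 1]] * dim), indexing="ij")
                           ).reshape(dim, -1).T  # (2^dim, dim)
        idx = base[:, None, :] + corners[None, :, :]          # (n, 2^dim, dim)
        w = np.ones((n, corners.shape[0]))
        for a in range(dim):
            w *= np.where(corners[None, :, a] == 1, frac[:, a:a + 1],
                          1.0 - frac[:, a:a + 1])
        self.grid = grid
        self.flat_idx = np.ravel_multi_index(
            tuple(idx.reshape(-1, dim).T), grid.shape).reshape(n, -1)
        self.weights = w

    def sample(self, fld: np.ndarray) -> np.ndarray:
        return np.sum(fld.ravel()[self.flat_idx] * self.weights, axis=1)

    def scatter(self, values: np.ndarray, out: np.ndarray) -> None:
        """Transpose of :meth:`sample`: accumulate channel values into ``out``."""
        np.add.at(out.ravel(), self.flat_idx.ravel(),
                  (values[:, None] * self.weights).ravel())


def sample_field(fld: np.ndarray, grid: Grid, positions: np.ndarray) -> np.ndarray:
    """One-shot multilinear sampling of a field at arbitrary positions (m)."""
    return FieldSampler(grid, positions).sample(np.asarray(fld, dtype=np.float64))


# --------------------------------------------------------------------------
# Measurement filter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementFilter:
    """Causal Butterworth low-pass applied per channel inside S.

    The adjoint of causal filtering is time-reversed filtering with the same
    coefficients, which is exact for the zero-initial-condition recursion.
    """

    fc: float = 0.5e6
    order: int = 2

    def coefficients(self, dt: float):
        nyq = 0.5 / dt
        if not 0 < self.fc < nyq:
            raise ValueError(f"cutoff {self.fc} Hz must lie in (0, {nyq}) Hz")
        return signal.butter(self.order, self.fc / nyq, btype="low")

    def apply(self, d: np.ndarray, dt: float) -> np.ndarray:
        b, a = self.coefficients(dt)
        return signal.lfilter(b, a, d, axis=-1)

    def apply_adjoint(self, d: np.ndarray, dt: float) -> np.ndarray:
        b, a = self.coefficients(dt)
        return signal.lfilter(b, a, d[..., ::-1], axis=-1)[..., ::-1].copy()


def butterworth_lowpass(data: SensorData, fc: float = 0.5e6, order: int = 2
                        ) -> SensorData:
    """Low-pass filter acquired channels (second-order, 0.5 MHz by default)."""
    filt = MeasurementFilter(fc=fc, order=order)
    return SensorData(filt.apply(data.d, data.dt), data.dt, data.t0,
                      meta=data.meta + f"|butterworth(fc={fc},order={order})")


# --------------------------------------------------------------------------
# Water sound speed
# --------------------------------------------------------------------------

# Fifth-order polynomial fit for pure water at atmospheric pressure
# (Marczak's least-squares fit), valid for 0-95 degrees Celsius.
_WATER_SOS_COEFFS = (
    1.402385e3, 5.038813, -5.799136e-2, 3.287156e-4, -1.398845e-6, 2.787860e-9,
)


def water_sos(temperature_c: float) -> float:
    """Speed of sound in pure water (m/s) from temperature (deg C)."""
    t = np.asarray(temperature_c, dtype=np.float64)
    if np.any(t < 0) or np.any(t > 95):
        raise ValueError("temperature outside the 0-95 C validity range")
    c = np.zeros_like(t)
    for k, a in enumerate(_WATER_SOS_COEFFS):
        c = c + a * t ** k
    return float(c) if np.isscalar(temperature_c) else c
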