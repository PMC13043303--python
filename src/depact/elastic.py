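"""Pseudo-spectral time-domain solver for the isotropic elastic wave equation.

The forward model A solves the velocity-stress initial value problem

    rho dv_i/dt    = d sigma_ij / dx_j
    d sigma_ij/dt  = lam delta_ij dv_k/dx_k + mu (dv_i/dx_j + dv_j/dx_i)
    sigma_ij(0)    = -p0 delta_ij,   v_i(0) = 0

on a regular grid.  Spatial derivatives are Fourier-spectral on grids
staggered by half a cell between velocity and stress components, with an
optional k-space temporal correction (sinc(c_ref |k| dt / 2)) that makes
propagation in a homogeneous medium at c_ref exact in time.  Time stepping is
explicit leapfrog (velocities at half-integer, stresses at integer times;
the first velocity update is a half step).  The domain is terminated by a
split-field perfectly matched layer (PML).

Adjoint by construction
-----------------------
Every time step is assembled as a *tape* of elementary linear operations
(scale by a field, accumulate a weighted field, accumulate a weighted
spectral derivative).  The exact discrete adjoint is the reversed tape with
each primitive transposed -- the transpose of the staggered spectral
derivative D_{+1/2} is -D_{-1/2}, and diagonal scalings are self-adjoint.
This makes the composed measurement operator S.A and its adjoint exact
companions, which the iterative reconstruction relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .media import ElasticMedium, Grid
from .sensing import FieldSampler, MeasurementFilter, SensorArray, SensorData

__all__ = [
    "PMLConfig", "WaveState", "spectral_derivative", "init_from_p0",
    "pressure_from_stress", "check_stability", "step_elastic",
    "ForwardOperator", "forward", "leapfrog_energy", "energy_trace",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PMLConfig:
    """Split-field PML: ``thickness`` cells per side, polynomial absorption
    profile of order ``profile_order`` rising from zero at the inner edge to
    ``target_alpha`` (nepers/s) at the outer edge.  When ``target_alpha`` is
    None it is chosen for a theoretical normal-incidence reflection of 1e-4
    at the reference speed."""

    thickness: int = 10
    profile_order: int = 4
    target_alpha: float | None = None

    def __post_init__(self):
        if self.thickness < 8:
            raise ValueError("PML thickness must be at least 8 cells")
        if self.profile_order < 1:
            raise ValueError("PML profile order must be >= 1")

    def alpha_max(self, c_ref: float, dx: float) -> float:
        if self.target_alpha is not None:
            return self.target_alpha
        length = self.thickness * dx
        return (self.profile_order + 1) * c_ref * np.log(1e4) / (2.0 * length)


@dataclass
class WaveState:
    """One time level of the solver: velocity components and the unique
    stress components (symmetric tensor; keys (i, j) with i <= j)."""

    v: list[np.ndarray]
    sigma: dict[tuple[int, int], np.ndarray]
    t_index: int = 0

    @property
    def dim(self) -> int:
        return len(self.v)

    def copy(self) -> "WaveState":
        return WaveState([a.copy() for a in self.v],
                         {k: a.copy() for k, a in self.sigma.items()},
                         self.t_index)


# --------------------------------------------------------------------------
# Spectral derivative
# --------------------------------------------------------------------------

def _wavenumbers(shape, spacing):
    """Angular wavenumber axes matching numpy's rfftn layout."""
    ks = [2.0 * np.pi * np.fft.fftfreq(n, d=s) for n, s in zip(shape, spacing)]
    ks[-1] = 2.0 * np.pi * np.fft.rfftfreq(shape[-1], d=spacing[-1])
    return ks


def _deriv_multiplier(shape, spacing, axis, shift, kappa=None):
    ks = _wavenumbers(shape, spacing)
    shp = [1] * len(shape)
    shp[axis] = len(ks[axis])
    k = ks[axis].reshape(shp)
    mult = 1j * k * np.exp(1j * k * spacing[axis] * 0.5 * shift)
    if shift == 0 and shape[axis] % 2 == 0:
        # unstaggered odd derivative: zero the Nyquist mode to keep the
        # circulant kernel antisymmetric
        nyq = shape[axis] // 2
        idx = [slice(None)] * len(shape)
        idx[axis] = nyq if axis < len(shape) - 1 else -1
        if axis < len(shape) - 1 or shape[-1] % 2 == 0:
            mult[tuple(idx)] = 0.0
    if kappa is not None:
        mult = mult * kappa
    return mult


def _kspace_kappa(shape, spacing, c_ref, dt):
    ks = _wavenumbers(shape, spacing)
    kmag2 = np.zeros([len(k) for k in ks])
    for a, k in enumerate(ks):
        shp = [1] * len(shape)
        shp[a] = len(k)
        kmag2 = kmag2 + k.reshape(shp) ** 2
    arg = c_ref * np.sqrt(kmag2) * dt / 2.0
    return np.sinc(arg / np.pi)


def spectral_derivative(fld: np.ndarray, axis: int, shift: float,
                        spacing, kappa: np.ndarray | None = None) -> np.ndarray:
    """Fourier-spectral partial derivative with optional half-cell staggering.

    ``shift`` is +0.5, -0.5 or 0 grid cells along ``axis``; the result lives
    on the grid shifted by that amount.  ``kappa`` is an optional real k-space
    multiplier (temporal correction) applied alongside the derivative.
    """
    fld = np.asarray(fld, dtype=np.float64)
    if not np.all(np.isfinite(fld)):
        raise ValueError("non-finite input field")
    if axis >= fld.ndim:
        raise ValueError("axis out of range")
    if np.isscalar(spacing):
        spacing = (float(spacing),) * fld.ndim
    mult = _deriv_multiplier(fld.shape, spacing, axis, shift, kappa)
    return sfft.irfftn(mult * sfft.rfftn(fld), s=fld.shape)


# --------------------------------------------------------------------------
# Tape primitives
#
# ("zero", a)                      a <- 0
# ("scale", a, w)                  a <- w * a            (w field/scalar)
# ("acc", a, b, w)                 a <- a + w * b
# ("deriv", a, b, axis, shift)     a <- D_{axis,shift} b (overwrite)
#
# Transposes, executed in reversed order on the adjoint state:
#   zero  -> zero(a)
#   scale -> scale(a, w)
#   acc   -> acc(b, a, w)
#   deriv -> b += -D_{axis,-shift} a ; a <- 0
# --------------------------------------------------------------------------

class _Engine:
    """Shared machinery: precomputed multipliers, tape construction and
    (adjoint) execution for one (medium, dt, pml, c_ref) configuration."""

    def __init__(self, medium: ElasticMedium, dt: float,
                 pml: PMLConfig | None = None, c_ref: float | None = None,
                 kspace: bool = True):
        self.medium = medium
        self.grid = medium.grid
        self.dim = self.grid.dim
        self.dt = float(dt)
        self.pml = pml
        self.c_ref = float(c_ref) if c_ref is not None else medium.max_speed
        self.kappa = (_kspace_kappa(self.grid.shape, self.grid.spacing,
                                    self.c_ref, self.dt) if kspace else None)
        self._mult = {}
        self._prof_cache = {}
        self.tape_first = self._build_step_tape(first=True)
        self.tape_step = self._build_step_tape(first=False)
        self.adj_first = [self._transpose(op) for op in reversed(self.tape_first)]
        self.adj_step = [self._transpose(op) for op in reversed(self.tape_step)]
        init = self._build_init_tape()
        self.tape_init = init
        self.adj_init = [self._transpose(op) for op in reversed(init)]

    # -- names ------------------------------------------------------------
    @staticmethod
    def _vs(i):  # summed velocity
        return f"v{i}"

    @staticmethod
    def _vsp(i, j):  # velocity split (damping axis j)
        return f"v{i}s{j}"

    @staticmethod
    def _ss(i, j):  # summed stress, i <= j
        return f"s{min(i, j)}{max(i, j)}"

    @staticmethod
    def _ssp(i, j, k):  # stress split (damping axis k)
        return f"s{min(i, j)}{max(i, j)}s{k}"

    def state_names(self):
        names = ["p0", "tmp"]
        d = self.dim
        for i in range(d):
            names.append(self._vs(i))
            names += [self._vsp(i, j) for j in range(d)]
        for i in range(d):
            names.append(self._ss(i, i))
            names += [self._ssp(i, i, k) for k in range(d)]
        for i in range(d):
            for j in range(i + 1, d):
                names.append(self._ss(i, j))
                names += [self._ssp(i, j, a) for a in (i, j)]
        return names

    def zero_state(self) -> dict:
        return {n: np.zeros(self.grid.shape) for n in self.state_names()}

    # -- PML profiles ------------------------------------------------------
    def _pml_factor(self, axis: int, staggered: bool) -> np.ndarray:
        """exp(-alpha dt / 2) profile along ``axis`` broadcast to the grid."""
        key = (axis, staggered)
        if key in self._prof_cache:
            return self._prof_cache[key]
        n = self.grid.shape[axis]
        pos = np.arange(n) + (0.5 if staggered else 0.0)
        alpha = np.zeros(n)
        if self.pml is not None:
            th = self.pml.thickness
            dx = self.grid.spacing[axis]
            amax = self.pml.alpha_max(self.c_ref, dx)
            left = np.clip((th - pos) / th, 0.0, None)
            right = np.clip((pos - (n - 1 - th)) / th, 0.0, None)
            alpha = amax * (left ** self.pml.profile_order
                            + right ** self.pml.profile_order)
        fac = np.exp(-alpha * self.dt / 2.0)
        shp = [1] * self.dim
        shp[axis] = n
        fac = fac.reshape(shp)
        self._prof_cache[key] = fac
        return fac

    # -- tapes -------------------------------------------------------------
    def _build_step_tape(self, first: bool) -> list:
        d = self.dim
        med = self.medium
        dt_v = self.dt / 2.0 if first else self.dt
        tape = []
        # velocity update: rho dv_i/dt = d sigma_ij / dx_j, split over j
        for i in range(d):
            rho_i = 0.5 * (med.rho + np.roll(med.rho, -1, axis=i))
            binv = 1.0 / rho_i
            for j in range(d):
                P = self._pml_factor(j, staggered=(j == i))
                shift = +0.5 if j == i else -0.5
                tape.append(("deriv", "tmp", self._ss(i, j), j, shift))
                tape.append(("scale", self._vsp(i, j), P * P))
                tape.append(("acc", self._vsp(i, j), "tmp", P * dt_v * binv))
            tape.append(("zero", self._vs(i)))
            for j in range(d):
                tape.append(("acc", self._vs(i), self._vsp(i, j), 1.0))
        # stress update: diagonal components, split over the derivative axis k
        for k in range(d):
            P = self._pml_factor(k, staggered=False)
            tape.append(("deriv", "tmp", self._vs(k), k, -0.5))
            for i in range(d):
                coeff = med.lam + (2.0 * med.mu if i == k else 0.0)
                tape.append(("scale", self._ssp(i, i, k), P * P))
                tape.append(("acc", self._ssp(i, i, k), "tmp",
                             P * self.dt * coeff))
        # off-diagonal components, split over their two staggered axes
        for i in range(d):
            for j in range(i + 1, d):
                for a, b in ((i, j), (j, i)):
                    P = self._pml_factor(a, staggered=True)
                    tape.append(("deriv", "tmp", self._vs(b), a, +0.5))
                    tape.append(("scale", self._ssp(i, j, a), P * P))
                    tape.append(("acc", self._ssp(i, j, a), "tmp",
                                 P * self.dt * med.mu))
        # rebuild stress sums
        for i in range(d):
            tape.append(("zero", self._ss(i, i)))
            for k in range(d):
                tape.append(("acc", self._ss(i, i), self._ssp(i, i, k), 1.0))
            for j in range(i + 1, d):
                tape.append(("zero", self._ss(i, j)))
                for a in (i, j):
                    tape.append(("acc", self._ss(i, j), self._ssp(i, j, a), 1.0))
        return tape

    def _build_init_tape(self) -> list:
        # sigma_ii(0) = -p0, distributed evenly over the dim splits
        d = self.dim
        tape = []
        for i in range(d):
            for k in range(d):
                tape.append(("acc", self._ssp(i, i, k), "p0", -1.0 / d))
            tape.append(("zero", self._ss(i, i)))
            for k in range(d):
                tape.append(("acc", self._ss(i, i), self._ssp(i, i, k), 1.0))
        return tape

    @staticmethod
    def _transpose(op):
        kind = op[0]
        if kind == "zero" or kind == "scale":
            return op
        if kind == "acc":
            _, dst, src, w = op
            return ("acc", src, dst, w)
        if kind == "deriv":
            _, dst, src, axis, shift = op
            return ("deriv_t", src, dst, axis, -shift)
        raise ValueError(kind)

    def _get_mult(self, axis, shift):
        key = (axis, shift)
        if key not in self._mult:
            self._mult[key] = _deriv_multiplier(
                self.grid.shape, self.grid.spacing, axis, shift, self.kappa)
        return self._mult[key]

    def _deriv(self, arr, axis, shift):
        return sfft.irfftn(self._get_mult(axis, shift) * sfft.rfftn(arr),
                           s=self.grid.shape)

    def run_tape(self, tape, st):
        for op in tape:
            kind = op[0]
            if kind == "acc":
                _, dst, src, w = op
                d_arr = st[dst]
                d_arr += w * st[src]
            elif kind == "deriv":
                _, dst, src, axis, shift = op
                st[dst] = self._deriv(st[src], axis, shift)
            elif kind == "deriv_t":
                _, dst, src, axis, shift = op
                d_arr = st[dst]
                d_arr -= self._deriv(st[src], axis, shift)
                st[src] = np.zeros(self.grid.shape)
            elif kind == "scale":
                _, dst, w = op
                st[dst] = st[dst] * w
            elif kind == "zero":
                st[op[1]] = np.zeros(self.grid.shape)
            else:
                raise ValueError(kind)

    # -- state conversion --------------------------------------------------
    def state_from_wavestate(self, ws: WaveState) -> dict:
        """Distribute summed fields evenly over the PML splits."""
        st = self.zero_state()
        d = self.dim
        for i in range(d):
            st[self._vs(i)] = ws.v[i].astype(np.float64).copy()
            for j in range(d):
                st[self._vsp(i, j)] = ws.v[i] / d
        for (i, j), arr in ws.sigma.items():
            st[self._ss(i, j)] = arr.astype(np.float64).copy()
            if i == j:
                for k in range(d):
                    st[self._ssp(i, i, k)] = arr / d
            else:
                for a in (i, j):
                    st[self._ssp(i, j, a)] = arr / 2.0
        return st

    def wavestate_from_state(self, st: dict, t_index: int = 0) -> WaveState:
        d = self.dim
        v = [st[self._vs(i)].copy() for i in range(d)]
        sigma = {}
        for i in range(d):
            sigma[(i, i)] = st[self._ss(i, i)].copy()
            for j in range(i + 1, d):
                sigma[(i, j)] = st[self._ss(i, j)].copy()
        return WaveState(v, sigma, t_index)


# --------------------------------------------------------------------------
# Public solver operations
# --------------------------------------------------------------------------

def init_from_p0(p0: np.ndarray, grid: Grid) -> WaveState:
    """Initial wave state: isotropic stress -p0, zero velocity."""
    p0 = np.asarray(p0, dtype=np.float64)
    if p0.shape != grid.shape:
        raise ValueError("p0 must be defined on the full simulation grid")
    if not np.all(np.isfinite(p0)):
        raise ValueError("p0 contains non-finite values")
    if np.any(p0 < 0):
        raise ValueError("initial pressure must be nonnegative")
    d = grid.dim
    v = [np.zeros(grid.shape) for _ in range(d)]
    sigma = {}
    for i in range(d):
        sigma[(i, i)] = -p0.copy()
        for j in range(i + 1, d):
            sigma[(i, j)] = np.zeros(grid.shape)
    return WaveState(v, sigma, 0)


def pressure_from_stress(state: WaveState) -> np.ndarray:
    """Fluid pressure p = -trace(sigma) / dim."""
    d = state.dim
    tr = sum(state.sigma[(i, i)] for i in range(d))
    return -tr / d


def check_stability(medium: ElasticMedium, grid: Grid, dt: float,
                    limit: float = 0.3) -> float:
    """CFL number c_max dt / dx_min; warns above ``limit``."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    cfl = medium.max_speed * dt / min(grid.spacing)
    if cfl > limit:
        warnings.warn(f"CFL {cfl:.3f} exceeds the configured limit {limit}",
                      stacklevel=2)
    return cfl


_stepper_cache: dict = {}


def _engine_for(medium, dt, pml, c_ref, kspace=True) -> _Engine:
    key = (id(medium), dt, pml, c_ref, kspace)
    eng = _stepper_cache.get(key)
    if eng is None or eng.medium is not medium:
        eng = _Engine(medium, dt, pml=pml, c_ref=c_ref, kspace=kspace)
        _stepper_cache.clear()
        _stepper_cache[key] = eng
    return eng


def step_elastic(state: WaveState, medium: ElasticMedium, dt: float,
                 pml: PMLConfig | None = None, c_ref: float | None = None,
                 first: bool | None = None) -> WaveState:
    """Advance one leapfrog step (half velocity step first when
    ``state.t_index == 0``).  Aborts if the fields have blown up."""
    eng = _engine_for(medium, dt, pml, c_ref)
    if first is None:
        first = state.t_index == 0
    st = eng.state_from_wavestate(state)
    ref = max(float(np.abs(a).max()) for k, a in state.sigma.items())
    eng.run_tape(eng.tape_first if first else eng.tape_step, st)
    out = eng.wavestate_from_state(st, state.t_index + 1)
    new_max = max(float(np.abs(a).max()) for a in out.sigma.values())
    if ref > 0 and (not np.isfinite(new_max) or new_max > 1e6 * ref):
        raise FloatingPointError(
            f"instability detected: stress grew from {ref:.3e} to {new_max:.3e}; "
            "reduce dt (see check_stability)")
    return out


# --------------------------------------------------------------------------
# Composed measurement operator S . A
# --------------------------------------------------------------------------

class ForwardOperator:
    """The discrete map from initial pressure to (filtered) channel data, and
    its exact transpose.

    ``roi`` is a tuple of slices selecting the reconstruction region within
    the simulation grid (the unknowns of the inverse problem); the default is
    the full grid.  ``measurement_filter=None`` disables the acquisition
    low-pass inside S.
    """

    def __init__(self, medium: ElasticMedium, sensors: SensorArray, nt: int,
                 dt: float, pml: PMLConfig | None = PMLConfig(),
                 roi: tuple[slice, ...] | None = None,
                 measurement_filter: MeasurementFilter | None = MeasurementFilter(),
                 c_ref: float | None = None):
        if nt < 1:
            raise ValueError("nt must be >= 1")
        self.engine = _Engine(medium, dt, pml=pml, c_ref=c_ref)
        self.grid = medium.grid
        self.nt = int(nt)
        self.dt = float(dt)
        self.sensors = sensors
        self.roi = roi if roi is not None else tuple(slice(None) for _ in self.grid.shape)
        self.roi_shape = np.zeros(self.grid.shape)[self.roi].shape
        self.filter = measurement_filter
        self.sampler = FieldSampler(self.grid, sensors.positions)
        if pml is not None:
            self._check_sensors_inside_pml(pml)
        check_stability(medium, self.grid, dt)

    def _check_sensors_inside_pml(self, pml: PMLConfig):
        idx = self.grid.coord_to_index(self.sensors.positions)
        shp = np.asarray(self.grid.shape)
        bad = np.any((idx < pml.thickness) | (idx > shp - 1 - pml.thickness),
                     axis=1)
        if bad.any():
            raise ValueError(
                "sensors inside the PML region: channels "
                f"{np.flatnonzero(bad).tolist()[:20]}")

    @property
    def n_channels(self) -> int:
        return self.sensors.n_channels

    def embed(self, p0_roi: np.ndarray) -> np.ndarray:
        full = np.zeros(self.grid.shape)
        full[self.roi] = p0_roi
        return full

    def apply(self, p0_roi: np.ndarray) -> np.ndarray:
        """S.A applied to an ROI image; returns (N_m, nt) channel data."""
        p0_roi = np.asarray(p0_roi, dtype=np.float64)
        if p0_roi.shape != self.roi_shape:
            raise ValueError(f"p0 shape {p0_roi.shape} != ROI {self.roi_shape}")
        eng = self.engine
        st = eng.zero_state()
        st["p0"] = self.embed(p0_roi)
        eng.run_tape(eng.tape_init, st)
        d = self.grid.dim
        out = np.empty((self.n_channels, self.nt))
        diag = [eng._ss(i, i) for i in range(d)]
        ref = float(np.abs(st["p0"]).max())
        for n in range(self.nt):
            eng.run_tape(eng.tape_first if n == 0 else eng.tape_step, st)
            tr = st[diag[0]].copy()
            for nm in diag[1:]:
                tr += st[nm]
            out[:, n] = self.sampler.sample(tr) * (-1.0 / d)
            if ref > 0 and n % 100 == 99:
                mx = float(np.abs(tr).max())
                if not np.isfinite(mx) or mx > 1e6 * ref:
                    raise FloatingPointError(
                        f"instability at step {n}: |p| reached {mx:.3e}")
        if self.filter is not None:
            out = self.filter.apply(out, self.dt)
        return out

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`apply`; returns an ROI image."""
        data = np.asarray(data, dtype=np.float64)
        if data.shape != (self.n_channels, self.nt):
            raise ValueError(
                f"data shape {data.shape} != ({self.n_channels}, {self.nt})")
        if self.filter is not None:
            data = self.filter.apply_adjoint(data, self.dt)
        eng = self.engine
        st = eng.zero_state()
        d = self.grid.dim
        diag = [eng._ss(i, i) for i in range(d)]
        for n in range(self.nt - 1, -1, -1):
            vals = data[:, n] * (-1.0 / d)
            scat = np.zeros(self.grid.shape)
            self.sampler.scatter(vals, scat)
            for nm in diag:
                st[nm] = st[nm] + scat
            eng.run_tape(eng.adj_first if n == 0 else eng.adj_step, st)
        eng.run_tape(eng.adj_init, st)
        return st["p0"][self.roi].copy()

    def forward_data(self, p0_roi: np.ndarray, meta: str = "") -> SensorData:
        return SensorData(self.apply(p0_roi), self.dt, t0=self.dt, meta=meta)


def forward(p0: np.ndarray, medium: ElasticMedium, sensors: SensorArray,
            nt: int, dt: float, pml: PMLConfig | None = PMLConfig(),
            measurement_filter: MeasurementFilter | None = None,
            c_ref: float | None = None) -> SensorData:
    """Run the forward model on a full-grid initial pressure image."""
    p0 = np.asarray(p0, dtype=np.float64)
    if np.any(p0 < 0):
        raise ValueError("initial pressure must be nonnegative")
    op = ForwardOperator(medium, sensors, nt, dt, pml=pml, roi=None,
                         measurement_filter=measurement_filter, c_ref=c_ref)
    return op.forward_data(p0)


# --------------------------------------------------------------------------
# Discrete energy
# --------------------------------------------------------------------------

def leapfrog_energy(v_prev: list[np.ndarray], state: WaveState,
                    medium: ElasticMedium) -> float:
    """Conserved discrete energy of the staggered leapfrog scheme.

    Kinetic part uses the product of velocities at the two half-time levels
    bracketing the stress time level (the quadratic form the scheme
    conserves exactly in a periodic lossless medium); strain part is the
    isotropic compliance energy, with the fluid limit p^2 / (2 K) where the
    shear modulus vanishes.
    """
    g = medium.grid
    dV = float(np.prod(g.spacing))
    d = g.dim
    kin = 0.0
    for i in range(d):
        rho_i = 0.5 * (medium.rho + np.roll(medium.rho, -1, axis=i))
        kin += 0.5 * float(np.sum(rho_i * v_prev[i] * state.v[i])) * dV
    lam, mu = medium.lam, medium.mu
    tr = sum(state.sigma[(i, i)] for i in range(d))
    ss = sum(state.sigma[(i, i)] ** 2 for i in range(d))
    for i in range(d):
        for j in range(i + 1, d):
            ss = ss + 2.0 * state.sigma[(i, j)] ** 2
    solid = np.where(mu > 0, mu, 1.0)
    e_solid = (ss - lam * tr ** 2 / (d * lam + 2.0 * mu)) / (4.0 * solid)
    e_fluid = tr ** 2 / (2.0 * d ** 2 * lam)
    strain = float(np.sum(np.where(mu > 0, e_solid, e_fluid))) * dV
    return kin + strain


def energy_trace(p0: np.ndarray, medium: ElasticMedium, nt: int, dt: float,
                 pml: PMLConfig | None = None,
                 c_ref: float | None = None) -> np.ndarray:
    """Run ``nt`` steps and return the conserved discrete energy per stress
    time level (pairing sigma^n with the velocities at n -/+ 1/2).  The first
    level reflects the half-step velocity initialization and is included."""
    state = init_from_p0(p0, medium.grid)
    energies = []
    for _ in range(nt):
        nxt = step_elastic(state, medium, dt, pml=pml, c_ref=c_ref)
        energies.append(leapfrog_energy(nxt.v, state, medium))
        state = nxt
    return np.asarray(energies)
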