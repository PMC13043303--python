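"""Synthetic phantoms, skull shells, and simulated acquisitions.

Everything the test and evaluation machinery needs is generated here, with
no external downloads: vessel-like absorbing phantoms (1-2 mm thick tubes
within a few centimeters), an elastic skull shell (~6.5 mm wall, density
1850 kg/m^3, compression speed 2800 m/s, shear speed 1250 m/s) immersed in
water, clean and noisy channel data from the elastic forward model, an
optional "skull background" interference component emulating external
illumination, and the model-perturbation suite (translation, rotation,
speed rescaling, acoustic-only) used for mismatch studies.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .elastic import ForwardOperator, PMLConfig
from .media import (ElasticMedium, Grid, RigidTransform, SkullMask,
                    assign_properties, rasterize_mask)
from .sensing import (MeasurementFilter, SensorArray, SensorData,
                      make_circular_array, water_sos)

# Default skull properties (homogeneous effective values for an adult skull)
SKULL_RHO = 1850.0     # kg/m^3
SKULL_CP = 2800.0      # m/s
SKULL_CS = 1250.0      # m/s (second-skull variant: 1400 m/s)
WATER_RHO = 1000.0     # kg/m^3


# --------------------------------------------------------------------------
# Phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Vessel/wire phantom: random-walk tubes of a given thickness confined
    to a square extent (1-2 mm thick within <= 5 cm by default)."""

    kind: str = "tubes"
    thickness: float = 1.5e-3
    extent: float = 0.03
    n_segments: int = 5
    seed: int = 0
    center: tuple[float, ...] | None = None  # default: grid center

    def __post_init__(self):
        if self.kind not in ("tubes", "wires", "letters"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not 0.5e-3 <= self.thickness <= 3e-3:
            raise ValueError("phantom thickness outside the supported range")
        if self.extent > 0.05:
            raise ValueError("phantom extent exceeds 5 cm")


def make_vessel_phantom(spec: PhantomSpec, grid: Grid) -> np.ndarray:
    """Binary-amplitude phantom of smooth random-walk tubes.

    Each segment is a random walk with slowly wandering direction, rasterized
    onto the grid and dilated to the requested thickness; amplitude 1 on the
    tubes, 0 elsewhere.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.zeros(grid.shape, dtype=bool)
    if spec.n_segments == 0:
        return img.astype(np.float64)
    dim = grid.dim
    dx = min(grid.spacing)
    if spec.center is not None:
        center = np.asarray(spec.center, dtype=float)
    else:
        center = np.array([(e[0] + e[1]) / 2 for e in grid.extent])
    half = spec.extent / 2.0
    n_steps = int(2.0 * spec.extent / dx)
    for _ in range(spec.n_segments):
        pos = center + rng.uniform(-0.6 * half, 0.6 * half, size=dim)
        direction = rng.standard_normal(dim)
        direction /= np.linalg.norm(direction)
        for _ in range(n_steps):
            idx = np.rint(grid.coord_to_index(pos)).astype(int)
            if np.all(idx >= 0) and np.all(idx < np.asarray(grid.shape)):
                img[tuple(idx)] = True
            direction += 0.15 * rng.standard_normal(dim)
            direction /= np.linalg.norm(direction)
            nxt = pos + direction * dx
            # reflect off the extent box to stay confined
            for a in range(dim):
                if abs(nxt[a] - center[a]) > half:
                    direction[a] = -direction[a]
                    nxt[a] = pos[a] + direction[a] * dx
            pos = nxt
    radius = max(1, int(round((spec.thickness / dx - 1) / 2)))
    coords = np.indices((2 * radius + 1,) * dim) - radius
    selem = (coords ** 2).sum(axis=0) <= radius ** 2
    img = ndimage.binary_dilation(img, structure=selem)
    return img.astype(np.float64)


# --------------------------------------------------------------------------
# Skull shell
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SkullShellSpec:
    """Elliptical (2D) / ellipsoidal (3D) bone shell in water.

    ``inner_radius`` is the semi-axis along the first axis; ``axis_ratios``
    scale the remaining axes (a mild asphericity so that rotations are
    geometrically meaningful, as for a real skull).  ``thickness`` is the
    wall thickness (default 6.5 mm), ``tilt`` an in-plane/about-z rotation
    of the shell (radians).
    """

    inner_radius: float = 15e-3
    thickness: float = 6.5e-3
    rho: float = SKULL_RHO
    cp: float = SKULL_CP
    cs: float = SKULL_CS
    center: tuple[float, ...] = (0.0, 0.0)
    tilt: float = 0.0
    axis_ratios: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.thickness <= 0 or self.inner_radius <= 0:
            raise ValueError("shell radius and thickness must be positive")

    def ratios(self, dim: int) -> tuple[float, ...]:
        if self.axis_ratios is not None:
            if len(self.axis_ratios) != dim:
                raise ValueError("axis_ratios length must equal grid dim")
            return self.axis_ratios
        return (1.0, 0.85) if dim == 2 else (1.0, 0.9, 0.85)


def make_skull_shell(spec: SkullShellSpec, grid: Grid,
                     water: tuple[float, float] = (WATER_RHO, 1500.0),
                     pml_margin: int = 10) -> tuple[ElasticMedium, SkullMask]:
    """Rasterize the shell and assign homogeneous elastic properties.

    Returns the medium (water background, ``mu = 0`` outside the bone) and
    the bone mask.  Raises if the shell does not fit inside the grid with a
    ``pml_margin``-cell clearance.
    """
    dim = grid.dim
    ratios = np.asarray(spec.ratios(dim))
    center = np.asarray(spec.center, dtype=float)
    if center.shape != (dim,):
        raise ValueError("shell center dimensionality mismatch")
    outer = spec.inner_radius * ratios + spec.thickness
    for a in range(dim):
        lo, hi = grid.extent[a]
        margin = pml_margin * grid.spacing[a]
        if center[a] - outer[a] < lo + margin or center[a] + outer[a] > hi - margin:
            raise ValueError("skull shell exceeds the usable (non-PML) grid region")
    mesh = grid.coordinate_mesh()
    rel = [m - center[a] for a, m in enumerate(mesh)]
    if spec.tilt != 0.0:
        c, s = np.cos(-spec.tilt), np.sin(-spec.tilt)
        x, y = rel[0], rel[1]
        rel[0], rel[1] = c * x - s * y, s * x + c * y
    rin = sum((rel[a] / (spec.inner_radius * ratios[a])) ** 2 for a in range(dim))
    rout = sum((rel[a] / outer[a]) ** 2 for a in range(dim))
    mask = SkullMask((rout <= 1.0) & (rin > 1.0), grid, provenance="synthetic")
    medium = assign_properties(mask, (spec.rho, spec.cp, spec.cs), water)
    return medium, mask


# --------------------------------------------------------------------------
# Simulated acquisitions
# --------------------------------------------------------------------------

def simulate_dataset(p0: np.ndarray, medium: ElasticMedium,
                     sensors: SensorArray, nt: int, dt: float,
                     noise_sigma: float = 0.0, seed: int = 0,
                     pml: PMLConfig | None = PMLConfig(),
                     measurement_filter: MeasurementFilter | None = MeasurementFilter(),
                     ) -> tuple[SensorData, np.ndarray]:
    """Forward-model channel data plus seeded white Gaussian noise.

    ``noise_sigma`` is the absolute noise standard deviation (Pa, on the
    gain scale of the data).  Returns the noisy data and the ground-truth
    initial pressure alongside.
    """
    op = ForwardOperator(medium, sensors, nt, dt, pml=pml, roi=None,
                         measurement_filter=measurement_filter)
    clean = op.apply(np.asarray(p0, dtype=np.float64))
    d = clean
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        d = clean + noise_sigma * rng.standard_normal(clean.shape)
    return SensorData(d, dt, t0=dt, meta=f"synthetic seed={seed}"), np.asarray(p0)


def add_skull_background(data: SensorData, medium: ElasticMedium,
                         sensors: SensorArray, mask: SkullMask,
                         strength: float, seed: int = 0,
                         pml: PMLConfig | None = PMLConfig(),
                         measurement_filter: MeasurementFilter | None = MeasurementFilter(),
                         smooth_sigma_vox: float = 3.0,
                         return_component: bool = False):
    """Add the photoacoustic interference generated by the skull itself.

    A seeded nonnegative random texture supported on the bone shell (smoothed
    to the phantom feature scale) is propagated through the same forward
    model and scaled so that its channel RMS equals ``strength`` times the
    RMS of the input data; strength > 1 emulates external illumination.
    """
    if strength == 0:
        out = data.copy()
        return (out, np.zeros_like(data.d)) if return_component else out
    if strength < 0:
        raise ValueError("background strength must be nonnegative")
    rng = np.random.default_rng(seed)
    tex = rng.uniform(size=mask.grid.shape) * mask.mask
    tex = ndimage.gaussian_filter(tex, smooth_sigma_vox) * mask.mask
    if tex.max() > 0:
        tex /= tex.max()
    op = ForwardOperator(medium, sensors, data.n_samples, data.dt, pml=pml,
                         roi=None, measurement_filter=measurement_filter)
    bg = op.apply(tex)
    rms_bg = float(np.sqrt(np.mean(bg ** 2)))
    rms_d = float(np.sqrt(np.mean(data.d ** 2)))
    if rms_bg == 0:
        out = data.copy()
        return (out, np.zeros_like(data.d)) if return_component else out
    bg *= strength * rms_d / rms_bg
    out = SensorData(data.d + bg, data.dt, data.t0,
                     meta=data.meta + f"|skull_background(strength={strength})")
    return (out, bg) if return_component else out


# --------------------------------------------------------------------------
# Model perturbations
# --------------------------------------------------------------------------

def perturb_model(mask: SkullMask, skull: tuple[float, float, float],
                  background: tuple[float, float], kind: str, magnitude
                  ) -> tuple[ElasticMedium, SkullMask]:
    """Perturbed skull model for mismatch studies (the originals untouched).

    kind:
      * ``translate``     -- magnitude is the shift vector (m)
      * ``rotate``        -- magnitude is the angle (rad; about z in 3D)
      * ``cp_scale``      -- magnitude is the fractional change (e.g. -0.10)
      * ``cs_scale``      -- likewise for the shear speed
      * ``acoustic_only`` -- magnitude ignored; skull shear speed set to 0
    """
    rho, cp, cs = skull
    if kind == "translate":
        shift = np.asarray(magnitude, dtype=float)
        tr = RigidTransform(np.eye(mask.grid.dim), shift)
        new_mask = rasterize_mask(mask, tr, mask.grid)
    elif kind == "rotate":
        angle = float(magnitude)
        centroid = mask.centroid()
        rot = RigidTransform.rotation_about_axis(angle, axis=2, dim=mask.grid.dim)
        # rotate about the mask centroid, not the grid origin
        t = centroid - rot.rotation @ centroid
        tr = RigidTransform(rot.rotation, t)
        new_mask = rasterize_mask(mask, tr, mask.grid)
    elif kind == "cp_scale":
        cp = cp * (1.0 + float(magnitude))
        new_mask = mask
    elif kind == "cs_scale":
        cs = cs * (1.0 + float(magnitude))
        new_mask = mask
    elif kind == "acoustic_only":
        cs = 0.0
        new_mask = mask
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return assign_properties(new_mask, (rho, cp, cs), background), new_mask


# --------------------------------------------------------------------------
# The standing 2D transcranial fixture
# --------------------------------------------------------------------------

@dataclass
class TranscranialFixture:
    """A complete 2D synthetic transcranial acquisition."""

    grid: Grid
    medium: ElasticMedium
    mask: SkullMask
    skull: tuple[float, float, float]
    water: tuple[float, float]
    sensors: SensorArray
    p0_true: np.ndarray
    roi: tuple[slice, ...]
    data: SensorData
    dt: float
    nt: int
    pml: PMLConfig
    measurement_filter: MeasurementFilter | None
    water_temperature_c: float

    @property
    def p0_roi(self) -> np.ndarray:
        return self.p0_true[self.roi]

    def recommended_recon_config(self, **overrides):
        """Regularizer weights tuned for this fixture (unit-peak data)."""
        from .reconstruct import ReconConfig
        base = dict(l1_weight=1e-3, tv_weight=2e-3, n_outer=10,
                    power_iters=10, seed=0)
        base.update(overrides)
        return ReconConfig(**base)

    @property
    def roi_grid(self) -> Grid:
        starts = [s.indices(n)[0] for s, n in zip(self.roi, self.grid.shape)]
        shape = self.p0_roi.shape
        origin = tuple(self.grid.origin[a] + starts[a] * self.grid.spacing[a]
                       for a in range(self.grid.dim))
        return Grid(shape, self.grid.spacing, origin)

    def operator(self, medium: ElasticMedium | None = None) -> ForwardOperator:
        return ForwardOperator(medium if medium is not None else self.medium,
                               self.sensors, self.nt, self.dt, pml=self.pml,
                               roi=self.roi,
                               measurement_filter=self.measurement_filter)


def make_transcranial_fixture(seed: int = 7, n: int = 192, nt: int = 1100,
                              noise_rel: float = 0.01,
                              background_strength: float = 0.0,
                              water_temperature_c: float = 20.0,
                              ) -> TranscranialFixture:
    """Build the standing 2D skull-shell acquisition used across the suite.

    The geometry is a scaled-down cross-section of the instrument that keeps
    its proportions: a 256-element circular array of radius 40 mm around an
    elliptical 6.5 mm-thick bone shell whose outer extent is ~0.62 of the
    array radius (as for an adult head in the 13 cm hemisphere), on a 96 mm
    domain at 0.5 mm spacing.  A 1.5 mm tube phantom sits close to the inner
    shell surface (cortical-vessel placement) and is clipped to the fluid
    cavity with 1 mm clearance.  Channel data use dt = 50 ns, the 0.5 MHz
    acquisition low-pass, and 1% additive white Gaussian noise relative to
    the peak signal; the data are normalized to unit peak amplitude,
    mirroring the self-normalization used when comparing images.
    """
    grid = Grid.centered((n, n), 0.5e-3)
    cw = water_sos(water_temperature_c)
    shell = SkullShellSpec(inner_radius=18.5e-3)
    medium, mask = make_skull_shell(shell, grid, water=(WATER_RHO, cw))
    sensors = make_circular_array(40e-3, 256)
    phantom_center = (0.0, -10e-3)
    phantom = make_vessel_phantom(
        PhantomSpec(thickness=1.5e-3, extent=12e-3, n_segments=5, seed=seed,
                    center=phantom_center), grid)
    # sources live inside the cranial cavity: clip to the inner ellipse with
    # 1 mm clearance from the bone
    mesh = grid.coordinate_mesh()
    ratios = np.asarray(shell.ratios(grid.dim))
    inner = sum((mesh[a] / (shell.inner_radius * ratios[a] - 1e-3)) ** 2
                for a in range(grid.dim))
    phantom = phantom * (inner < 1.0)
    ic = [int(round(v)) for v in grid.coord_to_index(np.asarray(phantom_center))]
    roi = tuple(slice(c - 20, c + 20) for c in ic)
    dt, pml = 50e-9, PMLConfig()
    filt = MeasurementFilter()
    op = ForwardOperator(medium, sensors, nt, dt, pml=pml, roi=None,
                         measurement_filter=filt)
    clean = op.apply(phantom)
    peak = float(np.abs(clean).max())
    if peak > 0:
        clean = clean / peak
    rng = np.random.default_rng(seed + 1)
    d = clean + noise_rel * rng.standard_normal(clean.shape)
    data = SensorData(d, dt, t0=dt, meta=f"transcranial fixture seed={seed}")
    if background_strength > 0:
        data = add_skull_background(data, medium, sensors, mask,
                                    background_strength, seed=seed + 2,
                                    pml=pml, measurement_filter=filt)
    return TranscranialFixture(
        grid=grid, medium=medium, mask=mask,
        skull=(shell.rho, shell.cp, shell.cs), water=(WATER_RHO, cw),
        sensors=sensors, p0_true=phantom, roi=roi, data=data, dt=dt, nt=nt,
        pml=pml, measurement_filter=filt,
        water_temperature_c=water_temperature_c)
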