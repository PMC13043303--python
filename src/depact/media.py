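"""Grids, elastic media, skull masks, and rigid registration.

Transcranial photoacoustic reconstruction needs an elastic description of the
skull on the simulation grid.  The skull geometry comes from an adjunct CT or
MR volume: it is binarized, its intra-osseous pores are filled, it is rigidly
registered into the photoacoustic frame using fiducial markers (Kabsch), and
the resulting mask is painted with homogeneous elastic properties (density
plus compression and shear wave speeds) on a water background.

Conventions: 0-based voxel indices, physical coordinates at voxel centers,
SI units throughout (meters, kg/m^3, Pa, m/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


# --------------------------------------------------------------------------
# Grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Regular grid with voxel-center physical coordinates.

    ``coordinate = origin + index * spacing`` per axis.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) not in (2, 3):
            raise ValueError("Grid must be 2D or 3D")
        if not (len(shape) == len(spacing) == len(origin)):
            raise ValueError("shape, spacing, origin must have equal length")
        if any(n < 8 for n in shape):
            raise ValueError("Grid requires at least 8 voxels per axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("Grid spacing must be positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def dim(self) -> int:
        return len(self.shape)

    @classmethod
    def centered(cls, shape, spacing):
        """Grid whose physical center coincides with the coordinate origin."""
        if np.isscalar(spacing):
            spacing = (float(spacing),) * len(shape)
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(tuple(shape), tuple(spacing), origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_to_coord(self, index) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def coord_to_index(self, coord) -> np.ndarray:
        coord = np.asarray(coord, dtype=float)
        return (coord - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_mesh(self) -> list[np.ndarray]:
        axes = [self.axis_coords(a) for a in range(self.dim)]
        return list(np.meshgrid(*axes, indexing="ij"))

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (o, o + (n - 1) * s)
            for o, n, s in zip(self.origin, self.shape, self.spacing)
        )


# --------------------------------------------------------------------------
# Elastic medium
# --------------------------------------------------------------------------

@dataclass
class ElasticMedium:
    """Isotropic elastic medium: density and Lame parameter fields.

    ``mu == 0`` marks fluid voxels (water); the skull is the ``mu > 0``
    region.  Validity (positive density, nonnegative shear modulus,
    positive bulk modulus) is checked on construction.
    """

    rho: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.rho = np.ascontiguousarray(self.rho, dtype=np.float64)
        self.lam = np.ascontiguousarray(self.lam, dtype=np.float64)
        self.mu = np.ascontiguousarray(self.mu, dtype=np.float64)
        for name, arr in (("rho", self.rho), ("lam", self.lam), ("mu", self.mu)):
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.rho <= 0):
            raise ValueError("density must be positive everywhere")
        if np.any(self.mu < 0):
            raise ValueError("shear modulus must be nonnegative")
        bulk = self.lam + 2.0 * self.mu / self.grid.dim
        if np.any(bulk <= 0):
            raise ValueError("bulk modulus lam + 2 mu / dim must be positive")

    @property
    def cp(self) -> np.ndarray:
        """Compression wave speed field (m/s)."""
        return np.sqrt((self.lam + 2.0 * self.mu) / self.rho)

    @property
    def cs(self) -> np.ndarray:
        """Shear wave speed field (m/s); zero in fluids."""
        return np.sqrt(self.mu / self.rho)

    @property
    def max_speed(self) -> float:
        return float(self.cp.max())

    def copy(self) -> "ElasticMedium":
        return ElasticMedium(self.rho.copy(), self.lam.copy(), self.mu.copy(), self.grid)


@dataclass
class SkullMask:
    """Boolean bone mask on a grid, with provenance (CT | MR | synthetic)."""

    mask: np.ndarray
    grid: Grid
    provenance: str = "synthetic"

    def __post_init__(self):
        self.mask = np.ascontiguousarray(self.mask).astype(bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> np.ndarray:
        """Physical centroid (m) of the bone voxels."""
        idx = np.argwhere(self.mask)
        return self.grid.index_to_coord(idx.mean(axis=0))


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion x -> R x + t mapping adjunct-image coordinates into the
    photoacoustic frame."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        if R.shape not in ((2, 2), (3, 3)) or t.shape != (R.shape[0],):
            raise ValueError("rotation must be dxd and translation length d")
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-12):
            raise ValueError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-12):
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def dim(self) -> int:
        return self.rotation.shape[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls, dim: int) -> "RigidTransform":
        return cls(np.eye(dim), np.zeros(dim))

    @classmethod
    def rotation_about_axis(cls, angle_rad: float, axis: int = 2,
                            translation=None, dim: int = 3) -> "RigidTransform":
        """Right-handed rotation about a coordinate axis (the only axis
        meaningful in 2D is the out-of-plane one, pass dim=2)."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        if dim == 2:
            R = np.array([[c, -s], [s, c]])
        else:
            R = np.eye(3)
            i, j = [(1, 2), (2, 0), (0, 1)][axis]
            R[i, i] = c
            R[j, j] = c
            R[i, j] = -s
            R[j, i] = s
        t = np.zeros(dim) if translation is None else np.asarray(translation, float)
        return cls(R, t)


# --------------------------------------------------------------------------
# Elastic constants
# --------------------------------------------------------------------------

def speeds_to_lame(rho: float, cp: float, cs: float) -> tuple[float, float]:
    """Convert (density, compression speed, shear speed) to Lame parameters.

    mu = rho cs^2 and lam = rho (cp^2 - 2 cs^2).  Rejects pairs whose
    implied bulk modulus would be non-positive (cs too large relative to cp).
    """
    rho, cp, cs = float(rho), float(cp), float(cs)
    if rho <= 0:
        raise ValueError("density must be positive")
    if cp <= 0:
        raise ValueError("compression speed must be positive")
    if cs < 0:
        raise ValueError("shear speed must be nonnegative")
    mu = rho * cs ** 2
    lam = rho * (cp ** 2 - 2.0 * cs ** 2)
    dim_min_bulk = lam + 2.0 * mu / 3.0  # most restrictive (3D) bulk modulus
    if dim_min_bulk <= 0:
        raise ValueError(
            f"speeds (cp={cp}, cs={cs}) imply non-positive bulk modulus"
        )
    return lam, mu


def lame_to_speeds(rho: float, lam: float, mu: float) -> tuple[float, float]:
    """Inverse of :func:`speeds_to_lame`."""
    cp = np.sqrt((lam + 2.0 * mu) / rho)
    cs = np.sqrt(mu / rho)
    return float(cp), float(cs)


# --------------------------------------------------------------------------
# Rigid registration (Kabsch)
# --------------------------------------------------------------------------

def kabsch_register(src_points: np.ndarray, dst_points: np.ndarray
                    ) -> tuple[RigidTransform, float]:
    """Least-squares rigid alignment of two corresponded point sets.

    Finds the rotation R (det +1) and translation t minimizing
    sum_k ||R src_k + t - dst_k||^2 via SVD of the cross-covariance, with the
    standard reflection correction (sign flip of the smallest singular
    direction).  Returns the transform and the residual RMSD (m).
    """
    src = np.asarray(src_points, dtype=np.float64)
    dst = np.asarray(dst_points, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2:
        raise ValueError("point sets must be K x dim arrays of equal shape")
    k, dim = src.shape
    if dim not in (2, 3):
        raise ValueError("points must be 2D or 3D")
    if k < dim:
        raise ValueError(f"need at least {dim} point pairs in {dim}D")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    H = src_c.T @ dst_c
    U, S, Vt = np.linalg.svd(H)
    # rank-deficient covariance (collinear 3D / coincident points) is
    # degenerate: the in-plane rotation about the deficient direction is free
    scale = max(S[0], np.finfo(float).eps)
    if np.sum(S / scale > 1e-9) < dim - 1 or S[0] == 0:
        raise ValueError("degenerate point configuration (rank-deficient covariance)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(dim)
    D[-1, -1] = d if d != 0 else 1.0
    R = Vt.T @ D @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(src) - dst) ** 2, axis=1))))
    return transform, rmsd


# --------------------------------------------------------------------------
# Mask extraction and resampling
# --------------------------------------------------------------------------

def binarize_fill_mask(volume: np.ndarray, grid: Grid, threshold="otsu",
                       invert: bool = False, closing_radius: int = 2,
                       provenance: str = "CT") -> SkullMask:
    """Binarize an adjunct skull volume and fill intra-osseous pores.

    The volume is thresholded (Otsu by default, or an explicit value), with
    ``invert=True`` for MR-style negative bone contrast.  Morphological
    closing (ball/disk of ``closing_radius`` voxels) bridges thin gaps, then
    every enclosed non-bone cavity is filled *except* the largest one, which
    is taken to be the cranial cavity and must stay fluid.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite values")
    if invert:
        vol = -vol
    if threshold == "otsu":
        if vol.max() == vol.min():
            raise ValueError("constant volume: threshold is pathological")
        thr = threshold_otsu(vol)
    else:
        thr = float(threshold)
    mask = vol > thr
    if not mask.any() or mask.all():
        raise ValueError(
            f"thresholding at {thr!r} produced an all-{'true' if mask.all() else 'false'} mask"
        )
    if closing_radius > 0:
        selem = _ball(closing_radius, vol.ndim)
        mask = ndimage.binary_closing(mask, structure=selem)
    mask = _fill_pores(mask)
    return SkullMask(mask, grid, provenance=provenance)


def _ball(radius: int, dim: int) -> np.ndarray:
    coords = np.indices((2 * radius + 1,) * dim) - radius
    return (coords ** 2).sum(axis=0) <= radius ** 2


def _fill_pores(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed non-bone components except the largest (cranial cavity).

    Non-bone components touching the volume border are exterior water and are
    never filled.
    """
    labels, n = ndimage.label(~mask)
    if n == 0:
        return mask
    border = np.zeros_like(mask)
    for axis in range(mask.ndim):
        sl = [slice(None)] * mask.ndim
        for edge in (0, -1):
            sl[axis] = edge
            border[tuple(sl)] = True
    border_labels = set(np.unique(labels[border])) - {0}
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    enclosed = [l for l in range(1, n + 1) if l not in border_labels]
    if enclosed:
        cavity = max(enclosed, key=lambda l: sizes[l - 1])
        fill = [l for l in enclosed if l != cavity]
        if fill:
            out = mask.copy()
            out[np.isin(labels, fill)] = True
            return out
    return mask


def rasterize_mask(mask: SkullMask, transform: RigidTransform, target: Grid
                   ) -> SkullMask:
    """Resample a rigidly transformed mask onto a target grid.

    Nearest-neighbor inverse mapping: each target voxel center is pulled back
    through the inverse transform and the nearest source voxel is read, which
    preserves binarity.
    """
    if transform.dim != target.dim or mask.grid.dim != target.dim:
        raise ValueError("transform/grid dimensionality mismatch")
    mesh = target.coordinate_mesh()
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    src_pts = transform.inverse().apply(pts)
    idx = np.rint(mask.grid.coord_to_index(src_pts)).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(mask.grid.shape)), axis=1)
    out = np.zeros(target.shape, dtype=bool).ravel()
    if inside.any():
        flat = np.ravel_multi_index(tuple(idx[inside].T), mask.grid.shape)
        out[inside] = mask.mask.ravel()[flat]
    out = out.reshape(target.shape)
    if mask.mask.any() and not out.any():
        raise ValueError("transformed mask falls entirely outside the target grid")
    return SkullMask(out, target, provenance=mask.provenance)


def assign_properties(mask: SkullMask, skull: tuple[float, float, float],
                      background: tuple[float, float]) -> ElasticMedium:
    """Paint homogeneous elastic properties onto a bone mask.

    ``skull`` is (rho, cp, cs); ``background`` is (rho, cp) for water
    (shear-free).  Setting the skull ``cs`` to zero yields the acoustic-only
    model variant in which the skull supports only compression waves.
    """
    rho_s, cp_s, cs_s = skull
    rho_w, cp_w = background
    lam_s, mu_s = speeds_to_lame(rho_s, cp_s, cs_s)
    lam_w, mu_w = speeds_to_lame(rho_w, cp_w, 0.0)
    m = mask.mask
    rho = np.where(m, rho_s, rho_w)
    lam = np.where(m, lam_s, lam_w)
    mu = np.where(m, mu_s, mu_w)
    return ElasticMedium(rho, lam, mu, mask.grid)
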