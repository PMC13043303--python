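"""Quantitative image comparison: correlation, sliding correlation, SSIM,
maximum amplitude projections, and line profiles.

Reconstructions are conventionally self-normalized by their maximum voxel
value before comparison; all metrics here are invariant to positive
rescaling of both images, so normalization affects presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .media import Grid


@dataclass
class ImagePair:
    """A test image and its reference, with optional self-max normalization."""

    test: np.ndarray
    reference: np.ndarray
    normalization: str = "self-max"

    def __post_init__(self):
        self.test = np.asarray(self.test, dtype=np.float64)
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.test.shape != self.reference.shape:
            raise ValueError("test and reference images must share a shape")
        if self.normalization not in ("self-max", "none"):
            raise ValueError("normalization must be 'self-max' or 'none'")
        if self.normalization == "self-max":
            if self.reference.max() <= 0:
                raise ValueError("self-max normalization needs a positive reference max")
            tmax = self.test.max()
            self.test = self.test / tmax if tmax > 0 else self.test
            self.reference = self.reference / self.reference.max()


def _as_pair(pair_or_test, reference) -> ImagePair:
    if isinstance(pair_or_test, ImagePair):
        return pair_or_test
    return ImagePair(pair_or_test, reference, normalization="none")


def correlation(pair: ImagePair | np.ndarray, reference: np.ndarray | None = None
                ) -> float:
    """Pearson correlation coefficient over all voxels."""
    p = _as_pair(pair, reference)
    a = p.test.ravel() - p.test.mean()
    b = p.reference.ravel() - p.reference.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a zero-variance image")
    return float(np.dot(a, b) / (na * nb))


def sliding_correlation(pair: ImagePair | np.ndarray,
                        reference: np.ndarray | None = None,
                        max_shift: int = 5, return_shift: bool = False):
    """Maximum zero-mean normalized cross-correlation over integer shifts.

    The test image is shifted by up to ``max_shift`` voxels per axis and the
    Pearson correlation is evaluated on the overlap region (per-overlap
    means and variances).  Insensitive to small translations by design.
    """
    p = _as_pair(pair, reference)
    if max_shift < 0:
        raise ValueError("max_shift must be nonnegative")
    shape = np.asarray(p.test.shape)
    min_overlap = np.prod(shape - max_shift)
    if min_overlap < 0.25 * np.prod(shape):
        raise ValueError("overlap at the maximal shift is below 25% of the image")
    best, best_shift = -np.inf, None
    ranges = [range(-max_shift, max_shift + 1)] * p.test.ndim
    for shift in np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, p.test.ndim):
        sl_t, sl_r = [], []
        for s, n in zip(shift, shape):
            if s >= 0:
                sl_t.append(slice(s, n))
                sl_r.append(slice(0, n - s))
            else:
                sl_t.append(slice(0, n + s))
                sl_r.append(slice(-s, n))
        a = p.test[tuple(sl_t)].ravel()
        b = p.reference[tuple(sl_r)].ravel()
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            continue
        cc = float(np.dot(a, b) / (na * nb))
        if cc > best:
            best, best_shift = cc, tuple(int(s) for s in shift)
    if best == -np.inf:
        raise ValueError("all shifted overlaps had zero variance")
    return (best, best_shift) if return_shift else best


def ssim(pair: ImagePair | np.ndarray, reference: np.ndarray | None = None,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
         dynamic_range: float | None = None) -> float:
    """Mean local structural similarity with a Gaussian window.

    Defaults follow the conventional choice: 11-tap Gaussian window
    (sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic range equal to the reference
    maximum unless given.
    """
    p = _as_pair(pair, reference)
    win = 2 * int(np.ceil(3 * sigma)) + 1
    if min(p.test.shape) < win:
        raise ValueError(f"images smaller than the {win}-tap SSIM window")
    if dynamic_range is None:
        dynamic_range = float(p.reference.max())
        if dynamic_range <= 0:
            raise ValueError("reference maximum is not positive; pass dynamic_range")
    return float(structural_similarity(
        p.test, p.reference, gaussian_weights=True, sigma=sigma,
        use_sample_covariance=False, K1=k1, K2=k2, data_range=dynamic_range))


def map_projection(volume: np.ndarray, axis: int = -1,
                   slab: tuple[int, int] | None = None) -> np.ndarray:
    """Maximum amplitude projection of a slab of slices along ``axis``."""
    volume = np.asarray(volume)
    axis = axis % volume.ndim
    n = volume.shape[axis]
    lo, hi = (0, n) if slab is None else slab
    if not (0 <= lo < hi <= n):
        raise ValueError(f"empty or out-of-bounds slab {slab} for axis size {n}")
    sl = [slice(None)] * volume.ndim
    sl[axis] = slice(lo, hi)
    return volume[tuple(sl)].max(axis=axis)


def line_profile(image: np.ndarray, grid: Grid, p1, p2, n_samples: int = 100
                 ) -> np.ndarray:
    """Bilinear samples at ``n_samples`` uniform points on the segment
    p1 -> p2 (physical coordinates, m)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    for p in (p1, p2):
        idx = grid.coord_to_index(p)
        if np.any(idx < 0) or np.any(idx > np.asarray(grid.shape) - 1):
            raise ValueError(f"profile endpoint {p} outside the image")
    ts = np.linspace(0.0, 1.0, int(n_samples))
    pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
    coords = grid.coord_to_index(pts).T
    return ndimage.map_coordinates(np.asarray(image, dtype=np.float64), coords,
                                   order=1, mode="nearest")
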