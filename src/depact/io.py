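"""File formats: NIfTI volumes/masks, HDF5 sensor data, CSV fiducials.

Round-trips are bit-exact for 64-bit payloads.  Volumes keep SI units: the
NIfTI affine is diagonal in the grid spacing (meters) with the translation
holding the physical coordinate of voxel (0, ..., 0); 2D grids are stored as
single-slice 3D volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .media import Grid, SkullMask
from .sensing import SensorArray, SensorData


# --------------------------------------------------------------------------
# NIfTI volumes
# --------------------------------------------------------------------------

def _affine_from_grid(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    for a in range(grid.dim):
        aff[a, a] = grid.spacing[a]
        aff[a, 3] = grid.origin[a]
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> Grid:
    dim = 2 if (len(shape) == 3 and shape[2] == 1) else len(shape)
    spacing = tuple(float(aff[a, a]) for a in range(dim))
    origin = tuple(float(aff[a, 3]) for a in range(dim))
    return Grid(tuple(int(n) for n in shape[:dim]), spacing, origin)


def save_volume(path, array: np.ndarray, grid: Grid) -> None:
    """Write a scalar field as NIfTI-1 (float64; masks should use save_mask)."""
    arr = np.asarray(array)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    if grid.dim == 2:
        arr = arr[..., None]
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), _affine_from_grid(grid))
    img.header.set_xyzt_units("meter")
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = _grid_from_affine(img.affine, data.shape)
    if grid.dim == 2 and data.ndim == 3:
        data = data[..., 0]
    return np.ascontiguousarray(data), grid


def save_mask(path, mask: SkullMask) -> None:
    """Write a skull mask as an 8-bit NIfTI volume."""
    arr = mask.mask.astype(np.uint8)
    if mask.grid.dim == 2:
        arr = arr[..., None]
    img = nib.Nifti1Image(arr, _affine_from_grid(mask.grid))
    img.header.set_xyzt_units("meter")
    img.header["descrip"] = mask.provenance.encode()[:79]
    nib.save(img, str(path))


def load_mask(path) -> SkullMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = _grid_from_affine(img.affine, data.shape)
    if grid.dim == 2 and data.ndim == 3:
        data = data[..., 0]
    prov = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "CT"
    return SkullMask(data > 0, grid, provenance=prov)


# --------------------------------------------------------------------------
# HDF5 sensor data
# --------------------------------------------------------------------------

def save_sensor_data(path, data: SensorData, sensors: SensorArray | None = None
                     ) -> None:
    """HDF5 layout: /data (N_m x N_t float64), /dt, /t0 (scalars, s),
    /positions (N_m x dim, m), and a JSON ``meta`` attribute."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("data", data=data.d, dtype=np.float64)
        f.create_dataset("dt", data=np.float64(data.dt))
        f.create_dataset("t0", data=np.float64(data.t0))
        if sensors is not None:
            f.create_dataset("positions", data=sensors.positions,
                             dtype=np.float64)
        f.attrs["meta"] = json.dumps({"meta": data.meta})


def load_sensor_data(path) -> tuple[SensorData, SensorArray | None]:
    try:
        with h5py.File(str(path), "r") as f:
            for key in ("data", "dt", "t0"):
                if key not in f:
                    raise ValueError(f"malformed sensor file: missing /{key}")
            d = f["data"][()]
            dt = float(f["dt"][()])
            t0 = float(f["t0"][()])
            meta = ""
            if "meta" in f.attrs:
                meta = json.loads(f.attrs["meta"]).get("meta", "")
            sensors = None
            if "positions" in f:
                sensors = SensorArray(f["positions"][()])
    except OSError as exc:
        raise ValueError(f"cannot read HDF5 sensor file {path}: {exc}") from exc
    return SensorData(d, dt, t0, meta=meta), sensors


# --------------------------------------------------------------------------
# Fiducial CSV
# --------------------------------------------------------------------------

def load_fiducials(path) -> np.ndarray:
    """Plain-text CSV of fiducial points, one per row, columns x,y[,z] in
    meters, header line required."""
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if len(lines) < 2:
        raise ValueError(f"fiducial file {path} has no data rows")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header[0] not in ("x",):
        raise ValueError("fiducial CSV must start with a header line (x,y[,z])")
    pts = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
    if pts.shape[1] not in (2, 3):
        raise ValueError("fiducial CSV must have 2 or 3 coordinate columns")
    return pts


def save_fiducials(path, points: np.ndarray) -> None:
    points = np.atleast_2d(points)
    header = ",".join("xyz"[: points.shape[1]])
    rows = [header] + [",".join(f"{v:.9e}" for v in p) for p in points]
    Path(path).write_text("\n".join(rows) + "\n")
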