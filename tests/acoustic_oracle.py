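"""Independent scalar acoustic reference solver for the fluid-limit check.

A first-order pressure--velocity pseudo-spectral solver written separately
from the package's elastic engine (no shared code beyond numpy/scipy): same
staggering, leapfrog, k-space temporal correction, and split-field PML
conventions, so that the elastic solver with mu = 0 must reproduce its
sensor traces.
"""

import numpy as np
from scipy import fft as sfft
from scipy.ndimage import map_coordinates
from scipy.signal import butter, lfilter


def _deriv(fld, axis, shift, spacing, kappa):
    shape = fld.shape
    ks = [2 * np.pi * np.fft.fftfreq(n, d=s) for n, s in zip(shape, spacing)]
    ks[-1] = 2 * np.pi * np.fft.rfftfreq(shape[-1], d=spacing[-1])
    shp = [1] * len(shape)
    shp[axis] = len(ks[axis])
    k = ks[axis].reshape(shp)
    mult = 1j * k * np.exp(1j * k * spacing[axis] * 0.5 * shift) * kappa
    return sfft.irfftn(mult * sfft.rfftn(fld), s=shape)


def acoustic_sensor_traces(p0, spacing, rho, c, dt, nt, sensor_idx,
                           pml_thickness=10, pml_order=4, filter_fc=None,
                           filter_order=2):
    """Pressure traces at fractional-index sensor positions.

    ``sensor_idx`` is (N, dim) fractional grid indices.  Returns (N, nt),
    sampled at the stress/pressure time levels t = dt, 2 dt, ..., optionally
    low-pass filtered like the acquisition chain.
    """
    p0 = np.asarray(p0, float)
    dim = p0.ndim
    shape = p0.shape
    ks = [2 * np.pi * np.fft.fftfreq(n, d=s) for n, s in zip(shape, spacing)]
    ks[-1] = 2 * np.pi * np.fft.rfftfreq(shape[-1], d=spacing[-1])
    kmag2 = np.zeros([len(k) for k in ks])
    for a, k in enumerate(ks):
        shp = [1] * dim
        shp[a] = len(k)
        kmag2 = kmag2 + k.reshape(shp) ** 2
    kappa = np.sinc(c * np.sqrt(kmag2) * dt / 2.0 / np.pi)

    def pml_fac(axis, staggered):
        n = shape[axis]
        pos = np.arange(n) + (0.5 if staggered else 0.0)
        alpha = np.zeros(n)
        if pml_thickness:
            L = pml_thickness * spacing[axis]
            amax = (pml_order + 1) * c * np.log(1e4) / (2.0 * L)
            left = np.clip((pml_thickness - pos) / pml_thickness, 0, None)
            right = np.clip((pos - (n - 1 - pml_thickness)) / pml_thickness, 0, None)
            alpha = amax * (left ** pml_order + right ** pml_order)
        shp = [1] * dim
        shp[axis] = n
        return np.exp(-alpha * dt / 2.0).reshape(shp)

    u = [np.zeros(shape) for _ in range(dim)]
    psplit = [p0 / dim for _ in range(dim)]
    out = np.empty((len(sensor_idx), nt))
    coords = np.asarray(sensor_idx, float).T
    for n_ in range(nt):
        dt_v = dt / 2.0 if n_ == 0 else dt
        p = sum(psplit)
        for a in range(dim):
            Pa = pml_fac(a, True)
            u[a] = Pa * (Pa * u[a] - (dt_v / rho) * _deriv(p, a, +0.5, spacing, kappa))
        for a in range(dim):
            Pa = pml_fac(a, False)
            psplit[a] = Pa * (Pa * psplit[a]
                              - dt * rho * c * c * _deriv(u[a], a, -0.5, spacing, kappa))
        p = sum(psplit)
        out[:, n_] = map_coordinates(p, coords, order=1, mode="nearest")
    if filter_fc is not None:
        b, a_ = butter(filter_order, filter_fc * 2 * dt, btype="low")
        out = lfilter(b, a_, out, axis=-1)
    return out
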