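"""Image formation: universal backprojection, adjoint image, and the
regularized least-squares inversion.

Three reconstruction routes are provided, in increasing model fidelity:

* :func:`ubp` -- closed-form universal backprojection assuming a homogeneous
  acoustic medium (the aberrated baseline when a skull is present);
* :func:`adjoint_reconstruct` -- the action of the transpose of the full
  elastic measurement operator S.A on the data, equivalent to a single
  unregularized gradient iteration from a zero image;
* :func:`fista_reconstruct` -- the accelerated proximal-gradient solution of

      min_{p0 >= 0}  1/2 ||S A p0 - d||^2 + w_l1 ||p0||_1 + w_tv TV(p0),

  with the step size from power iterations on (SA)^T (SA), a monotone
  safeguard, and an approximate composite proximal map (nonnegative soft
  thresholding followed by dual-gradient-projection isotropic TV denoising).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .elastic import ForwardOperator, PMLConfig
from .media import ElasticMedium, Grid
from .sensing import MeasurementFilter, SensorArray, SensorData


# --------------------------------------------------------------------------
# Configuration / result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconConfig:
    """Iterative reconstruction parameters.

    ``l1_weight`` and ``tv_weight`` multiply the two regularizers on the
    scale of the (possibly normalized) data; ``step_safety`` divides the
    power-iteration Lipschitz estimate; ``nonneg`` enforces the physical
    nonnegativity of the initial pressure.
    """

    l1_weight: float = 0.0
    tv_weight: float = 0.0
    n_outer: int = 10
    n_inner_tv: int = 20
    step_safety: float = 0.9
    power_iters: int = 20
    seed: int = 0
    nonneg: bool = True

    def __post_init__(self):
        if self.l1_weight < 0 or self.tv_weight < 0:
            raise ValueError("regularizer weights must be nonnegative")
        if not np.isfinite(self.l1_weight) or not np.isfinite(self.tv_weight):
            raise ValueError("regularizer weights must be finite")
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")
        if not 0 < self.step_safety <= 1:
            raise ValueError("step_safety must lie in (0, 1]")


@dataclass
class ReconResult:
    p0_hat: np.ndarray
    objective_trace: np.ndarray
    step_size: float
    config: ReconConfig

    def __post_init__(self):
        self.objective_trace = np.asarray(self.objective_trace, dtype=np.float64)
        if not np.all(np.isfinite(self.objective_trace)):
            raise ValueError("objective trace contains non-finite values")


# --------------------------------------------------------------------------
# Universal backprojection
# --------------------------------------------------------------------------

def ubp(data: SensorData, sensors: SensorArray, sos: float, roi: Grid
        ) -> np.ndarray:
    """Universal backprojection onto ``roi`` assuming homogeneous speed.

    Backprojects b(t) = 2 p(t) - 2 t dp/dt along spherical (circular in 2D)
    shells t = |r - r_s| / sos, weighted by the solid angle (arc length in
    2D) each element subtends as seen from the voxel, and normalized by the
    total weight per voxel.  Linear in the data; negative values retained.
    """
    times = data.times
    mesh = roi.coordinate_mesh()
    center = sensors.positions.mean(axis=0)
    dist_max = 0.0
    for pos in sensors.positions:
        dist_max = max(dist_max, max(
            np.linalg.norm(np.array([ext[k] for ext in roi.extent]) - pos)
            for k in (0, 1)))
    tau_max = dist_max / sos
    if tau_max > times[-1]:
        need = int(np.ceil((tau_max - data.t0) / data.dt)) + 1
        raise ValueError(
            f"insufficient time coverage: need N_t >= {need} samples "
            f"(have {data.n_samples})")
    p = data.d
    dpdt = np.gradient(p, data.dt, axis=1)
    b = 2.0 * p - 2.0 * times[None, :] * dpdt
    img = np.zeros(roi.shape)
    wsum = np.zeros(roi.shape)
    dim = roi.dim
    for s in range(sensors.n_channels):
        pos = sensors.positions[s]
        diff = [m - pos[a] for a, m in enumerate(mesh)]
        dist = np.sqrt(sum(d * d for d in diff))
        dist = np.maximum(dist, min(roi.spacing))
        normal = center - pos
        nn = np.linalg.norm(normal)
        normal = normal / nn if nn > 0 else normal
        cos_th = sum(d * normal[a] for a, d in enumerate(diff)) / dist
        w = np.abs(cos_th) / dist ** (dim - 1)
        img += w * np.interp(dist / sos, times, b[s], left=0.0, right=0.0)
        wsum += w
    return img / np.maximum(wsum, np.finfo(float).tiny)


# --------------------------------------------------------------------------
# Adjoint reconstruction
# --------------------------------------------------------------------------

def adjoint_reconstruct(data: SensorData, medium: ElasticMedium,
                        sensors: SensorArray,
                        roi: tuple[slice, ...] | None = None,
                        pml: PMLConfig | None = PMLConfig(),
                        measurement_filter: MeasurementFilter | None = MeasurementFilter(),
                        c_ref: float | None = None) -> np.ndarray:
    """Apply the exact transpose of the measurement operator to the data.

    Equivalent to one unregularized gradient iteration from a zero image (up
    to the step scaling); being linear and regularizer-free it is the probe
    of choice for model-mismatch studies.
    """
    op = ForwardOperator(medium, sensors, data.n_samples, data.dt, pml=pml,
                         roi=roi, measurement_filter=measurement_filter,
                         c_ref=c_ref)
    return op.adjoint(data.d)


# --------------------------------------------------------------------------
# Power iteration
# --------------------------------------------------------------------------

def power_iteration(apply_fn, adjoint_fn, shape, n_iter: int = 20,
                    seed: int = 0) -> float:
    """Largest eigenvalue of (SA)^T (SA) (the squared operator norm).

    Rayleigh quotients of the symmetric composition are monotone
    non-decreasing, so the estimate approaches the true norm from below.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(shape)
    nrm = np.linalg.norm(x)
    if nrm == 0:
        return 0.0
    x /= nrm
    lam = 0.0
    for _ in range(max(1, int(n_iter))):
        y = adjoint_fn(apply_fn(x))
        lam = float(np.vdot(x, y).real)
        nrm = np.linalg.norm(y)
        if nrm == 0:
            warnings.warn("power iteration hit the null space; operator may be zero")
            return 0.0
        x = y / nrm
    return lam


# --------------------------------------------------------------------------
# Proximal maps
# --------------------------------------------------------------------------

def _grad(x):
    """Forward-difference gradient per axis, Neumann (zero at the far edge)."""
    g = []
    for a in range(x.ndim):
        d = np.zeros_like(x)
        sl_hi = [slice(None)] * x.ndim
        sl_lo = [slice(None)] * x.ndim
        sl_hi[a] = slice(1, None)
        sl_lo[a] = slice(None, -1)
        d[tuple(sl_lo)] = x[tuple(sl_hi)] - x[tuple(sl_lo)]
        g.append(d)
    return g


def _div(g):
    """Negative adjoint of :func:`_grad` (discrete divergence).

    The gradient's last entry along each axis is structurally zero, so the
    dual field's last component is ignored there.
    """
    out = np.zeros_like(g[0])
    for a, d in enumerate(g):
        nd = d.ndim

        def sl(spec):
            s = [slice(None)] * nd
            s[a] = spec
            return tuple(s)

        dd = np.zeros_like(d)
        dd[sl(0)] = d[sl(0)]
        dd[sl(slice(1, -1))] = d[sl(slice(1, -1))] - d[sl(slice(0, -2))]
        dd[sl(-1)] = -d[sl(-2)]
        out += dd
    return out


def tv_denoise(y: np.ndarray, weight: float, n_iter: int = 20,
               nonneg: bool = False) -> np.ndarray:
    """Isotropic TV denoising by accelerated dual gradient projection.

    Solves min_x 1/2 ||x - y||^2 + weight TV(x), optionally over x >= 0,
    using the fast gradient projection scheme on the dual with step
    1 / (4 ndim weight), a unit-ball projection of the dual field, and
    gradient-based adaptive restart of the momentum.
    """
    if weight <= 0:
        return np.maximum(y, 0.0) if nonneg else y.copy()
    d = y.ndim
    L = 4.0 * d
    p = [np.zeros_like(y) for _ in range(d)]
    r = [np.zeros_like(y) for _ in range(d)]
    t = 1.0
    x = y.copy()
    for _ in range(max(1, int(n_iter))):
        x = y - weight * _div(r)
        if nonneg:
            np.maximum(x, 0.0, out=x)
        g = _grad(x)
        q = [r[a] - g[a] / (L * weight) for a in range(d)]
        mag = np.sqrt(sum(qa * qa for qa in q))
        denom = np.maximum(mag, 1.0)
        p_new = [qa / denom for qa in q]
        restart = sum(float(np.sum((r[a] - p_new[a]) * (p_new[a] - p[a])))
                      for a in range(d)) > 0
        t_new = 1.0 if restart else (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        r = [p_new[a] + ((t - 1.0) / t_new) * (p_new[a] - p[a]) for a in range(d)]
        p, t = p_new, t_new
    x = y - weight * _div(p)
    if nonneg:
        np.maximum(x, 0.0, out=x)
    return x


def total_variation(x: np.ndarray) -> float:
    """Isotropic TV semi-norm (Euclidean norm of the discrete gradient)."""
    g = _grad(x)
    return float(np.sum(np.sqrt(sum(d * d for d in g))))


def prox_composite(x: np.ndarray, l1_tau: float, tv_tau: float,
                   nonneg: bool = True, n_inner_tv: int = 20) -> np.ndarray:
    """Approximate proximal map of w_l1 |.|_1 + w_tv TV + indicator(x >= 0).

    The exact composite prox has no closed form; soft thresholding (folded
    with the nonnegativity projection) is applied first, then constrained TV
    denoising.  ``l1_tau``/``tv_tau`` are the weights already multiplied by
    the gradient step.
    """
    x = np.asarray(x, dtype=np.float64)
    if l1_tau > 0:
        if nonneg:
            x = np.maximum(x - l1_tau, 0.0)
        else:
            x = np.sign(x) * np.maximum(np.abs(x) - l1_tau, 0.0)
    elif nonneg:
        x = np.maximum(x, 0.0)
    else:
        x = x.copy()
    if tv_tau > 0:
        x = tv_denoise(x, tv_tau, n_iter=n_inner_tv, nonneg=nonneg)
    return x


# --------------------------------------------------------------------------
# Accelerated proximal gradient (monotone FISTA)
# --------------------------------------------------------------------------

def fista_reconstruct(data: SensorData, medium: ElasticMedium,
                      sensors: SensorArray, roi: tuple[slice, ...] | None,
                      config: ReconConfig,
                      pml: PMLConfig | None = PMLConfig(),
                      measurement_filter: MeasurementFilter | None = MeasurementFilter(),
                      c_ref: float | None = None,
                      op: ForwardOperator | None = None,
                      step_size: float | None = None) -> ReconResult:
    """Solve the regularized least-squares problem by monotone FISTA.

    Starts from a zero image; the step size is ``step_safety`` over the
    power-iteration estimate of ||SA||^2 (pass ``step_size`` to reuse a
    previous estimate).  The objective trace (initial value plus one entry
    per outer iteration) is non-increasing by the monotone safeguard.
    """
    if op is None:
        op = ForwardOperator(medium, sensors, data.n_samples, data.dt,
                             pml=pml, roi=roi,
                             measurement_filter=measurement_filter, c_ref=c_ref)
    d = data.d
    if step_size is None:
        L = power_iteration(op.apply, op.adjoint, op.roi_shape,
                            n_iter=config.power_iters, seed=config.seed)
        if L <= 0:
            raise ValueError("operator norm estimate is zero; cannot set a step")
        step = config.step_safety / L
    else:
        step = float(step_size)

    def regularizer(img):
        r = 0.0
        if config.l1_weight > 0:
            r += config.l1_weight * float(np.abs(img).sum())
        if config.tv_weight > 0:
            r += config.tv_weight * total_variation(img)
        return r

    def objective(img, residual):
        return 0.5 * float(np.sum(residual ** 2)) + regularizer(img)

    x = np.zeros(op.roi_shape)
    y = x
    f_x = 0.5 * float(np.sum(d ** 2))
    trace = [f_x]
    t = 1.0
    for _ in range(config.n_outer):
        res_y = op.apply(y) - d
        g = op.adjoint(res_y)
        z = prox_composite(y - step * g, config.l1_weight * step,
                           config.tv_weight * step, nonneg=config.nonneg,
                           n_inner_tv=config.n_inner_tv)
        f_z = objective(z, op.apply(z) - d)
        if f_z <= f_x:
            x_new, f_new = z, f_z
        else:  # monotone safeguard: keep the best iterate
            x_new, f_new = x, f_x
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = x_new + (t / t_new) * (z - x_new) + ((t - 1.0) / t_new) * (x_new - x)
        x, f_x, t = x_new, f_new, t_new
        trace.append(f_x)
        if f_x > 10.0 * trace[0]:
            raise FloatingPointError(
                f"objective diverged ({f_x:.3e} vs initial {trace[0]:.3e}); "
                f"step size {step:.3e} is too large")
    return ReconResult(x, np.asarray(trace), step, config)
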