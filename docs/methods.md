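# Methods

## The problem

Photoacoustic computed tomography (PACT) reconstructs an optically induced
initial pressure distribution p0 from acoustic signals recorded by a
transducer array. Through an adult skull the reconstruction assumption of a
homogeneous acoustic medium fails badly: bone is roughly twice as dense and
fast as soft tissue, and — unlike tissue — it supports shear waves, so
transcranial wavefronts suffer refraction, reverberation, and
compression-to-shear mode conversion. Images formed with the conventional
universal backprojection (UBP) formula are then severely aberrated.

`depact` de-aberrates such images by modeling the skull as a *homogeneous
isotropic elastic* solid whose geometry, position, and orientation come
from an adjunct CT/MR scan registered with fiducial markers, and by solving
a regularized least-squares inverse problem whose forward operator
propagates elastic waves through that model.

## Forward model

The solver integrates the velocity–stress form of the isotropic elastic
wave equation,

    rho ∂t v_i     = ∂j sigma_ij
    ∂t sigma_ij    = lambda delta_ij ∂k v_k + mu (∂i v_j + ∂j v_i)
    sigma_ij(0)    = −p0 delta_ij,   v_i(0) = 0,

with water as the fluid background (mu = 0) and the bone mask carrying the
homogeneous skull triple (rho, cp, cs); Lamé parameters follow from
mu = rho cs², lambda = rho (cp² − 2 cs²).

Discretization choices:

* **Space.** Fourier pseudo-spectral derivatives on grids staggered by half
  a cell between velocity and stress components (staggering applied as a
  spectral phase factor). Differentiation is exact for resolved modes; the
  default spacing of 0.5 mm is one-sixth of the in-water wavelength at the
  0.5 MHz acquisition cutoff.
* **Time.** Explicit leapfrog with velocities at half-integer and stresses
  at integer levels; the first velocity update is a half step. A k-space
  temporal correction sinc(c_ref |k| dt / 2) (reference speed c_ref
  defaulting to the medium maximum) makes propagation in a homogeneous
  medium at c_ref exact in time; the homogeneous-water test agrees with the
  analytic Fourier solution at machine precision. The default operating
  point dt = 50 ns at 0.5 mm gives CFL = 0.28 for cp = 2800 m/s, under the
  configured limit of 0.3.
* **Boundaries.** A split-field perfectly matched layer, 10 cells per side,
  quartic absorption profile, with the peak absorption chosen for a
  theoretical normal-incidence reflection of 1e-4. Measured re-entrant
  amplitude after a boundary interaction is below 1% of the outgoing peak.
* **Medium sampling.** Density is arithmetically averaged to the staggered
  velocity points; lambda and mu are sampled at their native points with no
  effective-medium homogenization — adequate for the homogeneous-skull use
  case this package targets.
* **Precision.** All operator applications run in 64-bit; the adjoint tests
  depend on it.

## The exact discrete adjoint

Iterative reconstruction needs the transpose of the *discrete* forward map,
not a discretization of the continuous adjoint. Each time step is therefore
assembled as a tape of elementary linear operations — diagonal scalings
(PML decay, material coefficients), weighted accumulations, and staggered
spectral derivatives. The adjoint executes the reversed tape with each
primitive transposed, using the identity D_{+1/2}^T = −D_{−1/2} for the
staggered derivative. The measurement side (multilinear interpolation to
the element positions; causal second-order Butterworth low-pass at 0.5 MHz)
is transposed the same way (scatter; time-reversed filtering). The composed
operator passes the dot-product test at ~1e-16 relative, far inside the
1e-9 requirement, for every shipped configuration (elastic or
acoustic-only, with or without the filter).

The measurement filter is applied inside the sampling operator S — to both
the measured data and the model predictions — so the inverse problem is
self-consistent; an acquisition chain that filters only the recorded
signals is equivalent up to that common filter.

## Reconstruction

Three routes, in increasing model fidelity:

1. **UBP** — backprojection of b(t) = 2p − 2t dp/dt over spherical
   (circular) shells with solid-angle (arc-length) weighting and per-voxel
   weight normalization. The delta shell is realized by linear
   interpolation into the time axis. This is the homogeneous-medium
   baseline and, through a skull, the aberrated one.
2. **Adjoint image** — (SA)^T d, one unregularized gradient iteration from
   a zero image. Linear and regularizer-free, hence the probe used for the
   model-mismatch study.
3. **Iterative** — monotone FISTA for
   min_{p0 ≥ 0} ½‖SA p0 − d‖² + w_l1 ‖p0‖₁ + w_tv TV(p0),
   from a zero initial image, step size = 0.9 / L with L estimated by power
   iteration (20 iterations by default; the transcranial fixture uses 10),
   standard two-sequence momentum t_{k+1} = (1 + √(1+4t_k²))/2 with a
   monotone fallback (a step that raises the objective keeps the previous
   iterate), terminated after 10 outer iterations by default.

The composite proximal map has no closed form; it is approximated by
nonnegative soft thresholding followed by isotropic TV denoising under the
nonnegativity constraint. The TV prox uses accelerated dual gradient
projection (step 1/(4·ndim·w), unit-ball projection) with gradient-based
adaptive restart; 20 inner iterations by default. Against the exact 1D
taut-string solution it is accurate to ~1e-8 on generic signals at 200
iterations; degenerate noise-free steps need a few hundred more.

Regularizer weights have no universally right values — they depend on the
noise level, the interference level, and the overall data scale — so each
fixture ships tuned defaults. The standing transcranial fixture (unit-peak
data, 1% noise) uses w_l1 = 1e-3, w_tv = 2e-3.

## Geometry processing

* **Registration.** Kabsch/SVD rigid fit of corresponded fiducial points,
  with the standard det = +1 reflection correction; degenerate (collinear)
  configurations are rejected. Marker-centroid extraction from the
  photoacoustic image of the markers is left to the user (points arrive as
  CSV in meters).
* **Mask extraction.** Otsu threshold by default (numeric override and an
  MR negative-contrast invert flag available), morphological closing (ball
  radius 2), then pore filling that never fills the cranial cavity: among
  enclosed non-bone components the largest is kept fluid, the rest are
  filled.
* **Resampling.** Rigid transforms are applied to masks by nearest-neighbor
  inverse mapping, preserving binarity.

## Synthetic study conditions

All fixtures are generated, not downloaded. The standing 2D fixture is a
scaled-down cross-section of the instrument that preserves its proportions:
the real system pairs a 13 cm-radius hemispherical array with a ~8 cm
skull; the fixture pairs a 40 mm-radius, 256-element circular array with an
elliptical bone shell of outer extent ~25 mm (ratio ~0.62) and 6.5 mm wall,
carrying the first-skull triple (1850 kg/m³, 2800 m/s, 1250 m/s) in water
at 20 °C, on a 192² grid at 0.5 mm. The shell is mildly elliptical (axis
ratio 0.85) so that orientation perturbations are geometrically meaningful.
The phantom is a union of 1.5 mm random-walk tubes placed close to the
inner shell surface — the cortical-vessel placement of the experimental
design, and the regime where oblique incidence makes shear conversion
matter — clipped to the fluid cavity with 1 mm clearance. Data are sampled
at dt = 50 ns over 1100 samples, low-pass filtered at 0.5 MHz, normalized
to unit peak, with 1% additive white Gaussian noise (single-shot
acquisition; no averaging). An optional skull-background component (a
smoothed nonnegative random texture on the shell propagated through the
same forward model, scaled to a chosen RMS ratio) emulates the
external-illumination interference.

On this fixture the through-skull UBP image correlates with the ground
truth at CC ≈ 0.2, the iterative elastic reconstruction at CC ≈ 0.97 — the
same qualitative de-aberration the experimental study reports at full
scale. Because data are simulated by the same discrete operator used in
inversion (an inverse crime in the strict sense), these numbers demonstrate
operator consistency and solver correctness, not experimental performance:
real skulls add heterogeneity, dispersion, frequency-dependent attenuation,
element directivity, and registration error that the fixture does not
contain.

## Model-mismatch study

The sensitivity protocol perturbs the skull model used in the adjoint
reconstruction while the data stay fixed: ±10% compression and shear
speeds, ±10° rotation, a 1 cm translation, and an acoustic-only variant
(shear support removed). Image quality is scored by sliding correlation
(the maximum of the zero-mean normalized cross-correlation over ±5-voxel
shifts), which discounts the bulk displacement a geometric perturbation
induces. On the fixture the correct elastic model ranks best; speed and
rotation perturbations degrade mildly; shear-speed errors degrade more than
equal compression-speed errors; and the acoustic-only model falls below all
speed/rotation variants.

One clause does not transfer to desk scale: a fixed 1 cm shift of a ~25 mm
skull displaces the wall by ~40% of its size (versus ~13% for a real head),
so on the fixture the shifted-elastic variant scores slightly below the
acoustic-only one (sliding CC 0.770 vs 0.794, against 0.875 for the correct
model). The corresponding assertion in the acceptance suite is left
failing rather than rescaled; the effect shrank monotonically as the
fixture was brought toward the instrument's proportions.

## Numerical edge cases

* Thresholding that yields an all-bone or all-fluid mask, fiducial sets
  with rank-deficient covariance, sensors outside the usable (non-PML)
  region, cutoffs at or above Nyquist, and insufficient time coverage for
  backprojection all raise named errors.
* The solver aborts with a diagnostic when fields grow by more than 1e6×
  (e.g., a time step violating the CFL bound with a low reference speed).
* `check_stability` returns the CFL number and warns above 0.3; the +10%
  compression-speed perturbation intentionally sits at 0.308 and only
  warns, matching how the sensitivity study reuses the nominal step.
* Unstaggered spectral derivatives zero the Nyquist mode to keep the
  circulant kernel antisymmetric; staggered ones need no special casing.

## Problem sizes

The suite and the acceptance script run 2D scenes: 64² for operator
algebra, 128² for fluid-limit/localization physics, 192² × 1100 steps for
the transcranial fixture (the package's own choice of a desk-scale study;
the full 3D experimental scale is supported in principle by the
dimension-generic code but is a GPU-class computation). A 64³ smoke path
exercises the 3D branches through the unit tests of the geometry and
sampling modules.

## Known limitations

* Homogeneous skull only: no HU-derived property maps, no dispersion or
  frequency-dependent attenuation, no viscoelasticity or anisotropy.
* Idealized point detectors: no element directivity or impulse response.
* The composite prox is approximate (L1 then TV); with the shipped inner
  iteration counts the induced objective error is well below the data
  term's scale, and the monotone safeguard keeps the trace non-increasing
  regardless.
* UBP weighting uses uniform element areas with cos-theta obliquity; for
  the canonical full-view arrays used here this affects amplitude shading
  only, not peak localization.
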