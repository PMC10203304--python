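# Methods

## The shell-inversion model

Microsensor transects through a spherical aggregate record one radius
of a (assumed) spherically symmetric concentration field. At steady
state the net volumetric conversion rate Q(r) and the diffusive flux
are linked by conservation: the transport through a spherical interface
of radius r is

    F(r) = −D · dC/dr · 4π r²,

and the net rate of the shell between two interfaces is the flux
divergence F(r_outer) − F(r_inner). The package discretizes this with
one shell per measurement point and interfaces at the midpoints between
adjacent measurement radii (a staggered grid). Two properties follow:

1. **Exactness on quadratics.** The two-point difference between
   adjacent measurements is the exact derivative at their midpoint for
   any locally quadratic C(r). The steady field of a uniform zero-order
   sink, C(r) = C_R − q(R²−r²)/(6D), is globally quadratic, so the
   inversion recovers −q in every shell and −q·(4/3)πR³ in total to
   rounding error. This is the primary analytic verification.
2. **Telescoping conservation.** Summing the per-shell divergences
   cancels every interior flux, so the whole-granule total equals the
   surface flux identically, for any profile, noisy or not. The prose
   description of "adding activities in all shells" is only consistent
   with mass conservation under this divergence reading, which is why
   it is implemented this way.

The flux at the surface interface (r = R) has no measurement pair
centred on it; its gradient is obtained by linear extrapolation of the
two outermost midpoint gradients. dC/dr is linear in r for any
quadratic C, so the extrapolation preserves property 1, and it is the
reason the inversion requires at least three in-granule points. At the
centre the flux is identically zero by symmetry. Profiles that stop
short of the centre are inverted under the same zero-flux assumption —
the unmeasured core is then implicitly assigned zero net rate — and the
result carries a `truncated` flag plus a warning, because the
volumetric rate of the deepest shell is averaged over a volume that
includes unmeasured material. Points above the surface (z < 0, in the
diffusive boundary layer) are retained in the data model but excluded
from inversion; the governing balance applies only inside the
aggregate.

Sign convention throughout: positive = production (outward transport at
the surface), negative = consumption. A concentration falling toward
the interior therefore yields an inward (negative) interface flux.

No smoothing is applied by default; an optional Savitzky–Golay
pre-smoother (window and polynomial order recorded in the output
metadata) is available for noisy LIX nitrate profiles, whose
point-to-point noise is differenced twice by the inversion and can
dominate per-shell rates.

## Time-series estimators

All fitted rates are ordinary least squares **with intercept** — vial
blanks at timepoint 0 need not be exactly zero — and report the
standard error of the slope; on noiseless linear inputs slope is exact
and stderr is 0.

- **Dark shift.** Immediately after darkening, photosynthesis stops
  while respiration continues at its (balanced) steady rate, so
  dC/dt(0⁺) = −P_gross at every depth. The estimator fits the 0–5 s
  window by default (configurable up to the 5–10 s shift duration);
  longer windows increasingly underestimate P_gross as diffusion
  relaxes the field. An increasing O₂ trace returns a negative rate
  with a warning flag, not an error.
- **¹⁵N vials.** Total excess ¹⁵N = excess ²⁹N₂ + 2·excess ³⁰N₂.
  Denitrification is the slope of that total versus time;
  nitrification is the slope of (total excess ¹⁵N + NOₓ), i.e.
  extracellular NOₓ accumulation plus the labelled N₂ already produced
  from it, so nitrified N passed on to denitrification is not lost from
  the budget. With 4 timepoints the 95 % confidence interval uses the
  t distribution with 2 degrees of freedom (±2·stderr would cover only
  ~82 %). NOₓ measured as a concentration is converted to a vial
  amount with `nox_amount_nmol` (vial volume minus headspace, both
  required inputs rather than hard-coded vial hardware).
- **Calibration.** Two-point linear for amperometric O₂ sensors
  (passes exactly through both standards); Nernstian
  signal = a·log₁₀(C) + b for potentiometric LIX nitrate sensors,
  inverted monotonically. Non-monotone standards are rejected.
- **Light.** Relative scalar irradiance is averaged over the requested
  band and fit log-linearly to I(z) = e^(−kz); z_p = −ln(p)/k (default
  p = 0.1, the 90 %-absorption depth). Wavelengths whose sub-surface
  irradiance exceeds the surface value — pigment fluorescence or
  scattering, typically 700–800 nm — are excluded from the fit and
  reported separately. A flat field returns k = 0 with z_p flagged
  undefined.
- **Radiographs.** counts × conversion / (area × thickness × duration),
  with optional killed-control blank subtraction. The count-to-mol
  conversion must be supplied by the caller: it depends on the tracer
  specific activity and imager efficiency, which are not properties of
  this package.
- **Reactor scaling** is a parameterized helper
  (nmol h⁻¹ granule⁻¹ × granules L⁻¹ → mmol L⁻¹ d⁻¹); the granule
  number density is an input, not a constant.

## The forward simulator

Zero-order (concentration-independent) kinetics within concentric
layers were chosen deliberately: the inversion itself is kinetics-free,
and zero-order admits closed-form cross-checks — the uniform-sink
parabola above and the anoxic-shell solution
C(r) = (q/6D)(r² + 2a³/r − 3a²) whose front radius a solves C(R) = C_R.
Monod kinetics would add parameters the profile data cannot constrain
and is left as an extension hook. Layers superpose linearly, so a
light-dependent production layer can overlap a respiration layer —
exactly the configuration the dark-shift method assumes.

The steady solver is a conservative finite-volume scheme on a uniform
radial grid (default 5 µm) with exact piecewise integration of the
layer sources, a symmetry (zero-flux) condition at r = 0 and either a
fixed bulk concentration at r = R (default — profiles are measured
from stirred bulk water) or a boundary-layer mass-transfer
coefficient. Non-negativity is enforced as an obstacle problem: nodes
are pinned at C = 0 where the unconstrained solution would go
negative and released where the residual (the net would-be source)
turns positive, locating the oxic–anoxic front to within one grid
cell. Discrete flux balance — surface flux = ∫Q over the oxic region —
holds to solver precision by construction; against analytic solutions
the field is accurate to <0.1 % at 5 µm spacing and the half-cell
source correction keeps the reported surface flux second-order
accurate.

The dark-shift transient integrates the same spatial operator with
light-dependent layers switched off (method of lines, BDF, tridiagonal
Jacobian) from the illuminated steady state. It is a linear ODE
system; scenarios are expected to keep oxygen positive over the
simulated 10–60 s, which all shipped scenarios do.

Stochastic generators draw from a single seeded `default_rng` per
artifact. `sample_profile` interpolates the fine-grid field at the
measurement depths, adds Gaussian noise, clips at zero, and attaches
ground-truth shell rates integrated exactly (including the front
masking) on the sampling grid. The isotope generator accumulates
total ¹⁵N–N₂ at denitrification × F and splits it ²⁹N₂:³⁰N₂ as
2F(1−F):F² by random isotope pairing — an explicit modelling
assumption, since real pairing ratios are measured, not derived; with
F = 1 all excess appears as ³⁰N₂ and the nitrification estimator's
NOₓ + ¹⁵N sum recovers the true rate. NOₓ accumulates at
(nitrification − denitrification).

## Study conditions used in tests and the acceptance script

Scenario values mirror the system the package targets: granule radius
1800 µm (2–4 mm granules), bulk O₂ 250 µmol L⁻¹ (air-saturated,
slightly supersaturated water), D(O₂) 2000 and D(NO₃⁻) 1700 µm² s⁻¹,
activity concentrated in the outer ~500 µm, attenuation
k = ln(10)/600 µm⁻¹ (90 % of light absorbed within 600 µm), vial
timepoints 0, 2, 4.5, 5.5 h, and photosynthesis probed at depths
200–400 µm where it peaks. The dark-shift verification probes depths
250–350 µm, at least 250 µm from both photic-layer boundaries: within
a 5 s window diffusion smears rate discontinuities over
√(4Dt) ≈ 200 µm, so probes closer to a boundary measure a genuinely
attenuated decline — a physical limit of the light–dark-shift method,
not of the estimator. Isotope calibration uses nitrification 30 and
denitrification 10 nmol h⁻¹ with σ = 10 % of the final excess amount
over 200 seeded replicates. Problem sizes (5 µm grids, 100 random
profiles, 200 vials) keep the whole acceptance run under a few seconds
while leaving every check's resolution limited by the method, not the
budget.

## What the synthetic data does and does not show

The generator reproduces the features the estimators rely on:
spherical diffusion geometry, layered zero-order activity, anoxic
cores, exponential light fields, linear tracer accumulation, additive
Gaussian sensor noise. It does not emulate sensor drift, the
analyte consumption of the sensor itself, granule asymmetry or surface
roughness, the diffusive boundary layer's effect on near-surface
gradients (unless a mass-transfer coefficient is supplied), Monod
kinetics, light-driven rate feedback, or coupled O₂/NOₓ/carbon
stoichiometry. Passing round-trip tests therefore demonstrate
correctness of the numerics and estimators under the stated model, not
robustness to those real-world effects; on real profiles the dominant
additional uncertainties are positioning of the surface (z = 0) and
deviation from spherical symmetry.

## Numerical choices and degenerate inputs

- Internal units µm, s, nmol; 1 µmol L⁻¹ = 10⁻¹² nmol µm⁻³ is the only
  unit bridge (rates reported per hour, ×3600).
- Shell grids accept a single point (whole-sphere shell) for geometry
  work; inversion demands ≥3 in-granule points (two pair gradients are
  the minimum for the surface extrapolation).
- Duplicate depths, non-finite values, depths beyond R, and negative
  concentrations are rejected with messages naming the offender;
  boundary-layer rows are flagged, never silently dropped.
- The obstacle iteration caps at 100 active-set updates and reports the
  last pinned bracket on failure; cycles collapse to the more
  conservative (pinned) set.
- Fits with a perfect line return stderr exactly 0 (scipy's linregress
  residual is zero); non-finite stderr (n = 2 exact fits) is reported
  as 0.
- CSV writers use 15 significant digits; manifests contain no
  timestamps, so repeated runs are byte-identical.
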