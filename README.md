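# photogranule

Functional-rate analysis for spherical phototrophic granules
("photogranules") — the dense, self-aggregated communities of
filamentous cyanobacteria, algae and heterotrophic bacteria used for
aeration-free wastewater treatment. The package turns raw microsensor
and incubation data into the quantities a microbial ecophysiologist
actually wants: where in the granule oxygen and nitrate are produced or
consumed, how fast, and how those rates scale to a reactor.

## What it computes

**Shell inversion of microsensor profiles.** A radial concentration
profile C(z) (depth z from the surface, r = R − z) is segregated into
concentric shells, one per measurement point, with interfaces at the
midpoints between adjacent measurement radii. The diffusive transport
through each interface follows Fick's first law scaled by the spherical
interface area,

    F(r) = −D · dC/dr · 4π r²       [nmol h⁻¹, positive = outward]

with the gradient taken as the two-point difference between the
adjacent measurements (the exact midpoint derivative for locally
quadratic profiles) and the surface gradient linearly extrapolated from
the two outermost pairs. Each shell's net conversion rate is the flux
divergence F(outer) − F(inner), so production is positive, consumption
negative, and the sum over shells telescopes exactly to the surface
flux — mass conservation is built in, not approximate. Defaults:
D(O₂) = 2000 µm² s⁻¹, D(NO₃⁻) = 1700 µm² s⁻¹.

**Time-series estimators.** Gross photosynthesis from light–dark
shifts (the initial O₂ decline after darkening, OLS slope over a
0–5 s window); denitrification as the slope of total excess ¹⁵N
(= excess ²⁹N₂ + 2 × excess ³⁰N₂) in closed vials; nitrification as the
slope of (excess ¹⁵N + NOₓ); two-point linear and Nernstian log-linear
sensor calibrations; band-averaged scalar-irradiance attenuation
I(z) = e^(−kz) with automatic exclusion of >100 % scattering/
fluorescence bands; and volumetric normalization of ¹⁴C microradiograph
counts. All slopes come with the standard error of the fit.

**A reaction–diffusion oracle.** A finite-volume solver for
(1/r²) d/dr(r² D dC/dr) = −Q(r) with zero-order layered sources/sinks
and a hard non-negativity constraint (an obstacle problem: consumption
shuts off where oxygen is exhausted, producing an anoxic core with a
sharp oxic–anoxic front), plus a method-of-lines transient for
dark-shift simulation. It generates every synthetic input with known
ground truth, so each estimator is verified by a full
forward-simulate → invert round trip.

## Worked example

Simulate a granule (R = 1800 µm) with a photosynthetic layer in the
outer 500 µm and a respiring interior, sample it every 100 µm like a
microsensor would, and invert the profile:

```python
import numpy as np
from photogranule import GranuleGeometry, invert_profile
from photogranule.simulate import (
    GranuleScenario, Layer, solve_steady_state, sample_profile,
)

geometry = GranuleGeometry(1800.0)
scenario = GranuleScenario(
    geometry=geometry,
    layers=(
        Layer(1300.0, 1800.0, 0.2, "production"),   # photic shell
        Layer(0.0, 600.0, 0.1, "consumption"),      # respiring core
    ),
    bulk_umol_per_l=250.0,
)
field = solve_steady_state(scenario, grid_spacing_um=5.0)
sim = sample_profile(field, np.arange(0.0, 1801.0, 100.0))
rates = invert_profile(sim.profile, geometry, 2000.0)
print(rates.to_frame().head(6).to_string(index=False))
print(f"total: {rates.total_rate_nmol_per_h:.1f} nmol/h "
      f"(surface flux {rates.surface_flux_nmol_per_h:.1f} nmol/h)")
```

```
 shell_index  r_inner_um  r_outer_um  net_rate_nmol_per_h  volumetric_rate_nmol_per_mm3_per_h
           0      1750.0      1800.0             1.482197                            0.748688
           1      1650.0      1750.0             2.616273                            0.720195
           2      1550.0      1650.0             2.317837                            0.720264
           3      1450.0      1550.0             2.037538                            0.720365
           4      1350.0      1450.0             1.775390                            0.720515
           5      1250.0      1350.0             0.785316                            0.369601
total: 10.7 nmol/h (surface flux 10.7 nmol/h)
```

The imposed production of 0.2 µmol L⁻¹ s⁻¹ equals 0.72 nmol mm⁻³ h⁻¹ —
the inversion recovers it shell by shell inside the photic layer
(shell 5 straddles the layer boundary, hence the intermediate value),
and the granule total equals the simulated surface efflux exactly.

The same operations are available from the shell:

```
photogranule simulate --seed 7 --out fixtures/
photogranule invert fixtures/profile.csv --radius-um 1800 --out results/
photogranule n15 fixtures/isotope.csv --out results/
```

Every run writes a `manifest.json` sufficient to reproduce it.

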