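# Methods

## Scope and assumptions

All budgets are steady state: the unloading zone is treated as a fixed
geometry through which a constant volumetric flow Q and solute flux I = Q·c
must pass. Flow in pores of 10–100 nm radius at µm/s velocities has
Reynolds numbers around 10⁻⁶, so inertia is neglected everywhere and each
channel is a linear hydraulic resistor. Only the PSE–PPP plasmodesmata are
assigned unloading flux; PDs toward companion cells and metaphloem sieve
elements are counted in the census but carry none, reflecting the
observation that those interfaces play little direct role in unloading.
Sieve-plate resistance, electro-osmosis and whole-plant pressure-flow
networks are out of scope.

## Pore hydraulics

**Simple PD.** A concentric annulus: desmotubule radius rᵢ = 7.5 nm, outer
wall radius rₒ = rᵢ + sleeve width = 10.3 nm, length L = 500 nm (the cell
wall thickness). The default model is the exact annular Poiseuille
solution, R = 8µL/(πk) with k = rₒ⁴ − rᵢ⁴ − (rₒ² − rᵢ²)²/ln(rₒ/rᵢ). A
planar thin-slit approximation (R = 12µL/wh³, w the mean circumference) is
available behind the `annulus_model: slit` flag; for this geometry the two
agree to a few percent, so the choice is not load-bearing.

**Funnel PD.** The outer wall tapers linearly from the mouth radius
(75 nm default) at the sieve-element face to the simple-PD radius at the
pericycle face — the minimal profile consistent with conical electron
micrographs, since only the endpoint apertures are measured. Resistance is
computed in the lubrication approximation as a series integral of the
local cross-sectional resistance (adaptive quadrature, relative tolerance
10⁻¹⁰; the closed-form open-cone resistance
(8µL/3π)(r₁² + r₁r₂ + r₂²)/(r₁³r₂³) anchors the integrator in the tests).
Entrance/Sampson corrections are not applied; at the pore aspect ratios
involved (L/r ≳ 7 at the mouth) the lubrication error is small compared to
the desmotubule-placement uncertainty, which is handled explicitly.

**Desmotubule placement extremes.** Where the desmotubule sits inside a
funnel is not observable in the reconstructions, so the model brackets it:

* `full_span` — the desmotubule runs the entire length; every
  cross-section is annular. This is the high-resistance extreme and gives
  0.175 MPa for the base mixed population.
* `neck_only` — the desmotubule obstructs only the last `neck_fraction` of
  the length; the rest is an open cone. A fully open cone would give
  0.011 MPa, below the reported favourable extreme, so `neck_fraction` is
  the one calibrated parameter of the hydraulic model: its default
  (0.00530, an obstructed neck of ~2.7 nm) is set so that the favourable
  extreme of the base mixed population requires exactly 0.05 MPa. The
  favourable extreme is therefore "essentially unobstructed", and the
  two extremes together span the quoted 0.05–0.2 MPa band.

**Population arithmetic.** Parallel PDs share the pressure differential;
flow partitions by conductance (never equal per-pore flow), so
ΔP = Q/Σ(nᵢ/Rᵢ). The base populations at the PSE–PPP interface come from
the census: 527 total PDs × 45.3% ⇒ ~240 at this interface (nearest ten;
nearest integer 239), of which 10% are simple ⇒ 24 simple + 216 funnel in
the mixed scenario.

## Diffusion and coupling

Per-PD diffusive permeability is P = D_eff·A/L for a uniform channel and
[∫dx/(D_eff·A(x))]⁻¹ along a taper. The effective diffusivity is
D_eff = H·D with hindrance H configurable in (0, 1]; the default H = 1
applies no steric/hydrodynamic hindrance, because the unhindered
calculation already reproduces the reported diffusive requirement (see
calibration below) and any H < 1 would overshoot it. The diffusive
scenario uses the `full_span` placement — the conservative choice, and the
only one consistent with the reported 276 mM (the open-cone placement
would give ~213 mM).

Convection and diffusion couple through the Patlak expression
I = Q(c_up − c_down·e^(−Pe))/(1 − e^(−Pe)), Pe = Q/P per pore, evaluated
with `expm1` and switched to its second-order series
P(c_up − c_down) + Q(c_up + c_down)/2 below Pe = 10⁻⁸ to avoid
cancellation. It advects a uniform solution exactly (I = Qc) and reduces
to the pure-diffusion and pure-advection limits. Osmotic equivalences use
van 't Hoff, Δπ = RTΔc, with scipy's gas constant.

## Parameters, units and defaults

Lengths are stated in the units the measurements use (nm for pores, µm for
tubes) and converted to SI internally; all returned quantities are SI.

| parameter | default | status |
|---|---|---|
| tube diameter d | 3.6 µm | measured (±0.44, n=11) |
| plateau velocity u | 22.6 µm/s | measured (±5.1, n=11) |
| unloading-zone length | 350 µm | measured |
| desmotubule diameter | 15 nm | measured |
| sleeve width | 2.8 nm | measured (GFP hydrodynamic radius) |
| wall thickness L | 500 nm | measured |
| funnel mouth | 150 nm | measured (up to 300 nm) |
| census | 527 ± 58; 45.3/40.8/13.9% | measured (n=4) |
| sap concentration c | 500 mol/m³ | literature consensus |
| membrane Lp | 10⁻¹⁴–10⁻¹² m/s/Pa | literature range |
| viscosity µ | 1.740·10⁻³ Pa·s | **calibrated** (see below) |
| sucrose diffusivity D | 5.2·10⁻¹⁰ m²/s | literature (25 °C) |
| temperature T | 298 K | assumed |
| hindrance H | 1 | assumed |
| neck_fraction | 0.00530 | **calibrated** (see below) |

**Calibration.** Two defaults are fixed by requiring the base scenario to
reproduce reported scenario outputs rather than taken from independent
measurement: the sap viscosity (so 240 simple PDs at 230 fl/s require
8.14 MPa; the value sits inside the accepted range for ~500 mM sucrose sap
at 20–25 °C) and the `neck_only` neck fraction (so the favourable
desmotubule extreme requires 0.05 MPa). Every run flags these, together
with D, T and H, as assumptions in its log, exactly once each. With these
defaults the unhindered diffusive requirement evaluates to 274 mM against
the quoted 276 mM (0.6% apart, within the uncertainty of the printed
inputs); D and H were deliberately left at their literature/neutral values
rather than tuned to close that gap.

## Leaky-tube model and fitting

Positions are µm basipetal of PSE zero (the terminal sieve element). The
default leak law is a uniform volumetric leak per unit length, giving a
piecewise-linear velocity: plateau u₀ basipetal of `zone_start`, linear
decline to zero at the apical zone end (`zone_start − zone_length`, at or
before PSE zero — the tube terminates, so all remaining flow unloads). A
pressure-proportional (exponential-decay) law is available behind the
`leak_law` flag. The tube cross-section is constant, so mass conservation
ties the cumulative lateral efflux to the axial velocity drop identically,
for any leak law in this family.

Fitting is profiled least squares: for fixed breakpoints the plateau has
the closed-form solution u₀ = Σφy/Σφ² (φ the unit ramp), so only the two
breakpoints are searched — a grid over the data positions followed by a
Nelder-Mead polish; ties break toward the smaller `zone_start`. A profile
whose piecewise fit is no better than a constant is returned with
`zone_length = 0` and a degeneracy flag instead of a spurious zone.
Confidence intervals are percentile bootstrap over residual resampling
(200 replicates by default, seeded). On noise-free model data the fitter
recovers parameters to machine-level accuracy; under the synthetic noise
model (σ = 2 µm/s, 30 stations over 700 µm) the median `zone_start` error
across 100 seeds is well under 10%.

## Synthetic data: what it does and does not emulate

Generators draw from seeded numpy PCG64 streams and are pure functions of
(spec, seed). Scalar measurement sets are Normal(mean, sd) clipped at zero
(clipping, not resampling, so the draw count is preserved; at all default
regimes < 1% of draws are affected). Censuses draw a rounded
zero-truncated-normal total and allocate it multinomially across the three
interfaces, so per-draw counts always sum to the total. Velocity profiles
are the model curve plus i.i.d. Gaussian noise clipped at zero.

These fixtures reproduce the *statistical summaries* the analysis consumes
(means, SDs, fractions, noise level) — they do not emulate serial-section
segmentation error, FRAP bleach-front kinetics, spatially correlated
velocity noise, or between-root variance structure. Passing tests
demonstrate that the estimators recover known parameters under the assumed
error model, not that the error model matches real roots.

## Numerical choices and edge cases

* Quadrature: `scipy.integrate.quad`, relative tolerance 10⁻¹⁰, with the
  desmotubule endpoint passed as an explicit breakpoint in `neck_only`
  mode.
* Degenerate funnel (mouth = neck) reduces to the simple PD to 10⁻⁶
  relative; zero flow yields zero requirements everywhere; zero
  diffusivity yields zero permeability rather than a failed integral.
* Census counts round to nearest integer per interface (the PSE–PPP count
  is also reported to the nearest ten, the resolution it is conventionally
  quoted at); the three counts always sum to within one of the total.
* Reports are timestamp-free and fully determined by the resolved
  configuration, which is echoed alongside them, so a re-run from the echo
  is byte-identical.

## Known limitations

* The desmotubule-placement bracket, not a measured position, drives the
  factor-of-3.5 spread in the funnel bulk-flow requirement.
* The linear taper and lubrication approximation are untested against a
  full Stokes solution of the actual funnel shapes; wide-mouth corrections
  would lower the funnel resistances slightly, well inside the placement
  bracket.
* Hindrance H = 1 ignores steric exclusion of sucrose in the 2.8 nm
  sleeve; a sub-unity H would raise the diffusive requirement
  proportionally.
* The leaky-tube fit assumes a shared plateau and a single contiguous
  zone; overlapping transfer/unloading zones or per-file variability are
  not modelled.
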