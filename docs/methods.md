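# Methods

## The lumped energy balance

The package models one irradiated cuvette as a single thermal node:

    ΣmC · dT/dt = Q(t) − hA·(T − T_surr)

where `Q(t) = I·(1 − 10^(−A₈₀₈))·η + Q_s` while the laser is on and 0
while it is off.  The assumptions behind this are the usual ones for a
small stirred sample: spatially uniform temperature (Biot number ≪ 1),
a single Newtonian loss term `hA·ΔT` absorbing convection, conduction and
radiation into one coefficient, and constant optical properties during a
run.  Only the product hA is identifiable from temperature data; the
package never attempts to separate the heat-transfer coefficient from the
surface area.

Because Q is piecewise constant, each segment solves exactly:
`T(t) = T∞ + (T₀ − T∞)·e^(−Δt/τ)` with `T∞ = T_surr + Q/hA` and
`τ = ΣmC/hA`.  The simulator stitches these closed forms across segment
boundaries, so its output is exact to rounding; a generic numeric ODE
integrator appears only as an independent cross-check in the tests and
the acceptance script (agreement ≤ 1e-6 K on four-cycle protocols).

Solvent heating `Q_s` is gated by the laser: it represents light absorbed
by the solvent, so it vanishes the moment the laser turns off.  Power 0
in a protocol segment therefore encodes "laser off" and contributes no
heat at all.

### Units and conventions

Temperatures are stored in °C, temperature *differences* in K, times in
seconds, powers in watts.  Laser instruments report power density
(W/cm²); the config carries an illuminated-area field `beam_area_cm2`
(default 1 cm²) and converts once, because the balance needs watts.
Initial temperature defaults to ambient but can be overridden.

## Inverse estimation of τ, hA, η

The estimator follows the standard cooling-curve procedure:

1. **Plateau rule.**  ΔT_max is the mean of the last k = 3 samples of
   the laser-on window minus ambient, not the single maximum sample —
   a single max is biased upward by noise.  If the window holds fewer
   than k samples the maximum is used with a warning.
2. **θ series.**  Cooling samples are mapped to
   θ = (T − T_surr)/(T_max − T_surr).  Points with θ ≤ 0.05 are dropped
   (the variance of −ln θ diverges as T approaches ambient); points with
   θ > 1 (above the assumed maximum, e.g. the laser-off sample itself
   when the plateau mean sits slightly below it) are dropped and counted.
   The floor is configurable.
3. **Time-constant fit.**  OLS of time against −ln θ; the slope is τ.
   The default fit includes an intercept, which absorbs any offset in the
   laser-off timestamp; a through-origin mode matches the textbook line.
4. **hA = ΣmC/τ**, then
   **η = hA·(ΔT_max,mix − ΔT_max,H₂O)/(I·(1 − 10^(−A₈₀₈)))**, with the
   water reference measured from its own trace under the identical
   protocol (not assumed zero).

η estimates outside [0, 1] are *returned and flagged*, not rejected:
measurement noise can legitimately push a point estimate past a physical
bound, and silently clamping would bias averages.  Ambient temperature is
taken from config or the first sample, never from the trace tail, because
a 10-minute cooling window need not reach ambient.

### Finite-irradiation bias of the plateau rule

With a 600-s heating window and τ = 120 s the last three 60-s samples sit
at 4–5 τ, so the plateau mean underestimates the true steady-state rise
by ≈ 1.2%.  Both sample and water plateaus shrink by the same factor, so
η inherits the ≈ 1.2% underestimate while τ and hA are unaffected (a
uniform rescaling of θ only shifts the fit's intercept).  This is a
property of the estimation procedure at finite irradiation time, not of
the implementation; the round-trip accuracy checks therefore heat for
≥ 8 τ (bias < 0.1%), while the noise-recovery study deliberately keeps
the realistic 600 s on / 600 s off protocol and absorbs the small bias
inside its error budget.

## Dye loading

Loading is quantified through a linear calibration `A = slope·c +
intercept` fitted by OLS to standard solutions (intercept included —
instrument baselines are real; a through-origin mode exists).  Inversion
clamps negative implied concentrations to zero and warns outside the
calibrated range.  Two modes: `indirect` (supernatant absorbance; loaded
= fed − supernatant mass) and `direct` (particle absorbance; loaded =
measured mass); the mode is an explicit field because either measurement
is common.  DLC uses carrier + loaded dye as its denominator — the mass
of the final dye-loaded particles — which is the only reading consistent
with the worked pairs the package reproduces (0.66/1.66 → 39.8%,
0.46/1.46 → 31.5%).  Percentages are reported at 1 decimal place; full
precision is kept internally.

## Photostability cycling

Cycle boundaries come from the protocol's known on/off times (an
inference from the signal would add failure modes the controlled
experiment does not have).  The per-cycle peak is the *maximum sample* of
the heating window — deliberately not the plateau mean, since the decay
metric is defined on the highest temperature reached.  The headline
metric is first-cycle peak minus last-cycle peak (positive =
degradation); whether a trend fit would be preferable is moot for 4-cycle
runs.  Power-series summaries reuse the plateau rule and flag
monotonicity violations rather than failing.

## Bioassay summaries

Viability is 100·A_sample/A_control with optional blank subtraction;
values above 120% are flagged as likely proliferation or pipetting error.
RTV is defined as V(day)/V(day 0) per animal — the common convention,
stated here explicitly as an assumption — and summarized as group mean ±
sd per day.  Tumor-volume caliper formulas are out of scope; volumes are
inputs.

## Synthetic data

The generators exist so every stage is testable with no instrument data:

* **Traces** — the exact forward model plus iid Gaussian noise
  (σ default 0.2 K, typical thermal-imager precision) at 60-s sampling,
  the logging rate of the emulated imager.  Optional photobleaching
  multiplies η by (1 − b) per completed on/off cycle — a geometric decay,
  the simplest phenomenology reproducing a monotone per-cycle peak loss;
  it is not a mechanistic claim.  Ground truth (per-cycle η, hA, τ, the
  noiseless trace) is returned alongside.
* **Calibration points** — a line plus Gaussian absorbance noise.
* **Viability plates** — control·viability/100 plus noise, replicated.

All generators are pure functions of their spec including the seed
(bitwise-reproducible).  They do *not* emulate imager drift,
autocorrelated noise, or convective transients, so passing recovery
studies demonstrate well-posedness of the estimators under iid noise at
the experimental sampling rate — not robustness to structured sensor
artifacts.

The shipped demo scenario (`icg_demo_scenario`) uses ΣmC = 4.18 J/K
(≈ 1 mL water), τ = 120 s (plateau within the 600-s window, cooled back
to ≈ ambient within the 600-s off window), I = 2.5 W (2.5 W/cm² × 1 cm²)
and η = 0.76; the absorbance (≈ 0.450) is *solved* from the target
steady-state rises of 35.7 K (sample, 26.3 → 62 °C) and 0.5 K (water,
26.3 → 26.8 °C) rather than hard-coded, so the printed endpoints are a
consequence of the physics, not assertions.

## Numerical choices and degenerate inputs

* Time-constant and calibration fits refuse inputs with zero predictor
  variance (`DegenerateFitError`) and fewer than 3 points
  (`InsufficientDataError`); a non-positive fitted τ is an error, not a
  value.
* R² is clamped to [0, 1] against floating-point spill.
* Mass-balance violations: indirect-mode loaded < 0 clamps to zero with
  a warning (supernatant noise); direct-mode loaded > fed is an error
  (physically impossible, indicates a calibration or dilution mistake).
* CSV parsing enforces one strict dialect (comma, "." decimal, UTF-8,
  required headers) and reports file name and row number on every
  failure.

## Problem sizes

The recovery studies use 100 seeds for η (600-s cooling window, 11
samples) and calibration slopes, 40 seeds in the faster unit variant, and
30 seeds for RTV growth — sizes at which Monte-Carlo error is comfortably
below the tolerances being checked while the whole suite runs in a few
seconds.

## Known limitations

* Single-compartment model: no spatial fields, tissue heat diffusion, or
  radiative losses beyond the lumped hA·ΔT law.
* Point estimates with regression diagnostics only; no Bayesian
  uncertainty on η.
* Single-wavelength calibration; no spectral deconvolution or scattering
  correction.
* The cooling fit assumes a single exponential; strongly stirred or
  multi-phase samples showing multi-exponential cooling will yield an
  effective τ with degraded R².
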