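# photothermics

Analysis toolkit for characterizing photothermal agents — light-absorbing
nanomaterials (dye-loaded porous carbon, gold nanostructures, organic dyes)
that convert near-infrared laser light into heat for photothermal therapy.
It is written for the bench scientist who has a thermal-imager log of a
cuvette under an 808-nm laser and wants the standard derived quantities:
the photothermal conversion efficiency η, the dye loading content and
efficiency (DLC/DLE), multi-cycle photostability metrics, and the small
bioassay summaries (CCK-8 viability, relative tumor volume) that accompany
such studies.

## The model

A stirred cuvette is a single thermal node with heat capacity
ΣmᵢC_p,ᵢ (J/K).  Under irradiation at laser power *I* (W) the energy
balance is

    ΣmC · dT/dt = Q_NPs + Q_s − hA·(T − T_surr)

with `Q_NPs = I·(1 − 10^(−A₈₀₈))·η` the heat released by the agent,
`Q_s` the solvent heating, and `hA` (W/K) the lumped product of the
heat-transfer coefficient and the container surface area — only the
product is identifiable.  Each constant-power interval solves in closed
form: temperature relaxes exponentially toward `T_surr + Q/hA` with time
constant `τ = ΣmC/hA`; the simulator stitches these exactly (no numeric
stepping).

At steady state the balance gives, with a pure-water reference run under
the identical protocol,

    η = hA·(ΔT_max,mix − ΔT_max,H₂O) / (I·(1 − 10^(−A₈₀₈))) .

`hA` comes from the laser-off cooling curve: with
θ = (T − T_surr)/(T_max − T_surr), cooling obeys θ(t) = e^(−t/τ), so an
ordinary least-squares fit of time against −ln θ has slope τ and
`hA = ΣmC/τ`.

Dye loading uses a linear Beer–Lambert calibration to convert a
supernatant (or particle) absorbance into a dye mass, then

    DLE = loaded/fed × 100 %,   DLC = loaded/(carrier + loaded) × 100 % .

## Worked example

Estimate η from a simulated experiment with known ground truth
(η = 0.76, τ = 120 s, ambient 26.3 °C, 2.5 W laser, A₈₀₈ ≈ 0.450):

```python
import numpy as np
import photothermics as pt

demo = pt.icg_demo_scenario(on_s=960.0, off_s=960.0)   # heat to full plateau
t = np.arange(0.0, 1921.0, 60.0)                       # 60-s imager sampling
sample = pt.simulate_trace(demo.sample_system, demo.protocol, t)
water = pt.simulate_trace(demo.water_system, demo.protocol, t)

model = pt.PhotothermalEfficiencyModel(
    sample, water, laser_off_s=960.0, heat_capacity_total=4.18,
    laser_power=2.5, absorbance=demo.sample_system.absorbance,
    ambient_temp=26.3)
print(model.fit().summary())
```

```
Photothermal conversion efficiency estimate
===========================================
time constant tau               120.0 s
hA                            0.03483 W/K
eta                             0.760
dT_max (sample)                 35.68 K
dT_max (water)                   0.50 K
laser power                     2.500 W
absorbance (808 nm)             0.450
cooling-fit R^2              1.000000
cooling-fit n                       5
warning: 1 cooling points above theta=1 dropped
```

Reading it: the cooling fit recovers the relaxation time τ = 120 s, hence
hA = 4.18/120 ≈ 0.0348 W/K; the sample plateaued 35.68 K above ambient
against 0.50 K for water, giving η = 0.760 — the generator's ground
truth.  The dropped point is the laser-off sample itself, which sits a
hair above the plateau mean (θ > 1) and is excluded by construction.

The same pipelines are available from the shell:

```sh
photothermics simulate --config run.yaml --out trace.csv
photothermics fit-efficiency --sample sample.csv --water water.csv --config run.yaml
photothermics loading --calibration cal.csv --fed-mg 1.0 --carrier-mg 1.0 \
    --absorbance 0.292 --volume-ml 10 --dilution 10 --mode indirect
photothermics stability --trace trace.csv --config run.yaml
photothermics bioassay viability --plate plate.csv
photothermics make-synthetic trace --config run.yaml --seed 7 --out synth.csv
```

For example, feeding 1 mg dye to 1 mg carrier with 0.34 mg recovered in
the supernatant prints `loaded_mg 0.66, dlc_percent 39.8, dle_percent 66.0`.

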