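# shipair

Ship-emission air quality, health burden and aerosol forcing assessment on
synthetic worlds.

International marine fuel-sulphur policy (the global 0.5 % S cap, on top of
0.1 % S emission control areas) trades public health against climate: less
fuel sulphur means less sulphate PM2.5 — fewer premature cardiovascular and
lung-cancer deaths and childhood asthma cases near shipping lanes — but also
less aerosol cooling, directly (scattering) and through cloud brightening.
`shipair` implements that whole assessment chain as a reusable Python
library, exercisable end to end on generated data: no downloads, explicit
seeds, deterministic reruns.

The five stages, each importable on its own:

- **`shipair.world`** — synthetic world: procedural land/sea mask, country
  partition, coastal-biased population with age cohorts, country incidence
  tables, smooth meteorology, lane-concentrated AIS-like vessel traffic.
- **`shipair.emissions`** — activity-based inventory: cubic-propeller engine
  load, load-dependent SFOC, MARPOL NOx tiers, fuel-sulphur-driven SOx with
  exact sulphur mass balance, PM and CO2 factors, sulphur-cap policy regions,
  compound fleet growth, gridding.
- **`shipair.exposure`** — steady-state lifetime/kernel surrogate mapping
  emission grids to PM2.5 component concentration fields
  (τ(SO2) = 1.5 d, τ(SO4) = 2.8 d), with a bounded ammonium-nitrate
  compensation term.
- **`shipair.health`** — concentration–response burden. Linear form
  RR = e^(βΔC), AF = (RR−1)/RR = 1 − e^(−βΔC), E = AF·B·P per cell and
  cohort, with CI propagation from the β intervals; log-linear form
  RR = ((C1+1)/(C0+1))^β for cross-study comparison.
- **`shipair.forcing`** — direct aerosol forcing via a Haywood–Shine-type
  box expression (with its tipping single-scattering albedo over bright
  surfaces) and the first-indirect Twomey effect via
  D_n = 31 + 93.5·C_NSS + 16.5·C_SSLT and ΔA = A₀(1−A₀)/3 · ln(Dn1/Dn0).

`shipair.pipeline` chains everything for the three standard scenarios
(no-shipping counterfactual, BAU at 2.7 % S, 2020 Action at 0.5 % S) and
produces comparison tables; `shipair.io` reads and writes NetCDF grids, CSV
tables and GeoJSON policy regions.

## Worked example

```python
from shipair import ScenarioConfig, compare_scenarios, run_pipeline

cfg = ScenarioConfig(seed=7, n_lon=30, n_lat=30, n_vessels=100, period_hours=48)
result = run_pipeline(cfg)
report = compare_scenarios(result, base="BAU", alt="ACTION_2020")
print(report["emissions"].round(2))
```

prints

```
          BAU  ACTION_2020  pct_reduction
so2    337.59        65.56          80.58
so4     10.67         2.07          80.60
nox    622.79       622.79           0.00
pm      49.88        23.60          52.68
co      57.06        57.06           0.00
co2  26827.69     26827.69           0.00
```

SO2 falls by ~81 % — the closed-form (2.7−0.5)/2.7 = 81.5 % for traffic
outside control areas, pulled slightly down by the SECA share that was
already burning 0.1 % S fuel. NOx, CO and CO2 are untouched by a sulphur cap.
`report["health"]` shows each endpoint's annual burden against the
no-shipping counterfactual with 95 % confidence bounds and the percent
avoided by the policy, and `report["forcing"]` the direct/indirect/net
forcing per scenario with the (positive, i.e. warming-direction) net change.

The `examples/` directory has one short narrative script per capability:
emission-factor curves, health burden on a synthetic world, the full scenario
pipeline, and the forcing sensitivities (tipping SSA, well-mixed vs detached
cloud sulphate).

See `docs/methods.md` for the model descriptions, parameter defaults and
the limits of what the synthetic setting demonstrates.

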