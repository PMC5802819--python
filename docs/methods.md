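# Methods

`shipair` estimates the public-health and aerosol-climate consequences of
marine fuel-sulphur policy on a self-contained synthetic world. This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic setting does and does not demonstrate.

## Pipeline overview

Five stages, each a pure function of its inputs:

1. **Synthetic world** — land/sea mask, countries, population, incidence
   tables, meteorology, ship traffic. All randomness lives here.
2. **Ship emissions** — activity-based per-record emission computation and
   gridding, under a fuel-sulphur policy scenario.
3. **Exposure surrogate** — emission grids to PM2.5 component concentration
   fields via species lifetimes and a mass-conserving spreading kernel.
4. **Health burden** — concentration-response functions applied to scenario
   concentration pairs, population cohorts and incidence rates.
5. **Aerosol forcing** — direct (box expression) and first-indirect (Twomey)
   forcing of the scenario aerosol differences.

Scenarios: `NO_SHIPPING` (counterfactual), `BAU` (2.7 % S residual fuel
outside control areas) and `ACTION_2020` (global 0.5 % S cap). Regional
control areas (SECA 0.1 % S; EU-directive/DECA-style 0.5 % S) override the
global cap only where stricter and only from their effective date.

## Synthetic world

The generators aim at the *statistical structure* the downstream maths is
sensitive to, not geographic realism.

- **Land/sea mask**: threshold on Gaussian-smoothed white noise (default
  correlation 3 cells, land fraction 0.4). Procedural, so no shoreline data
  are needed; coastlines are noise isolines, not real geometry.
- **Countries**: nearest-seed Voronoi partition of land cells.
- **Population**: a multinomial draw of the configured total over land cells
  (gamma-distributed base density), with coastal cells (land adjacent to sea)
  up-weighted by `coastal_bias` (default 3). Totals are conserved exactly in
  integer persons; with bias 4 on a 1600-cell grid a one-sided Mann-Whitney
  test rejects equal coastal/inland densities at alpha = 0.01.
- **Age cohorts**: uniform within a country — fraction aged 30+ drawn from
  U(0.35, 0.55), fraction under 14 from U(0.15, 0.35), spanning realistic
  demographic ranges while keeping their sum below 1.
- **Incidence**: per-country cardiovascular (150–600 per 100k of the 30+
  cohort), lung cancer (10–80) and childhood current-wheeze (2000–12000 per
  100k under-14) rates. A configurable fraction of countries (default 0.25)
  report only age-standardised rates, exercised through the crude = ASR x
  ratio conversion; missing countries fall back to the mean of present ones.
- **Traffic**: each vessel shuttles along one of `n_lanes` corridors between
  well-separated sea cells at 60–95 % of design speed, emitting hourly
  positions with cross-track jitter clipped to the corridor half-width
  (default 0.5°). Lane endpoints on land are a generation error. Hourly
  granularity is finer than a typical 3-h output step so gridding is
  genuinely exercised.
- **Meteorology**: smooth bounded 2-D fields (logistic squash of smoothed
  noise): cloud fraction 0.05–0.95, insolation 150–350 W m⁻², wind 2–12
  m s⁻¹, mixing height 300–1500 m, sea salt 2–15 µg m⁻³ over sea (zero over
  land), albedo 0.05–0.10 sea / 0.15–0.40 land. No seasons, no vertical
  structure.
- **Background PM2.5**: land-mean 12 µg m⁻³, sea-mean 2 µg m⁻³, modulated by
  a lognormal factor to give the long right tail (arid/fire-like hotspots)
  that distinguishes the linear and log-linear response forms.

## Ship emissions (activity-based)

Per movement record with a matched vessel spec:

- **Engine load**: cubic propeller law `(v/v_design)^3`, clamped to
  [0.02, 1]. The 2 % floor is a hotelling surrogate for stationary or
  slow-moving vessels; resistance-based propulsion modelling is out of scope.
- **SFOC**: base value (valid at 80 % load) scaled by
  `q(L) = 0.455 L² − 0.71 L + 1.28`, normalised to 1 at L = 0.8. This curve
  reproduces the published low-load values 165→186 and 250→282 g kWh⁻¹ to the
  integer.
- **NOx**: MARPOL Annex VI tier curves — SSD flat (17 / 14.4 / 3.4), MSD
  rpm-dependent (45 n⁻⁰·², 44 n⁻⁰·²³, 9 n⁻⁰·²), HSD flat (9.8 / 7.7 / 2.0);
  Tier 0 engines get 110 % of Tier I.
- **SOx**: fuel sulphur mass per kWh is `s_frac × SFOC`. A fuel-family
  fraction f of that sulphur leaves as primary sulphate (f = 0.04 for
  distillates, 0.063 for residual fuel — both implied by the published factor
  table) and the remainder as SO2 at twice the sulphur mass. The balance
  `S(fuel) = S(SO2)/2 + S(SO4)` is exact per record; the inventory stores
  primary sulphate as sulphur mass to keep it that way.
- **PM**: piecewise linear in fuel sulphur between anchors at 0.1 / 0.5 /
  2.7 % S, at each of the two tabulated load points, then linear in load
  between them and clamped beyond.
- **CO2**: fuel carbon factors are the table-implied ratios 515/165 (HFO) and
  803/250 (distillate) times the load-dependent SFOC.
- **Policy**: effective sulphur at a record is the minimum of the scenario's
  global cap and every containing region whose effective date has passed.
- **Growth projection**: compound annual rates per ship type (dry bulk
  +1.74 %, liquid bulk −1.90 %, unitised +2.79 %, passenger −0.55 %,
  miscellaneous 0 %), applied as `(1+g)^years`.
- **Gridding**: energy = power × load × Δt; mass = energy × factor,
  accumulated in grams into the containing cell (half-open cell membership,
  longitude −180…180). Records outside the grid are excluded and counted.
  Totals are reported in tonnes; grams internally to avoid unit drift.

Consequence worth noting: for a fleet burning residual fuel entirely outside
control areas, the 2.7 % → 0.5 % switch cuts SO2 by exactly
(2.7−0.5)/2.7 = 81.5 %; any SECA traffic share pulls the global reduction
strictly below that.

## Exposure surrogate

A steady-state lifetime/kernel model replaces a full chemical transport
model. The health and forcing stages consume concentration *fields*, and the
surrogate preserves the two properties those stages rely on: linearity in
emissions and spatial decay away from sources.

- Per species, the steady-state column burden is `Q·τ` (emission rate times
  lifetime). Defaults: τ(SO2) = 1.5 d (sink dominated by oxidation to
  sulphate), τ(SO4) = τ(NO3) = τ(primary) = 2.8 d.
- The burden is spread over the domain with an isotropic exponential kernel,
  e-folding length ℓ = (domain-mean wind) × τ. Rows of the kernel are
  normalised to 1, so spreading conserves column mass exactly on the closed
  domain; a per-cell ℓ would break that normalisation, which is why the
  domain-mean wind is used.
- Near-surface concentration = column burden / (cell area × local mixing
  height).
- **Chemistry**: a fixed fraction (default 0.5) of emitted SO2 sulphur is
  oxidised to sulphate; a fixed fraction (default 0.1) of NOx mass forms
  particulate nitrate (scaled 62/46); primary PM is the inventory PM minus
  the primary sulphate already counted. Gas-phase mechanisms, organic
  aerosol, dust and fires are out of scope — the background field stands in
  for all non-ship PM.
- **Nitrate compensation**: when sulphate falls, freed ammonia forms nitrate
  worth κ = 0.01 of the local sulphate reduction (up to 0.15 in designated
  high-ammonia cells), capped by an ammonia-equivalent availability and never
  above 15 % of the local reduction. This mimics the reported magnitude
  bounds of the equilibrium chemistry, not the chemistry itself.
- **Diagnostics**: the global sulphur burden is Σ Q_S·τ over sulphur species
  and the mean lifetime is the flux-weighted average of the species lifetimes
  (equal SO2/SO4 sulphur fluxes at 1.5 and 2.8 d give 2.15 d).

## Health burden

- Linear form: `RR = exp(β ΔC)`, `AF = (RR−1)/RR = 1 − exp(−β ΔC)` — the two
  AF routes agree to machine precision and are tested as an identity. The
  field calls this form "linear" although it is exponential in ΔC; the
  terminology is kept.
- Log-linear form: `RR = ((C1+1)/(C0+1))^β` (Ostro 2004 convention). With
  *equal* β the log-linear RR is strictly below the linear RR for any
  C0 ≥ 0 (since ln(1+x) < x), so the documented low-C0 advantage of the
  log-linear form only appears with its own, larger coefficients: the package
  demonstrates the crossover using the Ostro log-linear lung-cancer exponent
  0.23218 against the Lepeule linear 0.031481 on a C0 sweep of 1–100 µg m⁻³.
- Default coefficients (per µg m⁻³, 95 % CI): cardiovascular mortality
  β = 0.023111 (0.013103, 0.033647); lung-cancer mortality β = 0.031481
  (0.006766, 0.055962); childhood asthma β = 0.002469 (0.001291, 0.003633).
  Burden bounds re-evaluate E at the interval ends, preserving
  E_low ≤ E_central ≤ E_high for ΔC ≥ 0.
- `E = AF × B × P` per cell; incidence B per 100,000 converted to
  per-person-year; P is the cohort population (all CV and LC deaths
  attributed to the 30+ cohort; asthma to under-14). Scenario burdens are
  computed against the no-shipping counterfactual; avoided burden is the
  difference of two such burdens and is additive exactly before rounding.
- Report rounding: mortality to the nearest 100 cases, asthma to the nearest
  100,000.

## Aerosol forcing

Single-band box expressions replace spectral radiative transfer; they retain
every sensitivity the assessment turns on (SSA, cloud fraction, surface
albedo, vertical mixing) but their absolute global values are not comparable
with full radiative-transfer results.

- **Direct**:
  `F = −(S/4) T² (1−f_c) ω β̄ ΔAOD [(1−R_s)² − (2R_s/β̄)(1/ω − 1)]`
  per cell, with S = 1361 W m⁻², atmospheric transmittance T = 0.76,
  backscatter fraction β̄ = 0.29, all configurable. ΔAOD comes from the
  sulphate+nitrate column mass at a fixed mass extinction efficiency
  (default 8.5 m² g⁻¹, a standard dry-sulphate value). The bracket's root
  `ω* = 1/(1 + β̄(1−R_s)²/(2R_s))` is the tipping SSA: darker aerosol over a
  bright scene warms. For R_s = 0.7, β̄ = 0.29 the root is 0.982; it
  increases with surface brightness and does not exist over a black surface.
- **First-indirect**: droplet number `D_n = 31 + 93.5 C_NSS + 16.5 C_SSLT`
  (concentrations in µg m⁻³; the constants are read as droplet numbers per
  cm³ — a per-m³ reading would be physically implausible for cloud droplets,
  and only the ratio Dn1/Dn0 enters the forcing, so the choice is
  inconsequential and configurable). Cloud-albedo susceptibility
  `ΔA = A₀(1−A₀)/3 · ln(Dn1/Dn0)` with the perturbed albedo clamped to
  [0, 1]; forcing `F = −S_local f_c ΔA T²`, area-weighted to a global mean in
  mW m⁻².
- **Vertical mixing envelope**: the `detached` mode scales the ship sulphate
  entering the droplet relation by a detachment factor d (default 0.25,
  tuned so the detached/well-mixed forcing ratio matches the reported
  envelope of the two extreme vertical-profile assumptions). Detached
  magnitude is strictly below well-mixed for any d < 1.
- Sign conventions: negative = cooling; adding sulphate never warms via the
  indirect effect, removing it never cools.

## Determinism, numerics, degenerate inputs

- All generators take explicit seeds; downstream stages are deterministic
  transforms, so rerunning a configuration reproduces stage checksums
  (SHA-256 of the arrays) bit for bit.
- Cell membership is half-open; points infinitesimally below the upper grid
  bound are clamped into the last cell to absorb floating-point division
  rounding.
- Kernel spreading degenerates to the identity at zero wind; tiny grids that
  would be all-land or all-sea are nudged to keep both classes non-empty.
- AF uses `expm1` to avoid cancellation at small β·ΔC.
- Zero baselines (percent reduction of a zero burden, zero mixing height,
  RR ≤ 0) raise typed errors rather than propagating NaNs.

## Problem sizes

Default desk-scale runs use 15×15–50×50 grids, 10–200 vessels, 12–72 h of
hourly traffic and 3 scenarios; the largest configuration exercised by the
test suite (50×50 cells, 200 vessels, 48 h, three scenarios) completes in a
few seconds on one CPU. The spreading kernel is a dense (n_cells)² matrix,
which is the binding cost if grids grow much beyond ~100×100.

## What passing tests do and do not show

The synthetic world preserves conservation laws, spatial concentration of
activity, coastal population bias, bounded meteorology and long-tailed
background PM — so the tests demonstrate the *correctness of the methods*
(mass balances, closed forms, monotonicities, published worked examples) and
the *direction and rough magnitude structure* of policy effects. They do not
validate global absolute totals (deaths, Mt of emissions, global mW m⁻²),
which depend on real traffic density, chemistry-transport meteorology and
real population/incidence data that the synthetic world does not claim to
reproduce.
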