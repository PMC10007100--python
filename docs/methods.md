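# Methods

This note documents the models implemented in `etcmp`, the assumptions
behind them, the default parameter values and why they were chosen, what
the synthetic generators do and do not emulate, and the numerical choices
that matter when interpreting results.

## 1. Satellite route (S-SEBI)

### Radiative preprocessing

Broadband albedo is the weighted sum of the six shortwave band
reflectances (weights 0.293, 0.274, 0.233, 0.156, 0.033, 0.011 for
B2…B7; they sum to 1). Top-of-atmosphere reflectance follows
ρ = π L d² / (K↓ cos θz), clipped to [0, 1] with a log message rather
than an error — out-of-range values are routine sensor/correction
artifacts. NDVI is the usual normalized difference; MSAVI uses the
self-adjusting-L closed form
`(2ρN + 1 − sqrt((2ρN+1)² − 8(ρN − ρR)))/2`, the standard choice where a
source publication names the index without printing a formula.

Net radiation is `Rn = (1 − α) Rg − σ εs Ts⁴ + σ εa Ta⁴` with
σ = 5.670374419×10⁻⁸ W m⁻² K⁻⁴. Surface emissivity defaults to the
constant 0.98; atmospheric emissivity defaults to the Brunt-type
clear-sky form `εa = 1.24 (e_a/Ta)^(1/7)` (vapor pressure in hPa) with a
constant-εa override, since only the L↓ = σ εa Ta⁴ structure is fixed by
the method and the εa model is otherwise open. Missing pixels are NaN
and propagate through every per-pixel operation.

### Edge fitting

Operational S-SEBI work often delineates the dry and wet edges of the
(α, Ts) scatter by hand. `fit_edges` replaces that with a reproducible
procedure: mask to vegetated pixels (NDVI ≥ 0.3 by default), bin albedo
into 20 equal-width bins between the 2nd and 98th albedo percentiles,
take each bin's extreme-Ts *pixel* (not an interpolated percentile — the
extreme pixel lies exactly on a noiseless envelope, which makes the
closure test sharp) as the dry/wet candidate, restrict the dry fit to
bins right of the candidate maximum (the radiation-controlled limb) and
fit both lines by least squares with one robustness pass discarding
candidates beyond 2 standard deviations of residual. All knobs live in
`EdgeFitConfig`; `dry_percentile`/`wet_percentile` can be backed off
from the extremes for heavy-tailed noise.

Evaporative fraction is clipped to [0, 1]; pixels beyond the fitted
envelopes are physical-range violations and the clipped fraction is
reported per scene rather than silently absorbed.

### Soil heat flux and daily ET

Five G0 parameterizations are implemented (CLO, DAU, BAS, SOB, CONST;
formulas in `soil_heat_flux`'s docstring). The DAU and BAS damping
factors use NDVI⁴ and DAU uses α² — the forms of the cited originals —
because the available source text garbles those exponents. All models
take Ts in kelvin and convert internally where the formula is written in
Celsius. Energy closure `G0 + H + λE = Rn` holds *by construction*:
λE = Λ·max(Rn − G0, 0) and H is the remainder, so pixels with negative
available energy get λE = 0 and never negative ET.

Latent heat converts to water flux with 2,454,000 J kg⁻¹. The
instantaneous-to-daily upscaling assumes the diurnal λE course follows
the solar sinusoid, giving `ET_day = ET_i (2N/π) / sin(πt/N)` with N the
daylength and t the hours since sunrise. The division (rather than
multiplication) by the sine is the only reading consistent with the
integral of the assumed diurnal course — a noon observation must scale
*up* to the daily total — and the suite verifies the identity against
numerical integration to 0.1 %.

## 2. FAO-56 route

ET0 is the standardized daily Penman–Monteith for the grass reference,
with the standard psychrometric and radiation sub-formulas (Angot
radiation from latitude and day of year, clear-sky index for the
longwave term, γ from elevation-dependent pressure; G = 0 at the daily
step). The independent oracle in the tests is a literal step-by-step
recomputation of the classic mid-latitude July worked example
(ET0 ≈ 3.88 mm d⁻¹), agreed to within 5 %.

Crop coefficients follow the stagewise trajectory (constant Kc_ini,
linear development ramp, constant Kc_mid, linear late-season ramp).
Season dates and Kc triplets for the three monitored seasons are shipped
as fixtures (potato 0.5/1.15/0.75; barley 0.3/1.15/0.25). Stage
*lengths* are not part of the record; the defaults are standard
stage-length tables rescaled to the actual season length (potato
0.19/0.23/0.35/0.23, barley 0.25/0.25/0.30/0.20) and are overridable in
the crop config. ETc splits into potential transpiration and soil
evaporation through the Ritchie surface-cover fraction
`SCF = 1 − exp(−0.46 LAI)`; the split conserves ETc exactly.

LAI comes either from a piecewise-linear literature trajectory (potato
1 → 3.5 → 1 m² m⁻²; barley 0.29 → 3.5 → 0.29) or from NDVI through
`LAI = exp(−4.58 + 7.33 NDVI)`. The dual-coefficient form
`ETa = (Ks Kcb + Ke) ET0` is provided for completeness with Ks supplied
by the caller — in this package's workflow the stress response is
computed mechanistically by the soil route, not by FAO-56 Ks.

## 3. Soil-water route

### Flow

The Richards equation is solved on a cell-centered uniform grid
(default Δz = 1 cm over the 1 m profile) in the mass-conservative mixed
form with modified-Picard linearization; the implicit system is
tridiagonal and solved directly each iteration. Internodal conductivity
is the arithmetic mean by default (geometric and upstream available).
Convergence requires max |Δh| < 10⁻⁵ m or max |Δθ| < 10⁻⁹ — the θ
criterion matters near saturation, where the capacity degenerates and
head-only criteria stall. The iteration is under-relaxed adaptively
(ω down to 0.2) when it overshoots or cycles, which happens when nodes
cross the saturation point; iterates are clamped to h ∈ [−10⁵, 10²] m
to keep a wild linearization step from overflowing the constitutive
functions, and a 10⁻¹² diagonal floor keeps rows of completely dry cells
non-singular.

Time stepping is adaptive in [10⁻⁶, 0.05] d: grown ×1.3 when the step
converges in ≤ 4 iterations, shrunk ×0.7 above 10, retried at ×0.3 on
failure. The per-step water-balance increment error is computed and
accumulated, never absorbed; the full-season audit closes to well below
0.1 % of gross flux.

Boundary conditions: the top is "atmospheric" — a prescribed net flux
(rain + irrigation − potential evaporation) that switches to a ponded
head (h = 0, excess to runoff) when supply exceeds infiltrability, and
to a dry-surface head limit when evaporative demand cannot be met. The
evaporation-limiting surface head h_crit defaults to −150 m
(configurable; it is a numerical proxy for the air-dry surface state,
not a measured site value). The bottom is free drainage (unit hydraulic
gradient), appropriate for a deep (~9 m) water table; prescribed head
and flux are also available for verification setups. Depth is positive
down throughout the soil package; conversions to/from elevation
conventions are internal to the solver's flux definition.

Hydraulics are van Genuchten–Mualem with m = 1 − 1/n. The shipped
`oued_souhil` profile carries the five-layer calibrated parameter set of
the experimental sandy-loam plot (θs of the 0–0.2 m layer 0.3938,
Ks 2 m d⁻¹, etc.).

### Root uptake and stress

Potential transpiration distributes over the root zone by a normalized
root-density profile (uniform over the rooting depth by default, a
linearly decreasing option; rooting depth fixed at 0.6 m for potato and
1.0 m for barley, constant through the season). Uptake is reduced by
the product of two independent factors (multiplicative, no
compensation): the Feddes piecewise-linear pressure-head response —
zero above h1 (anaerobiosis) and below h4 (wilting), optimal between h2
and h3, with h3 interpolated between its high- and low-demand anchors by
the day's T_pot — and a threshold–slope osmotic response, 1 up to the
crop's pore-water-EC threshold and declining by slope % per dS m⁻¹ above
it (potato: 3.40 dS m⁻¹ and 6 %/dS m⁻¹; barley: 16 dS m⁻¹ and
2.5 %/dS m⁻¹). The Feddes pressure heads are the conventional crop-database
defaults for potato and wheat-type cereals, clearly marked as defaults
in `data/crops.yaml`; any site-specific deviation is a config change.

### Salinity transport

Salinity state is pore-water EC (dS m⁻¹) used directly as a linear
concentration proxy, because the stress functions are written in EC
units. Transport is advection–dispersion: explicit flux-weighted upwind
advection with internal CFL sub-stepping (never failure),
Crank–Nicolson implicit dispersion with D = λ|v| + D_m (dispersivity
default 0.05 m — a calibration-class parameter with no public value,
configurable; molecular diffusion default 0). The top boundary is
third-type (Cauchy): salt enters only with infiltrating water at the
infiltration-water concentration, and evaporation leaves all salt
behind; the bottom is zero concentration gradient (advective outflow
only). Roots take up water only. A first-type (fixed concentration)
inlet is available for laboratory-column verification, where it matches
the analytic step-input (erfc) profile to < 1 % RMSE of the inlet
concentration; salt mass balances against the boundary fluxes to
machine precision in steady flow and to < 0.1 % in transient runs.

The dilution/concentration cycle this produces — EC rising between
irrigations as roots remove water, dropping after rain — is the
qualitative behavior the root-zone salinity figure in field studies
shows; with 3.5 dS m⁻¹ drip irrigation and little leaching the seasonal
trend is strongly upward, which is what drives the potato scenario's
osmotic stress.

### Season driver

Each forcing day: ET0 → Kc → ETc → LAI split into (T_pot, E_pot); the
net surface flux and sink integrate sub-daily with the adaptive stepper;
the solute step uses the flow step's interface fluxes. Daily outputs:
potentials, actual E/T/ET, infiltration, runoff, drainage, profile
storage, θ-weighted root-zone EC, and the solute boundary terms. Initial
conditions default to uniform h = −2 m (a field-capacity-like state for
this sandy loam) and EC = 1 dS m⁻¹; both accept per-node arrays. The
driver is deterministic — identical inputs give bitwise-identical
outputs.

## 4. Synthetic generators

The generators exist so that every stage has inputs with known truth;
they are calibrated to the study conditions, not tuned to any test.

- **Scenes.** Albedo ~ U(0.10, 0.45); true Λ ~ Beta(2, 2);
  Ts = (1−Λ)T_H(α) + Λ T_λE(α) + N(0, σ_T) with default edges
  a_H = 330 K, b_H = −25 K, a_λE = 288 K, b_λE = +10 K — invented
  values chosen so the trapezoid spans a realistic Mediterranean Ts
  range with the qualitative dry/wet-edge geometry of the method's
  scatter diagrams (no fitted edge coefficients are on public record).
  A small albedo-stratified fraction of pixels (2 % per edge) is pinned
  exactly on each envelope: contextual retrieval presupposes that both
  hydrological extremes are present in the scene, and their presence is
  what makes the noiseless closure loop exact rather than asymptotic.
  NDVI = 0.3 + 0.5Λ + N(0, 0.03) clipped to [0.3, 0.95] (so the default
  mask keeps all pixels) encodes the positive Λ–NDVI coupling seen in
  vegetated fields; red/NIR reflectances are back-solved under
  ρN + ρR = 0.5.
- **Weather.** Sinusoidal daily-mean temperature (≈8 °C January to
  ≈32 °C July–August), shortwave as a noisy clear-sky fraction of
  extraterrestrial radiation (cloudier on rain days), RH anticorrelated
  with temperature, lognormal wind, winter-weighted Poisson rain
  occurrence with gamma depths scaled to an expected 450 mm yr⁻¹. With
  these settings annual reference ET lands in 1100–1600 mm, bracketing
  the ~1370 mm climatology of the target region.
- **Forcing fixtures.** The three seasons with their documented totals
  (336 mm in 16 equal drip events + 20 mm rain; 170 mm in 8 events +
  70 mm; 291 mm rain, no irrigation; irrigation EC 3.5 dS m⁻¹).
  Irrigation events space evenly through the 20–80 % span of the season
  (development + mid stages); rain spreads in equal events over the wet
  part of the season (whole season for the potato crops, through April
  for the winter barley). ET0 comes from the weather generator for the
  matching calendar years.
- **Sensor series.** Daily nodal θ/EC profiles interpolated to hourly at
  the nodes nearest 0.05/0.25/0.45/0.90 m depth, with additive
  N(0, 0.01 m³ m⁻³) water-content noise and 5 % multiplicative EC noise,
  emulating capacitance probes.

What the generators do *not* emulate — and therefore what passing tests
do not demonstrate about real data: atmospheric and sensor radiometric
effects (the scenes are born as surface quantities), spatial correlation
and mixed pixels, cloud contamination, real storm structure and
intra-day weather, hysteresis or macropore flow in the soil, and probe
installation artifacts. Results on synthetic inputs validate the
machinery and its internal consistency, not field accuracy.

## 5. Scenario grid and statistics

Sixteen scenarios: S{1,2,3}{P1,P2,B} (satellite route with G0 model
CLO/BAS/SOB per season), F{P1,P2,B} (FAO-56 unstressed baseline), HP1,
HP2, H1B, H2B (soil route; the two barley variants differ in LAI source,
literature vs NDVI-derived). Scene seeds depend only on (seed, season,
overpass index) so scenarios differing in the G0 model see identical
scenes — controlled comparisons by construction. Satellite overpasses
repeat every 16 days at 10:30 solar time with clear-sky instantaneous
radiation from solar geometry.

R² is squared Pearson correlation (scale-free); Nash–Sutcliffe
efficiency is reported separately and labelled, since model-vs-model
comparisons often want it. Series pair on exact date intersection only,
no interpolation — satellite estimates exist only on overpass days. The
G0 comparison table reports, per scene set, the RMSE of plot-mean G0 and
λE of each model against the constant-ratio reference G0 = 0.2 Rn
(plot means, matching how such flux tables are built; per-pixel RMSE is
a one-line change in `g0_comparison_table`).

Seasonal headline statistics of the original field campaign (R² and
RMSE of satellite vs soil-route ETa, seasonal ET percentages) depend on
undeposited scenes and field data and are deliberately not asserted
anywhere in this package; the scenario grid reproduces the *structure*
of that comparison on synthetic inputs.

## 6. Known limitations

- 1D vertical flow only; no hysteresis, heat transport, preferential
  flow, or compensatory root uptake.
- The FAO-56 route does not compute a stress coefficient; it is the
  deliberately unstressed baseline.
- Edge fitting assumes the radiation-controlled limb dominates the
  masked scatter; scenes dominated by the low-albedo (forest) limb need
  the mask tightened.
- The Picard solver trades speed for robustness near saturation; ponded
  infiltration into near-saturated fine-textured columns drives the
  adaptive stepper to small steps (10⁻⁴–10⁻³ d).
- Problem sizes in the shipped tests (5000-pixel scenes, 1 cm/0.5 cm
  grids, full 119- and 246-day seasons) were chosen as the smallest
  sizes at which every verification property is sharply testable.
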