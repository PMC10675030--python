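# Methods

This note documents the models implemented in `aeroeta`, the choices made
where the methodology is genuinely open, and what the synthetic-trial
validation does and does not demonstrate.

## Penman–Monteith reference and potential ET

Daily reference ET0 follows the FAO-56 methodology: net radiation from
measured shortwave with the extraterrestrial/clear-sky procedure
(latitude, day of year, elevation; relative shortwave bounded to
[0.3, 1]), actual vapour pressure from mean relative humidity and the
Tmin/Tmax saturation mean, and the combination equation for a clipped
grass reference (height 0.12 m, bulk surface resistance 70 s·m⁻¹, albedo
0.23).

The implementation uses the *resistance-explicit* form of the combination
equation —

LE = [Δ·(Rn − G) + ρₐ·c_p·(e_s − e_a)/r_a] / [Δ + γ·(1 + r_s/r_a)]

— rather than the tabulated daily equation with the rounded 900 and 0.34
coefficients. The reason is internal consistency: potential ET of the
actual canopy (ETp) uses the same equation with canopy-dependent
resistances, a bulk surface resistance r_s = r_l/(0.5·LAI) with leaf
resistance r_l = 100 s·m⁻¹ (LAI floored at 0.1 so a bare plot still
evaporates at a large but finite resistance), and an aerodynamic
resistance from the FAO log profile of the actual crop height
(d = 2/3·h, z_om = 0.123·h, z_oh = 0.1·z_om, measurement height raised to
h + 0.5 m over tall canopies, wind floored at 0.5 m·s⁻¹). With r_s = 70
and h = 0.12 the two routes coincide identically, which the tests assert
to 1e-9. λ is fixed at 2.45 MJ·kg⁻¹ for daily totals (FAO convention) and
temperature-dependent where instantaneous fluxes are converted to water
depths. Daily ET0/ETp are floored at zero.

## Two-source energy balance (TSEB-2T)

Per-flight actual ET comes from a two-source energy balance using the
*measured* canopy and soil temperatures (the 2T variant); no
Priestley–Taylor initial guess is needed because high-resolution thermal
imagery resolves both components.

* Net radiation over the composite surface uses one net-radiation pool
  (single-Rn simplification): shortwave with albedo 0.20, longwave
  exchange at the fc-weighted fourth-power composite of T_C and T_S,
  emissivity 0.98, and downwelling longwave estimated from air
  temperature and vapour pressure (Brutsaert) when not measured. A full
  multi-stream canopy radiation scheme was deliberately not implemented;
  at plot scale the partition below dominates.
* Partition by exponential extinction through the canopy:
  Rn_soil = Rn·exp(−κ·LAI/√(2·cosθ)), κ = 0.45; soil heat flux
  G = 0.35·Rn_soil.
* Sensible heat through a series resistance network: aerodynamic
  resistance from the log profile with Businger–Dyer stability
  corrections, a Norman-style canopy boundary-layer resistance
  r_x = (C′/LAI)·√(s/u(d+z_om)) with C′ = 90 s^½·m⁻¹ and leaf size
  s = 0.03 m, and a soil-surface resistance 1/(a + b·u_soil) with
  a = 0.004, b = 0.012; wind inside the canopy attenuates exponentially
  (Goudriaan coefficient clipped to [0.5, 4]). The within-canopy air
  temperature is solved from the three-node network, giving H_canopy and
  H_soil; the Obukhov length is iterated (damped, tolerance 1e-3, cap 50
  iterations).
* Latent heat is the residual per source: LE_c = Rn_c − H_c,
  LE_s = Rn_s − G − H_s. Negative residuals (non-physical condensation at
  midday) are floored at zero with the excess returned to the sensible
  term, so energy closure holds exactly on every output; the tests assert
  closure to 1e-6 W·m⁻².

All coefficients live in `TsebParams`. A one-source residual fallback
(`single_source_fluxes`) exists for plots where one component temperature
is missing (e.g. full canopy cover leaves no soil pixels).

Instantaneous LE is upscaled to a daily ETa with the ET0-ratio method —
ETa_daily = (LE as mm·h⁻¹) × ET0_daily/ET0_hourly at flight time — which
assumes the crop/reference ratio (the stress coefficient) is constant over
the day. The constant-evaporative-fraction alternative was not used
because the ratio method is the one consistent with the Ks framework
below.

## LAI models

The LAI regression searches all non-empty subsets of {PH, VARI, fc}
(seven candidates), fits each by OLS and keeps the subset with the lowest
BIC, defined as n·ln(RSS/n) + k·ln(n) with k counting the intercept. The
selection is exhaustive by construction, so tests compare it against an
independent enumeration, and the OLS path against normal equations and
statsmodels. Predictions are raw linear values by default (they can be
slightly negative for sparse canopies); the pipeline floors them at zero
before curve fitting.

The seasonal sigmoid LAI(DAS) = c/(1 + exp(−a·(DAS − b))) is fitted with
`scipy.optimize.curve_fit` under bounds, from a deterministic start:
c₀ = max observed LAI, b₀ = DAS at half of c₀ by linear interpolation,
a₀ = 4/(20–80% rise span). If the optimiser fails, up to 8 perturbed
starts from a seeded generator are tried before an explicit failure.
Because the default start almost always converges, the fit is
seed-insensitive in practice (asserted in tests). Plant height is fitted
with the same machinery to provide the daily heights ETp needs.

## Ks interpolation and stage integrals

Ks = ETa/ETp per flight. Ks is *not* capped above 1 by default — daily
ETa can legitimately exceed the modelled potential when the upscaling day
differs from the reference conditions — a cap is available in
configuration.

Daily Ks over the season: Ks ≡ 1 from sowing through 100 days after
sowing (early water needs assumed met); each flight's Ks applies
piecewise-constant from the midpoint with the previous flight (or DAS 101
for the first) through the midpoint with the next (floor division), and
the last value holds to maturity. Flights at or before DAS 100 are
rejected as inconsistent with the early-season assumption. A linear
interpolation scheme is available as a configurable alternative. The step
scheme satisfies an exact round-trip identity: any piecewise-constant
truth whose breakpoints sit on the midpoint boundaries is reproduced to
machine precision (asserted at 1e-9 mm).

Stage split convention: the heading day belongs to the vegetative
integral ([0, heading]); grain filling is (heading, maturity]. The two
stages partition the season total exactly. Water productivity uses the
whole-season cumulative ETa: WP = GY/(10·ΣETa) kg·m⁻³, since 1 mm over
1 ha is 10 m³.

## Trial statistics

Variance components use balanced ANOVA method-of-moments (mean squares
from the variety or variety × environment layout), truncating negative
moment estimates at zero; REML was deliberately omitted to keep the
module dependency-light. Broad-sense heritability is reported on the
entry-mean basis H² = σ²g/(σ²g + σ²/r); an optional multi-environment
form H² = σ²g/(σ²g + σ²ge/e + σ²/(r·e)) is behind a flag. Percent
treatment reductions are reported rounded to the nearest integer (full
precision retained internally). Reported water productivity is the mean
of per-plot ratios, not the ratio of treatment means — the two differ and
the choice matters when comparing to published tables.

## The synthetic trial generator

The generator emulates the study conditions the pipeline targets:
22 varieties × {full irrigation, rainfed} × 3 blocks; a Mediterranean
winter-wheat season (sowing in early December at 41.7° N, 250 m;
sinusoidal seasonal temperature with AR(1) noise, ~10 °C diurnal range;
radiation below the clear-sky envelope; sparse rainfall events rescaled
to a 130 mm season total; FAO-56 ET0 from the generated weather);
per-variety sigmoid LAI trajectories (a ∈ [0.08, 0.13] d⁻¹,
b ∈ [108, 124] DAS, c ∈ [4.8, 7.4]) with proportional plant-height
curves; thermal flights at 118/138/155 DAS plus RGB-only flights at 61/81
DAS for curve calibration.

Phenology: heading varies per variety over 127–133 DAS (late April, the
stage window the second flight targeted); physiological maturity is
synchronous at 162 DAS. Under terminal Mediterranean drought and heat,
maturity differences compress strongly across genotypes, and a
synchronous maturity also places each flight near the centre of its Ks
interpolation interval, so the three-flight campaign samples a linear
stress decline without systematic bias — the property that lets the
zero-noise pipeline recover the true cumulative ETa to better than 1%
(the residual being pure interpolation discretization). Varietal
phenological diversity is expressed through heading, curve shape and the
stress trajectory.

Stress truth: Ks ≡ 1 for the irrigated treatment; under rainfed, Ks = 1
until anthesis (= heading by default) and declines linearly to a
per-variety terminal value in [0.35, 0.6] at maturity.

Flight observations are generated by *inverting* the observation models:
VARI is solved from the linear LAI map (default coefficients match the
shipped reference regression) so that, at zero noise, predicting LAI from
(PH, VARI, fc) returns the true LAI exactly. Canopy temperature has two
modes:

* `linear` (default): T_C = unstressed canopy temperature + 5 °C per unit
  (1 − Ks); a minimal model convenient for arithmetic checks of the
  stress→temperature link.
* `energy_balance`: T_C is found by root-finding so that the TSEB flux at
  flight conditions, upscaled to a daily ETa, equals Ks_true·ETp exactly
  (soil temperature offset 6 °C + 4 °C per unit stress). This mode makes
  the generated imagery physically consistent with the retrieval chain
  and is the one under which end-to-end truth recovery is meaningful.

Yields respond asymptotically to grain-filling ETa:
GY = Ymax·(1 − exp(−k·max(0, ETa_GF − offset)))·variety effect + noise,
with Ymax = 11 000 kg·ha⁻¹, k = 0.012 mm⁻¹ and offset = 50 mm chosen so
the rainfed treatment sits on the rising limb (≈25–30% yield loss) while
irrigation approaches the plateau — the saturating water-response pattern
the stage-split analysis is meant to expose. TKW and grain number share
the monotone dependence. Weekly irrigation doses replace the
crop-coefficient demand unmet by rain: max(0, ΣKc·ET0 − Σrain).

### What the synthetic validation does not show

The generator's observations are *model-consistent by construction*: the
energy-balance temperature mode inverts the same TSEB formulation the
pipeline applies, so end-to-end recovery validates the numerical chain
(calibration → curve fitting → ETp → flux partition → upscaling →
interpolation → integration), not the physical adequacy of TSEB for real
wheat canopies. Real thermal imagery carries radiometric error, mixed
pixels, view-geometry effects and surface-roughness deviations that no
noise term here emulates; real LAI regressions have structural (not just
Gaussian) residuals; real stress trajectories are not piecewise-linear.
Published field accuracies of the underlying models are the relevant
evidence for those aspects.

## Problem sizes and numerical conventions

The shipped tests run the end-to-end recovery on 4 varieties × 2 regimes
× 1 block and the statistical simulations at 100–500 replicates; the
acceptance script uses 8 varieties for the zero-noise recovery and the
full 22 × 2 × 3 layout for the noisy trial statistics. Grids are
row-major with origin top-left; masks are boolean arrays of identical
shape; Ks, LAI, fc and all variances are non-negative by construction or
validation; degenerate inputs (zero VARI denominator, missing component
temperature, single replicate, zero ETp) raise explicit errors rather
than propagating NaNs.
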