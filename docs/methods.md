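# Methods

This note describes the models and procedures implemented in `isoflux`, the
assumptions behind them, the tunable parameters that matter, and what the
synthetic world does and does not emulate.

## Open dynamic chamber fluxes

A transparent chamber (60 L, base area 962 cm², configurable) is flushed at
a known volumetric flow (0–40 L min⁻¹) and the net flux of a gas is the
molar air flow times the inlet/outlet mixing-ratio difference per unit
ground area:

    F = n · (χ_out − χ_in) / A,     n = P·V̇ / (R·T_K).

NEE is reported in µmol CO₂ m⁻² s⁻¹ with negative values denoting net
carbon uptake; ET in mmol H₂O m⁻² s⁻¹, positive toward the atmosphere. For
water vapor an optional dilution correction divides the flux by
(1 − x_out), the outlet water mole fraction, accounting for the vapor the
plot itself adds to the air stream. The correction is on by default for ET
and off for CO₂ (the ~2% effect is within CO₂ measurement noise); both are
toggles. Records with `h2o_out < h2o_in` (condensation) yield negative ET
and a flag rather than an error.

Ecosystem respiration comes from darkened-chamber records: each light
record is paired with the nearest dark record of the same plot within a
configurable window (default 30 min; exact ties resolve to the earlier dark
record), Reco is the dark NEE (positive release), and GPP = NEE − Reco. The
identity NEE = GPP + Reco is therefore exact on every partitioned record.

## Isotope-based evapotranspiration partitioning

The transpired fraction of ET follows from two-endmember mixing of the
vapor flux's ¹⁸O composition:

    ft = T/ET = (δ_ET − δ_E) / (δ_T − δ_E).

* **δ_ET** is measured by chamber mass balance,
  δ_ET = (w_out·δ_out − w_in·δ_in)/(w_out − w_in), per reading. It is
  undefined (flagged) when the chamber adds no net vapor (w_out ≤ w_in).
* **δ_E** is the Craig–Gordon composition of soil evaporation,

      δ_E = [ (1000 + δ_soil)/α_eq − h·(1000 + δ_atm) ]
            / [ (1 − h)(1 + ε_k/1000) ] − 1000,

  with α_eq the equilibrium liquid–vapor fractionation at the temperature
  of the evaporating soil layer (Majoube 1971 coefficients:
  ln α = 1137/T² − 0.4156/T − 0.0020667, T in K) and h the atmospheric
  humidity normalized to that temperature. The kinetic enrichment ε_k
  defaults to 14.25‰ — the fully diffusive ¹⁸O value of 28.5‰ weighted by
  an aerodynamic factor of 0.5, a mid-range choice for a ventilated canopy
  — and is a plain configuration parameter.
* **δ_T** assumes isotopic steady state: transpired vapor carries the
  xylem/source-water signature unchanged. Non-steady-state leaf-water
  enrichment is a deliberate extension point, not implemented.

`ft_raw` is clamped to [0, 1] with a `clamped` flag (budgets need
E + T = ET exactly; the flag preserves diagnosability). Records with
|δ_T − δ_E| below a conditioning threshold (default 1‰) are flagged
invalid instead of producing an exploding ratio. Standard deviations are
first-order propagated assuming one common, independent δ uncertainty.
Spectrometer calibration is an ordinary least-squares line from measured to
true values through ≥2 laboratory standards, optionally preceded by a
time-linear drift correction estimated from repeated measurements of a
constant standard.

## Daily integration

Campaign-day series are smoothed by loess — local polynomial regression
with tricube weights over the nearest `ceil(span·n)` points. The
uncertainty band is ±1 standard error of the local fit ("68% confidence
interval"), computed from the locally weighted residual variance; it
collapses to zero on noise-free data. The generic default is span 0.75,
degree 1; the campaign pipeline uses span 0.35, degree 2, which tracks the
curvature of diel flux peaks with negligible bias while still averaging
across plot replicates (local linear fits at wide spans systematically
flatten a half-sine peak). The smooth is evaluated on a 6-min grid so the
trapezoid error of the daily integral is negligible.

Daily sums apply the night rules: GPP and T are anchored to zero at sunrise
and sunset and through the night; Reco and E continue at night at the mean
of the first/last measured hour (start value for the pre-measurement night,
end value after); night NEE equals Reco and night ET equals E. NEE and ET
daily sums are composed from the parts, making the composition identities
exact. Sunrise/sunset come from the PPFD record rather than solar geometry:
the morning (evening) ramp through the first (last) two above-threshold
samples (threshold 5 µmol m⁻² s⁻¹) is extrapolated to zero, clipped to the
bracketing samples. Measurement windows shorter than 2 h are flagged
low-confidence. Sums are converted to g C m⁻² d⁻¹ (×12·10⁻⁶ per second)
and kg H₂O m⁻² d⁻¹ (×18·10⁻⁶).

Error propagation is quadrature for sums (independence assumed — the loess
band is serially correlated, so daily-sum SDs are mildly optimistic) and
first-order relative variances for ratios.

## Seasonal budgets from chamber / eddy-covariance fusion

The eddy-covariance tower measures untreated (ambient) grassland
continuously; chambers measure all treatments on campaign days. Per
campaign and flux, the half-hourly control-treatment chamber series
(plot-averaged, paired to the nearest EC timestamp within 15 min, ≥5
pairs) is compared to the EC series by Spearman rank correlation — ranks
because neither series is normal, and the gate should be invariant to
monotone response differences. If r > 0.75 the campaign is accepted and
the additive offset mean(chamber daily sum − EC daily sum) is retained per
treatment; rejected campaigns contribute nothing and are spanned by the
interpolation. Offsets are nearest-neighbour interpolated to every season
day (ties to the earlier campaign), added to the EC daily series (missing
EC days linearly gap-filled, flagged), and summed per growth stage and
season. Offsets are additive, not multiplicative: they must be able to
cross zero, and an "offset" is what the gate estimates. Season
WUE_eco = (−NEE)/ET; treatment contrasts are reported as signed percent
change of the magnitude relative to the control, computed from unrounded
sums and rounded for reporting.

The method assumes the chamber−EC offset varies slowly relative to the
campaign spacing. Under that assumption nearest-neighbour interpolation at
(approximately) evenly spaced campaigns behaves like a midpoint quadrature
and is nearly unbiased; strongly uneven schedules concentrate error where
coverage is sparse.

## Environment utilities

Vapor pressure deficit uses the August-Roche-Magnus saturation curve with
the (17.625, 243.04, 0.61094 kPa) coefficient set:
VPD = e_s(T)·(1 − RH/100). Soil-moisture series are gap-filled on daily
means: runs of ≤10 missing days are linearly interpolated; longer outages
(a broken sensor) are reconstructed by adding, to the replicate-sensor
mean, the mean offset between the broken sensor's last 10 pre-gap daily
values and the replicate mean at those same times. Every value carries a
provenance flag (`measured` / `interpolated` / `offset_modeled` /
`missing`), and the filler is idempotent. Treatment summaries report
100·(mean_trt − mean_control)/mean_control per depth and growth stage.

## The synthetic world

The generator produces a full growing season (default 2017-04-01 to
2017-09-30, 30-min cadence) with known truth, so every pipeline stage is
testable without field data.

* **Meteorology.** Smooth seasonal + diel cycles: air temperature is a
  seasonal sinusoid (daily means ≈ 11–21 °C) with a 5 °C diel swing peaking
  at 14:30; PPFD is a half-sine over a season-dependent photoperiod
  (12 ± 3.4 h) with peak 900–1550 µmol m⁻² s⁻¹; humidity follows a constant
  within-day vapor pressure (62% of saturation at the daily-mean
  temperature), which yields a realistic diel RH cycle and keeps the
  normalized humidity near 0.55. Precipitation is stochastic (seeded):
  wet-day draws with gamma amounts scaled so the ambient season total is
  exactly 446.6 mm; sheltered plots receive exactly
  (1 − 0.367) × ambient = 282.7 mm.
* **Fluxes.** Four growth stages (spring start, summer peak, dieback,
  autumn peak) are encoded as a smooth PCHIP amplitude curve through stage
  midpoints, flattened outside the campaign-covered window. GPP and T scale
  with the PPFD half-sine (zero whenever PPFD is zero); Reco follows a
  Q10 = 2 response to the daily-mean temperature; E has a constant soil
  baseline plus a flat-shouldered (s⁴) daytime component whose relative
  weight declines over the season, so the true transpiration fraction rises
  as the canopy develops. Treatment multipliers on (GPP, Reco, ET) produce
  the seasonal contrast pattern of a fertilisation × drought experiment;
  defaults give season sums near (−409, −218, −142, −88) g C m⁻² and
  (309, 232, 270, 187) kg H₂O m⁻² for CC/CD/NC/ND. The ET multiplier
  scales T and E jointly, so true ft is treatment-invariant.
* **Sampling.** Default 10 campaigns, evenly spaced (≈ every 18 days), 3
  plots per treatment, 30-min cadence over the photoperiod; each light
  record is followed six minutes later by a darkened-chamber record whose
  truth NEE is Reco. Mixing ratios are back-computed from truth through the
  inverted flux equation (dilution-corrected for H₂O), then Gaussian noise
  is added on the flux scale (defaults 0.5 µmol, 0.05 mmol). Isotope
  observations are built so the exact inversion chain (mass balance →
  Craig–Gordon → steady state → endmember mixing) returns true ft before
  noise; δ noise (default 0.3‰) is added to each observable. Source water
  sits near −8‰ per plot, soil water near −3‰ enriching over the season,
  and background vapor near −18‰, keeping |δ_T − δ_E| ≥ 5‰ so the
  partition is well conditioned. The eddy series is the true control flux
  plus a configurable additive daily-sum bias (defaults +0.6 g C m⁻² d⁻¹,
  +0.2 kg m⁻² d⁻¹, spread uniformly over the 48 half-hours) plus
  half-hourly Gaussian noise; a recovered calibration offset of −bias is
  therefore the expected answer.

**Design choices made for internal consistency.** The world is built so
that, with all noise SDs zero, the full pipeline reproduces the truth
season sums (observed worst error ≈ 0.14%, dominated by smoothing and
quadrature): respiration responds to the daily-mean rather than
instantaneous temperature, and radiation has no day-to-day synoptic
variability, because the night-extrapolation rule and nearest-neighbour
offset interpolation are only exact when night fluxes are flat and
between-campaign variation is smooth. Campaigns are evenly spaced by
default for the same reason (an uneven field schedule can be passed
explicitly).

**What passing tests therefore do not show.** Real nights have temperature-
driven respiration cycles, real radiation is intermittent, real offsets
drift between campaigns, δ noise can be structured, and leaf water is
rarely at perfect isotopic steady state at dawn or dusk. Recovery results
on the synthetic world demonstrate correctness of the computations and
well-behavedness of the estimators, not field accuracy of the method.

## Numerical choices and degenerate inputs

* Loess falls back to linear interpolation (flagged) below 4 points; local
  fits use a centred Vandermonde basis and `lstsq` for conditioning.
* Partition conditioning threshold 1‰ on |δ_T − δ_E|; clamping flagged.
* Ties: dark-record pairing and offset interpolation both resolve exact
  ties to the earlier record, so results are order-independent.
* All-dark days carry zero GPP/T sums; an empty photoperiod is not an
  error.
* Craig–Gordon with h ≥ 1, mass balance with w_out ≤ w_in, and WUE with a
  zero denominator all return NaN with a machine-readable flag.
* Written tables use fixed 6-decimal formatting, so a given seed produces
  bit-identical files across platforms.

## Problem sizes

The bundled experiments use one 183-day season (8784 half-hours), 10
campaigns × 4 treatments × 3 plots (≈ 6700 chamber records, ≈ 3400 isotope
records), 200 replicate campaigns for the partition-recovery experiment,
and 10 campaigns for offset recovery. A full end-to-end run takes a few
seconds on one core.

## Known limitations

Only ¹⁸O is implemented (no ²H, no dual-isotope consistency check); no
leaf-water Péclet/non-steady-state model; no light-response gap-filling of
NEE; offsets are additive only; the generator does not model soil-water
dynamics, plant growth, or community composition — treatment effects are
imposed, not emergent.
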