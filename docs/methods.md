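# Methods

## Model

The package values a catchment's ecosystem services through a cascade
with the function step kept implicit: land-cover *structure* →
biophysical *flow* → monetary *value*.  Its assumptions are deliberately
minimal:

1. Pooled CORINE land cover, plus a handful of river and beneficiary
   metrics, is a sufficient indicator of ecosystem structure.  Land
   cover enters as tabulated areas in hectares — no rasters, no
   polygons.
2. Fifteen CICES 5.1 final services cover what matters at catchment
   scale; each is valued by a single linear rate or a threshold
   knowledge rule (benefit transfer where no local estimate exists).
3. Monetary values (approximately 2010 euros, no purchasing-power
   correction) are comparative indicators, not absolute welfare
   measures.  Provisioning services use net farmgate revenue, regulating
   services avoided cost, cultural services stated willingness to pay.

Every value is normalized by total catchment area (€ ha⁻¹ yr⁻¹) so that
services with different footprints are additive; the per-ha values are
therefore homogeneous of degree zero under joint scaling of all areas,
counts and generation rates, which the test suite checks.

### CORINE pooling

The pooling of level-3 CORINE codes into nine working classes is a
documented package default (see `escascade/data/corine_pooling.csv`):
211/212/213 → cropland, 231/321 → grassland, 312 → coniferous forest,
311/313 → deciduous forest (mixed forest is pooled with deciduous so
its carbon uses the more conservative rate), 411/412 → wetland,
111/112/121 → built-up, 511/512 → open water, remaining common codes →
other.  Riparian woodland is *not* a CORINE class: the valuation treats
it through the proportion of river length with riparian cover, so it is
supplied directly as an area plus `RiverMetrics.riparian_fraction`.
"Woodland" in the knowledge rules means coniferous + deciduous +
riparian woodland; "forest" (timber, scenic rule) excludes the riparian
strip.

### Knowledge rules and double counting

Pest control and riparian shading are modulations of other services.
To keep TEV additive, the modulated totals sit on the provisioning and
cultural lines (crops carry the 80% productivity when woodland is
scarce; angling carries the survival-modulated WTP) and the regulating
lines credit only the increment over the degraded floor: pest
regulation = crop revenue × (factor − 0.8), temperature regulation =
angler WTP × (survival − 0.1).  Users who prefer the pure modulation
reading can ignore those two regulating lines; nothing else depends on
them.

The "stepwise decline" of trout survival below the 50% shading
threshold is interpreted literally: the shaded fraction is floored to
0.1 steps, then survival interpolates linearly from the 10% residual at
zero shade to 100% at the threshold (0.25 shade → step 0.2 → survival
0.46).  All threshold comparisons are strict (`< 25%`, `below 20%`,
`above 70%`); boundary values take the non-degraded factor.  Drinking
water uses a 365-day year.

### Parameters

All unit values, rates and thresholds live in `ServiceParameterSet`
(defaults in `escascade/data/default_parameters.yaml`); any field can
be overridden per scenario.  The ones that matter most in practice:

| parameter | default | unit |
|---|---|---|
| crop_revenue / dairy_revenue | 400 / 500 | € ha⁻¹ yr⁻¹ |
| timber_annuity | 200 | € ha⁻¹ forest yr⁻¹ |
| c_seq coniferous/deciduous/riparian | 6 / 5 / 4 | t C ha⁻¹ yr⁻¹ |
| carbon_price | 5 (20 under NBP1) | € t C⁻¹ |
| p_price | 1.1322 | € kg P⁻¹ |
| erodible P grassland/cropland | 1 / 2 | kg P ha⁻¹ yr⁻¹ |
| flood damage built/agri/wood | 252 / 7 / 1 | € m⁻² |
| flood depth factor / annualization | 0.2 / 0.01 | – |
| instream_p_retention | 10 | kg P km⁻¹ yr⁻¹ |
| wtp_angler | 275 | € angler⁻¹ yr⁻¹ |
| tev_relative_standard_error | 0.24 | – |

The hydropower value follows the stated formula (generation ×
0.05 € kWh⁻¹ / catchment area); published per-ha hydropower figures
derived from the same inputs are not internally consistent with that
price, and this package does not attempt to match them.

## Scenarios

A scenario is data, not code: either target land-cover fractions
(summing to 1) or hectare deltas (summing to 0), optional river-metric
overrides, and sparse parameter overrides.  Total area is conserved;
land-use intensity effects are out of scope by design.  The packaged
NBP0–NBP5 files are *stylized* articulations of the pathway narratives
(NBP1 diversifies toward grassland/riparian/wetland and prices carbon
at 20 €; NBP3/NBP5 intensify toward cropland and production forest;
NBP4 urbanizes at the margin); users holding the original per-scenario
land-cover workbook can import it (`import-s1`) for exact
reproduction.

## Significance screen

"Relative difference" between two accounts is mean-normalized,
|b − a| / ((a + b)/2) — symmetric and bounded — with `baseline` and
`max` normalizers available.  The ratio of this to the benchmark
relative standard error of TEV estimates (0.24, from a comparable
multi-case study) flags a line as likely significant when above 1.
A line that is zero in both accounts has ratio 0 by convention.  This
screen is a coarse plausibility filter, not a hypothesis test; no
Monte-Carlo uncertainty propagation is attempted.

## Synthetic catchments

The generator emulates two archetypes so that every stage is testable
without data downloads:

* `cropland_small` — 470 ha default, cropland fraction drawn in
  (0.65, 0.80), drains directly to the sea (hence zero flood
  prevention), no hydropower or drinking-water extraction, a few
  hundred households.  The small first-order agricultural catchment
  case.
* `forest_large` — 150,000 ha default, forest fraction in (0.55, 0.75)
  split ~70/30 coniferous/deciduous, hydropower fixed at 9 GWh yr⁻¹ and
  drinking water at 2700 m³ day⁻¹ (the reported magnitudes for this
  catchment type), floodplain 100–400 ha, flood-P sedimentation
  500 kg P yr⁻¹ (a mid-range choice consistent with the 10 kg P km⁻¹
  in-stream rate over a ~100 km main river; the study's exact
  per-event figure is only in its supplementary workbook).  Household
  counts (10–18k) match a mid-sized Nordic municipality.

All draws flow from one integer seed (`numpy.random.default_rng`); a
fixed seed is bit-reproducible.  What the generator does **not**
emulate: spatial arrangement (the model has none), correlations between
land cover and beneficiary counts, inter-annual variability, or the
real study catchments' exact land-cover tables.  Passing tests
therefore demonstrate the accounting machinery and the direction of
scenario effects, not site-specific magnitudes.

## Numerical choices

* Area bookkeeping tolerance: relative 1e-6 on "class areas sum to
  catchment area", corridor shares and scenario fraction/delta sums;
  scenario application conserves area to better than 1e-9 relative.
* Target-fraction scenarios renormalize the sub-ppm rounding slack so
  the projected areas sum exactly to catchment area; delta scenarios
  leave untouched classes bit-identical.
* The trout-survival step floor uses `floor(10·s + 1e-9)/10` so that
  values like 0.3 stored as 0.2999… land on their intended step.
* Computation is in full precision; report CSVs round only at write
  time (default 2 decimals in the CLI, lossless in the library
  writers).
* Degenerate inputs fail loudly with `ValidationError`/`InputError`
  naming the offending field, class or CORINE code; the CLI maps these
  to exit code 2, unexpected errors to 1.

## Known limitations

No spatial disaggregation or routed flows; no land-use intensity
effects; no uncertainty propagation beyond the RSE screen; no
beneficiary-group distributional analysis; benefit-transfer values are
comparative, not absolute.  The significance multiples reported by any
particular study depend on its (often unstated) normalization and
should not be expected to match this package's mean-normalized ratios
exactly.
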