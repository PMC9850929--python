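# Methods

## The estimation problem

Domestic open burning of plastic waste is a source of fine particulate
matter (PM2.5), black and organic carbon (BC, OC), CO and CO2 that
national emission inventories typically omit. `openburn` implements a
bottom-up estimation chain for this source:

1. **Survey statistics.** A household survey records the mass of plastic
   waste each household set aside over four weekly collections, household
   size, the primary disposal method, education, and asset ownership.
   From these we compute weekly mass summaries, per-capita daily
   generation rates, the share of households (and of generated mass)
   attributable to burning, and significance tests for covariate effects.
2. **Burned-mass models.** The per-capita daily rate is annualized and
   scaled by the fraction of households that burn waste — used as a proxy
   for the fraction of generated plastic that is burned — at community,
   city, department, and national levels. Two generation scenarios
   bracket the unknown national rate: a *lower bound* from the field
   survey (12.2 ± 5.8 kg/capita/yr) and an *upper bound* from a published
   national point value (29.3 kg/capita/yr, no distribution available).
3. **Monte Carlo propagation.** Per-species emissions follow
   E_i = M × EF_i, with burned mass M (kg/capita/yr) and emission factor
   EF_i (g per kg plastic burned) modelled as independent normals; the
   emission distribution is formed from one million paired draws.
4. **Inventory comparison.** National plastic-burning totals are
   expressed as percent increases over a national inventory baseline
   (EDGAR v5.0 totals, which exclude domestic open burning), per species
   and bound, plus the gap between the bounds.

## Model assumptions

- **Independent normals for M and EF.** Both uncertainties are modelled
  as normal and uncorrelated. Negative draws are *not* truncated: the
  closed-form product-of-normals moments
  (mean = μ_M μ_F, var = μ_M²σ_F² + μ_F²σ_M² + σ_M²σ_F²)
  hold only for the untruncated product, and the published per-capita SDs
  match that closed form. A `truncate_negative` switch exists as a
  diagnostic; it biases the mean upward and is off by default. The
  fraction of negative draws is reported per cell (it is material for CO,
  whose EF has sd/mean ≈ 0.82) and follows
  p_M(1−p_F) + p_F(1−p_M) with p = Φ(−μ/σ).
- **Burn-fraction proxy.** The fraction of households whose primary
  disposal is burning multiplies the per-capita generation rate. This is
  justified empirically: in the survey, burning households contribute a
  mass share (~80%) close to their household share (~84%).
- **Shared uncertainty across aggregation.** The generation rate and each
  EF are *global* random variables. Department and national quantities
  are linear scalings of one shared draw vector per (bound, species) — a
  department's per-capita estimate is the national draw vector times its
  burn fraction, and the national total is the draw vector times the
  effective burning population C = Σ_d population_d × burn_fraction_d.
  Relative SD is therefore preserved exactly through aggregation; summing
  independent per-department draws would instead shrink the national
  relative SD far below the ~50% the totals carry.
- **Additive baseline.** The inventory is treated as exact and free of
  this source, so percent increase = 100 × total/baseline with the SD
  scaled the same way. The bound gap is the difference of the two mean
  percent increases; its quadrature-combined SD is reported for
  orientation only (the bounds share the EF uncertainty, so quadrature
  overstates the spread).

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| survey rate (all households) | 3.34e-2 ± 1.58e-2 | kg/person/day | lower-bound generation |
| survey rate (burners only) | 2.66e-2 ± 1.32e-2 | kg/person/day | community burned mass |
| upper-bound generation | 29.3 (point) | kg/capita/yr | upper scenario |
| days per year | 365 | d | annualization |
| days per week / weeks | 7 / 4 | d | per-capita rate denominator |
| city burn fractions | Guatemala city 0.280, Jutiapa 0.875 | – | city burned mass |
| EF table | 5 species, back-derived | g/kg | see below |
| MC draws | 1,000,000 | – | per (region, species) cell |

The two published passages on city collection/burning rates conflict
(each assigns 87.5% and 28.0% to the opposite city). The default mapping
(Jutiapa burns 87.5%) is the one consistent with the downstream burned
masses of 7.87 and 13.5 kg/capita/yr; the alternate mapping is kept in
`CITY_BURN_FRACTIONS_ALTERNATE` and selectable via
`RunConfig(city_mapping_alternate=True)` so the conflict stays visible
rather than silently reconciled.

### Emission factors

The packaged default EF table covers PM2.5, BC, OC, CO and CO2,
back-derived by inverting E = M × EF on the published Guatemala-city
per-capita emission row, whose burned mass (7.87 kg/capita/yr) is a point
value, making the division exact for both mean and SD
(e.g. PM2.5 ≈ 83.7 ± 12.7 g/kg, CO2 ≈ 2579 ± 158 g/kg). Back-derivations
from the community and Jutiapa rows agree within 1%, consistent with a
single EF distribution underlying all regions. The full 62-species table
from field burn measurements is user-supplied via `ef_table.csv`
(columns `species, ef_mean_g_per_kg, ef_sd_g_per_kg, source`); each EF is
an independent normal with no cross-species correlation.

## Survey-statistics choices

- Tests run on natural-log masses (the raw totals are right-skewed);
  group differences are reported on the raw-kg scale.
- The two-sample test is Welch's (unequal variance), two-tailed. Weeks
  are compared as independent samples, not paired, although households
  repeat across weeks.
- Zero masses are excluded from log transforms with a logged count; no
  offset is added, since offsets distort small values.
- The per-capita rate is the unweighted mean/SD of household-level rates
  (total mass over persons × 7 × observed weeks), not pooled mass over
  pooled person-days: the published SD describes between-household
  spread.
- Education (4 levels) uses one-way ANOVA on log totals; its reported
  kg "difference" is the mean absolute pairwise difference of category
  means, since a two-group contrast does not exist.
- Missing weeks are excluded from that week's summary and from the rate
  denominator — never zero-filled, never imputed.

## Synthetic data: what it emulates and what it does not

No household microdata or departmental census table can be shipped, so
generators provide stand-ins with known ground truth:

- **Households** (`SurveyGenSpec`): weekly masses are lognormal with the
  published weekly means/SDs (1.31/0.66, 1.12/0.91, 0.92/0.70,
  0.99/0.77 kg), so the declining weekly trend is built in; an optional
  extra multiplicative `week_trend` operates on the log scale, keeping
  the log-scale tests well calibrated on synthetic nulls. Household sizes
  follow a discrete distribution with median 6 whose E[1/size] is chosen
  so the implied mean per-capita rate is exactly the published
  3.34e-2 kg/person/day — the mean of total/(28 × persons) is driven by
  E[1/size], and matching both the size median and the rate mean
  constrains the distribution's low tail. Asset effects (e.g. colour TV
  −1.21 kg on the 4-week total) are additive and *mean-centred*
  (effect × (indicator − prevalence)), so the owner-vs-non-owner contrast
  equals the injected effect while weekly marginal means stay on target;
  masses are clipped at zero, a negligible distortion at the default
  effect sizes. Optional knobs inject zero masses, missing weeks, and a
  latent (Gaussian-copula) size–mass correlation.
- **Census** (`CensusGenSpec`): 22 departments with lognormal populations,
  uniform rural fractions, and burn fraction = a + b·rural + noise,
  clipped to [0,1]. `CensusGenSpec.calibrated(target_r2)` sets the noise
  SD so the expected regression R² equals the target
  (sd = |b|·sqrt(Var(rural)(1−R²)/R²)); `target_effective_population`
  rescales populations so C matches a chosen value — the analysis default
  calibrates C to 193 Gg / 29.3 kg/capita/yr, which makes the national
  chain land on the published 193 / 80.2 Gg totals.
- **EF tables** (`gen_ef_table`): log-uniform means over several orders of
  magnitude with SDs a random fraction of the mean, for 62-species-scale
  capability tests.

Deliberate departures from real data: burning status, assets, education
and household size are drawn independently of the masses (the survey
itself found size and mass essentially uncorrelated, r = −0.08); the
generator's between-household rate SD (≈2.3e-2) is heavier than the
published 1.58e-2 because weekly masses are drawn independently within a
household; and no intervention mechanism is simulated — the declining
weekly means are reproduced as marginal targets, not as a causal effect.
Passing tests therefore demonstrate that the pipeline recovers known
parameters under the stated distributional conditions, not that those
conditions describe any particular community.

## Numerical choices

- One root seed; per-(region, species) child streams are derived via
  CRC-32 labels fed to NumPy's `SeedSequence`, so adding a species or
  region never perturbs existing draws, and repeated runs are
  byte-identical.
- Histogram binning uses Freedman–Diaconis on the draw vector.
- Paper-facing report values are rounded to 3 significant figures;
  machine CSVs keep full precision (`repr` round-trip).
- Degenerate inputs: sd = 0 normals are handled as point masses;
  a constant burned mass across departments yields slope 0 and R² = 0 by
  definition (nothing to explain); a covariate constant across the cohort
  or a group with fewer than two households raises a named error.
- One published department-level CO2 SD cell (lower bound, 15.6 ± 0.747)
  is inconsistent with the closed form, which gives ≈7.47 — an apparent
  factor-of-10 slip; the closed-form value is asserted. Likewise the
  lower-bound CO2 percent-increase SD prints 0.369 where its own printed
  totals give 0.269; the recomputation is asserted.

## Problem sizes

Monte Carlo cells use 10^6 draws (matching the published methodology);
test-suite calibration runs use 10,000 null replicates for the type-I
error of the log-scale Welch test, 200 census replicates for the R²
recovery, and cohorts of 1,000–10,000 households for parameter recovery.
A full pipeline run at 10^6 draws completes in well under a minute.

## Known limitations

- Upper-bound city estimates assume all uncollected waste is burned, an
  upper bound by construction; burial and dumping routes are not
  modelled.
- EFs are borrowed from field burns elsewhere in the Global South; no
  local EF measurements exist.
- The inventory baseline is treated as exact; its own uncertainty is not
  propagated.
- The bound-gap SD has no principled combination rule (the bounds share
  EF uncertainty); the quadrature value reported is an upper bound on the
  spread.
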