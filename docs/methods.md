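# Methods

## The assessment model

`dietexpose` implements a deterministic (point-estimate) dietary exposure
assessment of the kind used in food-contaminant surveillance programs.
The inputs are a table of laboratory concentration measurements — one row
per food sample, possibly left-censored at the method's limit of
detection (LOD) — and a consumption survey — one row per person and food
category, in g/day. The outputs are descriptive summary tables,
residue-limit exceedance rates, and per-age-group exposure estimates.

For age group *g* with standard body weight *bw_g*, and food categories
*f* with mean concentration *C_f* (mg/kg) and group consumption summary
statistics *Q_{g,f}* (mean, g/day) and *Q95_{g,f}* (95th percentile):

```
E_mean(g) = Σ_f  C_f · Q_{g,f}   / 1000          (mg/day)
E_p95(g)  = Σ_f  C_f · Q95_{g,f} / 1000          (mg/day)
W(g)      = E(g) · 7 / bw_g                      (mg/kg bw/week)
MOS(g)    = W(g) / PTWI                          (ratio)
```

`MOS ≥ 1` flags unacceptable risk. Note the sign convention: this margin
of safety *grows* with exposure — it is intake divided by the
health-based guidance value, inverted relative to some other uses of the
term. Per-food contribution percentages are each food's share of the
group's mean daily exposure; they sum to 100 before rounding.

The P95 variant deliberately combines the *mean* concentration with the
*P95* consumption food-by-food and then sums. Summing per-food 95th
percentiles is not the 95th percentile of the total — a high consumer of
flour is rarely also a high consumer of jellyfish — so `E_p95` is a
conservative high-consumer screen, not a distributional quantile. It is
kept because it is the standard deterministic-screening convention, and
the package asserts no ordering between `E_p95` and `E_mean` terms.

## Censoring

Nondetects are handled by the GEMS/Food substitution rule: when the
nondetect rate of a stratum is below 60%, each nondetect is replaced by
half its own LOD. The rate is evaluated per food-type × year stratum
(LODs shift across years as methods improve, and the summary tables are
built per stratum). A stratum at or above 60% raises an error rather
than silently falling back — the substitution rule has no stated
validity there, and imputing most of a stratum at LOD/2 would dominate
its mean. Substitution is idempotent and never alters detected values.

On data generated from a lognormal left-censored at LOD *L*, the imputed
sample mean estimates

```
E[X · 1{X ≥ L}] + (L/2) · P(X < L)
```

which `simulate.censored_halflod_mean` evaluates in closed form via the
lognormal partial expectation; the tests check the same quantity by
numerical quadrature independently of that formula.

No maximum-likelihood or Kaplan–Meier censored estimators are provided:
the pipeline exists to reproduce and extend substitution-based
surveillance reporting, and mixing estimators would change what the
summary tables mean.

## Key parameters

| parameter | unit | default | why |
|---|---|---|---|
| residue limit | mg/kg | 100 | regulatory maximum for aluminum in flour, aquatic and puffed foods (GB2760-2011); exceedance uses strict `>` |
| PTWI | mg/kg bw/week | 2 | JECFA (2011) provisional tolerable weekly intake for aluminum |
| censoring threshold | fraction | 0.6 | validity bound of the LOD/2 substitution rule |
| age groups | years | [2,8), [8,13), [13,20), [20,50), [50,66), [66,∞) | dietary-reference-intake groupings; infants (<2 y) excluded |
| standard body weights | kg | 20, 40, 50, 60, 60, 60 | fixed per-group normalization weights |
| rounding | decimals | 2 | applied half-up at the report boundary only |

All internal arithmetic is full precision; rounding happens once, when a
report is written. This matters: the reference intake table's MOS of
9.09 for the youngest group is `round(51.97·7/20/2) = round(9.0948)`,
which a pipeline that rounded the weekly intake first would miss.

Quantiles use linear interpolation between order statistics at
probability positions `(k−1)/(n−1)` (the numpy default). Published
surveillance tables rarely state their quantile convention, so the
headline reproductions here are arranged to take printed quantiles as
*inputs* rather than recompute them. Standard deviations use the `n−1`
denominator; a single observation reports SD 0. Pooling across strata is
sample-size-weighted for means and additive for exceedance counts, which
makes pooled figures exactly equal to statistics of the concatenated
samples; SDs are not pooled (that would need within-stratum sums of
squares the summary objects do not carry).

## Reference aggregates

`fixtures.reference_aggregates()` packages the printed summary tables of
a six-year (2010–2015) aluminum surveillance program in Tianjin: yearly
and per-food concentration summaries over 1,263 samples, consumption
summaries from a 1,814-person survey, and the per-food exposure matrix
by age group. Only aggregates were published, so these serve as exact
fixture inputs for the deterministic arithmetic while the raw-data path
is exercised on synthetic data.

Two internal inconsistencies of the source tables are preserved rather
than repaired: (a) the per-food exposure columns do not always sum to
the printed totals row (off by one rounding unit for four of the six
groups; recomputing from the columns therefore shifts two rounded
report cells — the 8–13 y mean MOS to 4.34 and the 66+ y mean weekly
intake to 8.66); (b) the narrative text gives the flour-products
consumption SD as 149.95 where the table prints 145.95 — the fixture
carries the table value.

## Synthetic data

The generator is the testing counterpart of the assessment's
assumptions, not a calibration target:

- **Concentrations** are lognormal per food type, left-censored by
  thresholding at the food's LOD (a draw below the LOD becomes a
  nondetect with no value — matching a substitution-only treatment,
  with no separate detection model). Lognormality is the minimal
  right-skewed stand-in consistent with surveillance summaries whose
  means sit far above their medians.
- **Consumption** is zero-inflated gamma per person and food: a point
  mass at zero for never-consumers (survey tables show P25 = 0 for
  several foods) and a gamma amount otherwise. Ages are drawn uniformly
  within the assigned group (capped at 90 y for the open-ended group).

Default parameters per category are set once to resemble a metropolitan
surveillance program: staple flour foods with high, heavy-tailed
concentrations and near-universal consumption; condiment-like foods
(jellyfish, algae) with high concentrations but rare, small consumption;
low concentrations in fresh aquatic products. Expected nondetect rates
stay below ~0.36 per category so strata sit well under the 60% ceiling.

What the generator does *not* emulate: the multistage cluster design of
a real survey (no household or community correlation, no design
effects), within-person day-to-day variation, correlation between foods
in a diet, or LOD drift across years. Passing recovery tests therefore
show the *arithmetic* is right under the stated distributional
assumptions — they say nothing about survey-design bias in real data.

## Numerical and design choices

- Age intervals are half-open `[min, max)`; group assignment is exact on
  boundaries (an 8-year-old is in the 8–13 group).
- Exceedance is strictly greater than the limit, matching the
  ">100 mg/kg" column convention of surveillance tables.
- Contribution denominators are per age group. Whole-population
  contribution shares would need person-level survey weights that
  aggregate tables do not provide, and are out of scope.
- The censoring summary stores a single substitution value when the
  stratum has one LOD and NaN when LODs are mixed; imputation always
  uses each record's own LOD regardless.
- Reports are written atomically (temp file + rename) with a run
  manifest (input paths, config hash, seed, timestamp, version).
- CLI exit codes: 0 success, 2 validation/config failure, 3 I/O failure.
- Table parsing collects *all* offending rows before failing, so input
  row count always equals parsed + rejected.

## Problem sizes used in checks

The deterministic reproductions run on the printed aggregates directly
(six yearly strata, ten food categories, six age groups; well under a
second). The stochastic recovery check uses 1,000 concentration samples
per food and 5,000 survey persons, which leaves the pooled exposure
estimate with a relative standard error around 10% (dominated by the
heavy-tailed flour-products concentration) and tests recovery at ±3
standard errors; distributional unit checks use 10,000 draws.

## Limitations

- Point estimates only: no Monte Carlo exposure distributions, no
  uncertainty intervals on MOS.
- The LOD/2 convention is biased when censoring is heavy or the
  below-LOD mass is far from LOD/2; the 60% guard bounds but does not
  remove this.
- Standard body weights, not measured ones; results are per-group
  normalizations, not individual risk estimates.
- Inferential statistics (between-year or between-food hypothesis
  tests) are out of scope; the package produces the descriptive tables
  such tests would consume.
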