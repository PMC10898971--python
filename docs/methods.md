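# Methods

`flukemr` estimates the abundance trend of a migratory, photo-identifiable
whale population from an archive of encounter records (individual ID, date,
position), using a rolling pooled two-occasion Chapman–Petersen design with
a resampling-based correction for uneven geographic survey effort.  This
note documents the model, its assumptions, the tunable parameters, the
synthetic-data generator used to test it, and the numerical conventions.

## Capture histories

An *encounter* is one photographic identification.  Each date is assigned
to a season-year: winter of year *y* spans 16 October (*y*−1) through
15 May (*y*) with midpoint 1 March, and summer of *y* spans 16 May through
15 October with midpoint 1 August.  The source convention gives only the
two midpoints; our window boundaries split the gap between them
symmetrically and are configurable.  All of an individual's encounters
within one season-year are condensed to a single *capture*, keeping the
encounter closest to the seasonal midpoint (ties resolved to the earlier
date, which makes condensation deterministic and independent of row order).
The surviving encounter also fixes the individual's geographic stratum for
that season-year.

Strata are named regions classed as wintering (breeding, south of a 32°N
split by default) or summer (feeding, north of it).  The bundled default
stratification is a set of 13 coarse lat/lon boxes (7 feeding, 6 breeding)
covering the North Pacific regions commonly used for this species; users
can supply exact polygons in YAML.  Encounters that fall in no stratum, or
in a stratum of the opposite season class (e.g. a feeding-ground position
dated mid-winter), are excluded from estimation and counted in the
condensation report — this preserves the independence of the winter and
summer occasions.

## Abundance estimation

The estimation window labelled by mid-year *t* pools winters
{*t*−1, *t*, *t*+1} as capture occasion 1 and summers {*t*−1, *t*} as
occasion 2.  With n₁ and n₂ unique individuals per occasion and m seen in
both, the Chapman bias-corrected Petersen estimator is

    N′ = (n₁+1)(n₂+1)/(m+1) − 1,

nearly unbiased for a closed population when E[m] is moderately large.
Data years 2001–2022 yield 20 overlapping annual windows (2002–2021).
Windows are never edge-clipped: a range of *k* years yields *k*−2 windows.
The closed-population assumption is approximated, not met, by a population
with births and deaths; the three-year pooling trades a small closure bias
for much larger samples, and the two occasions exploit the behavioural and
geographic separation of breeding and feeding seasons to decouple capture
heterogeneity between occasions.

## Geographic-sampling bias correction

Pooled two-occasion estimates are robust to capture heterogeneity in one
occasion, but biased when under-sampling is *correlated* across occasions —
exactly what happens when a region's breeding and feeding grounds both go
unsurveyed for a stretch of years.  The correction anchors each window to a
reference capture set collected under representative effort with known
abundance N_ref (default 21 063, CV 0.04, the 2004–2006 reference window
with mid-year 2005).  For each target window *t*:

1. count unique individuals per (stratum, season) in the reference window
   and in the target window;
2. take the element-wise minimum — the largest common sample size (LCSS);
3. randomly subsample both capture sets, without replacement, down to the
   LCSS in every cell, giving them identical geographic sample-size
   distributions;
4. compute the Chapman estimate on the subsampled reference
   (N_alt); then F_t = N_ref / N_alt measures the bias the target's
   sampling pattern would induce, and N_t = N′_t × F_t.

Design choices that were genuinely open:

* **Source of N′_t.**  We compute N′_t on the LCSS-subsampled target, so
  both datasets share identical per-stratum sample sizes and the ratio
  interpretation of F_t is exact; `uncorrected_source="full"` switches to
  the full-window Chapman estimate.  With the default, running the pipeline
  with target = reference returns N_ref *exactly* (the LCSS is the full
  count table and no randomness enters), which is the anchoring property
  the tests check.
* **Replicates.**  Whether the original procedure drew one subsample or
  several is unknowable from a 2-d.p. F value; we draw 25 replicates by
  default (configurable), report the replicate mean of N_alt and N′, and
  expose the replicate spread.  Replicates with zero matches in a subsample
  are discarded with a warning.
* **Subsampling unit.**  The unique individual within a (stratum, season,
  window) cell.  An individual appearing in two strata across the pooled
  years is selected independently per cell; its records elsewhere survive
  only if those cells also select it.

## Uncertainty

Standard errors come from a delete-d jackknife: each of n = 20 replicates
drops ⌊5%⌋ of the condensed capture records uniformly without replacement
(fresh draw per replicate), re-runs the full estimator — including the bias
correction — and

    s.e. = sqrt((n−1)/n · Σᵢ (x̂ᵢ − x̄)²).

Dropping is global across strata by default; a `stratified` option drops
proportionally within each stratum (the source phrasing is ambiguous
between the two; its per-stratum wording describes the deduplication step,
so global is our default).  The reference capture set is held fixed during
jackknifing: the reference estimate's own uncertainty enters separately, as
the CV of the corrected estimate combined in quadrature,
cv_total = sqrt(cv_jack² + cv_ref²), with cv_ref = 0.04 by default.
This is a delete-d jackknife with random d, not leave-one-out; its SE is an
approximation whose coverage we check by simulation rather than assume.

## Trend summaries

Raw year-over-year rates are r_t = N_t/N_{t−1} − 1.  The smoothed ΔYoY
column is the year-over-year change of the centred 3-year moving average of
abundance; recomputing from the published corrected series, this definition
reproduces the printed interior values to ±0.1 percentage points, whereas a
moving average of the raw rates does not, so we adopt it.  At the series
ends the moving average is truncated to the available terms and the
affected entries carry an `end_truncated` flag (the published end values
follow no single consistent rule).  Period growth rates are arithmetic
means of ΔYoY entries over stated year ranges; headline percent changes are
100·(N_b − N_a)/N_a rounded to the nearest whole percent.

## Regional indices and migration tests

A regional pair couples one wintering stratum (three pooled winters,
occasion 1) with its main feeding strata (two pooled summers, occasion 2).
The resulting Chapman series carries no bias correction and is an *index of
relative abundance* only — the wintering sample is not assumed to be a
random draw from all contributing feeding areas — and is never summed with
basin-wide estimates.  Jackknife SEs for a pair use only that pair's
records.

The share of one region in the combined index of two regions is summarised
by an OLS line (share ~ mid-year); the slope is reported in percentage
points per year with the F-test p-value of a non-zero slope (equivalent to
the slope t-test; this is our concrete reading of an otherwise unspecified
"ANOVA" on the proportion series).  A perfectly constant share series is
reported as slope 0, p = 1.

Migratory stability is tested with a 2×3 destination table: for each of two
time periods, the individuals captured in a focal feeding area during the
period's summers are cross-matched to winter captures in two destination
regions, counting destination A, destination B, and both.  Following the
reporting convention of the source tables, the A and B columns each include
the "both" individuals; the Pearson chi-square (no continuity correction)
is computed on the table as reported, which reproduces the published
statistic but mildly violates the independence assumption of the test — an
`overlap="exclusive"` variant with disjoint columns is available.  For
df = 2 the upper-tail p equals exp(−χ²/2), which the tests use as a
closed-form cross-check.  The pipeline drops destination columns with a
zero margin (e.g. an empty "both" column in simulations with strict site
fidelity) before testing.

## Synthetic-data generator

The simulator is an individual-based model used as the test harness for
every pipeline stage.  Each individual has a fixed breeding stratum and a
feeding stratum drawn once from a breeding→feeding fidelity matrix (rows
sum to 1); strong natal philopatry justifies holding both fixed across
years (an optional switching rate, default 0, relaxes this).  Each year
every survivor is present in its wintering stratum in winter (an optional
per-year presence probability, default 1, models non-annual migration) and
its feeding stratum in summer.  Detection is an independent Bernoulli draw
per (individual, season, year) at p(stratum) × effort(year); a detected
animal emits 1–3 encounter rows dated within ±60 d (winter) or ±45 d
(summer) of the season midpoint, at uniform positions inside the stratum
box (10% inset).  Demography is survival s = 0.96 plus per-capita
recruitment chosen to hit a target growth rate: +6%/yr before a pivot year
(2013), −3%/yr after; recruits appear as identifiable adults one year after
birth, so N(t+1) = survivors(t) + recruits(t) holds exactly and is asserted
by tests.

Default conditions emulate the study system: season-years 2001–2022,
initial abundance 15 800 across six breeding strata (Hawai'i and Mainland
Mexico dominant), the 13 default strata, strongly heterogeneous per-stratum
detection probabilities (0.005 in rarely surveyed regions to 0.12 in
well-worked ones) and a linear effort ramp from 0.6× to 1.4× over the
study, giving per-stratum seasonal sample sizes of the same order as the
real archive and ~30 000 distinct animals over the run.  The
`heatwave_scenario` helper overlays a pulse of reduced survival
(−0.04 during 2014–2016) and persistently reduced recruitment on any base
configuration.  `splash_like_reference` packages the simulation's own
2004–2006 window as a reference whose N_ref is the true mid-window
abundance, enabling end-to-end correction tests with a known answer.

What the generator does **not** emulate: within-stratum spatial structure,
environmental covariates and prey dynamics, calf-specific detection,
misidentification or missed matches (IDs are exact), and inter-annual
individual heterogeneity in capture probability beyond stratum membership.
Passing tests therefore demonstrate the estimator's arithmetic, the
correction's mechanics and its efficacy against *geographic* sampling bias;
they do not certify robustness to identification error or individual
trap-response, which the real archive may contain.

## Problem sizes and numerical conventions

Tests and the acceptance script run scaled-down configurations chosen to
exercise every code path while keeping the suite quick: a quarter-scale
2003–2010 population (~4 000–6 000 animals) for unit and integration
fixtures, a two-stock ~2 500-animal population over 7 years × 100
(respectively 60) replicates for the bias-correction efficacy check, and an
eighth-scale 2001–2022 population (~2 000–4 000 animals) for the end-to-end
growth-then-decline pipeline run.  Chapman near-unbiasedness is checked
with ≥1 200 vectorised two-occasion draws at N = 5 000, p = 0.25/occasion
(E[m] ≈ 312).

All randomness flows through `numpy.random.Generator`; the pipeline spawns
independent child generators per window so results are reproducible
end-to-end from one seed and invariant to input row order (capture records
are canonically sorted before resampling).  Validation failures raise
`ValidationError` (CLI exit 2) and estimation failures `EstimationError`
(CLI exit 3).  Degenerate inputs have defined behaviour: an empty capture
occasion warns and evaluates the formula; an empty union rejects the match
rate; a constant share series returns slope 0 with p = 1; zero-margin
chi-square tables are rejected.

## Known limitations

* The default stratum boxes are coarse; analyses of real archives should
  supply survey-accurate polygons.
* The correction assumes the reference window is itself representatively
  sampled and that the population's geographic distribution is stationary;
  a genuine redistribution of animals (which the share-trend diagnostic is
  designed to flag) leaks into F_t as bias.
* The delete-d jackknife SE is an approximation; simulation puts its CV
  within a factor of ~3 of the analytic Chapman CV and its ±2 s.e.
  interval coverage in a wide (85–99%) band, not at nominal level.
* No open-population modelling: the package estimates abundance, not
  survival or recruitment.
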