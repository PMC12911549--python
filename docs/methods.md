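# Methods

This note documents the models, defaults, and numerical choices behind
`stormcohort`, and what the synthetic-data tests do and do not demonstrate.

## Exposure construction

**Track densification.** Best-track fixes (strictly increasing timestamps,
WGS84 decimal degrees) are interpolated linearly in latitude and longitude
against time to a fixed step (default 15 min). Linear interpolation is a
declared choice: at 15-minute resolution over 6-hour source fixes the
deviation from any smooth alternative is far below the kilometres that
matter for a 4-day rain window, and linearity makes the operation exactly
oracle-checkable. The grid has `floor(span/step) + 1` points starting at the
first fix; if the span does not divide evenly the final source fix is
appended so both endpoints are always preserved. Longitudes must stay within
[-180, 180] and may not straddle the antimeridian (Gulf-of-Mexico scope);
crossing input is an explicit error rather than a silent mis-interpolation.

**Closest approach.** Minimum haversine distance (IUGG mean Earth radius
6371.0088 km) over the densified track, ties broken by the earliest
timestamp. The *approach date* is the calendar date of the approach time
under a configurable UTC offset, default −6 h (Central Standard Time):
daily rain gauges report local days and the exposure window is defined in
calendar days, so calendar alignment must be local.

**IDW rainfall.** The centroid estimate for a date is the `d^-p`-weighted
mean of in-radius station values, `p = 2` by default; stations missing that
day contribute nothing (GHCN missingness is not zero rain). The search
radius starts at 150 km and doubles until at least 3 reporting stations are
inside, capped at 600 km — defaults chosen for Gulf-region gauge density and
all exposed in configuration. A station within 1 m of the centroid is used
directly. The estimate is a convex combination, so it is bounded by the
contributing station values (a property test).

**Classification.** Cumulative rain over approach date −2 … +1 (4 calendar
days) strictly greater than 75 mm defines high-rain exposure; exposure is
uniform within an area. No distance-to-track cap is applied by default —
the exposure rule is rain-only, with distance entering only through window
timing — but an optional cap exists for users following other conventions.
Inches are reported at one decimal (25.4 mm/in, round-half-even).

## Cohort

Inclusion: age ≥ 65, complete covariates (complete-case analysis; a ledger
note is attached when covariate missingness exceeds 3% of input rows),
and — in the primary analysis — no relocation during follow-up. Exclusions
are applied in a fixed order (age → missingness → relocation) so ledgers are
comparable; cohort size plus ledger counts always equal the input size.
Follow-up time is whole days from landfall to death, censored at 365;
landfall-day deaths get 0.5 days. Any strictly positive convention works
for tied-at-origin deaths; 0.5 is the standard one and is what the
synthetic generator also uses, so date arithmetic and survival records are
mutually consistent.

## Descriptive measures

Mortality "rates" are one-year cumulative-incidence proportions (fixed
365-day follow-up), not person-time rates. Attributable fraction among the
exposed is `(RR − 1)/RR`; attributable deaths are
`n_exposed (r1 − r0) ≡ AF × deaths_exposed`. Negative values are reported
as computed, never floored. Subgroup measures use subgroup-restricted
denominators. Kaplan–Meier estimation and the log-rank test are delegated
to lifelines; Table-1 tests follow the conventional mapping (Welch t-test
for means, Mann–Whitney for medians, Pearson chi-squared without continuity
correction for proportions), two-sided, α = 0.05, no multiplicity
adjustment.

## Shared-frailty Cox model

The hazard for subject *i* in area *j* is
`h0(t) · w_j · exp(β_E E + βᵀx)` with `w_j ~ Gamma(1/θ, 1/θ)` (mean 1,
variance θ). Gamma frailty is the canonical, oracle-checkable choice for an
unspecified area-level random effect. Estimation:

* **Inner loop** — Newton maximization of the Breslow-ties partial
  likelihood with `log w_j` offsets; risk-set sums are accumulated over
  distinct-time tie groups; tolerance 1e-8 on the log-likelihood change,
  step-halving on overshoot. With θ = 0 this path *is* ordinary Cox partial
  likelihood (verified against an independent brute-force maximization of
  the explicit likelihood, and against lifelines).
* **E-step** — posterior frailty means `(1/θ + D_j)/(1/θ + A_j)` with `D_j`
  the cluster's events and `A_j` its accumulated expected events.
* **Outer loop** — bounded Brent search for θ on the profile Klein marginal
  likelihood over [0, 2], tolerance 1e-6, warm-starting coefficients and
  frailties between evaluations; the θ = 0 boundary is evaluated explicitly
  and wins ties. (A cyclic EM update of θ was tried first and converged too
  slowly near the flat optimum; the profile search reaches the same optimum
  in bounded time.)

Breslow tie handling is the documented default because it is exactly
specifiable for oracle tests; ties in the synthetic data are integer-day
ties among risk sets of tens of thousands, where Breslow attenuation is
negligible at the effect sizes involved.

**Variance.** Standard errors are the β block of the inverse of the full
(β, log-frailty) penalized Hessian (Schur complement; the gamma penalty
contributes `w_j/θ` on the frailty diagonal), verified against a numerical
Hessian of the explicit penalized log-likelihood. This matters specifically
for the exposure coefficient, which varies only *between* areas: holding
frailties fixed understates its variance and mis-calibrates CIs. θ
uncertainty itself is not propagated (standard for shared-frailty
software); the parameter-recovery test shows coverage within [0.88, 0.99]
at the default study size. CIs are Wald with z = 1.96; HRs are reported to
2 decimals in the CLI outputs.

**Subgroups.** Stratified refits for each chronic condition (ADRD, CHF,
COPD, DM, CKD), age 85+, dual eligibility, NH-Black, and Hispanic/Latino.
Race-defined subgroups drop the race covariate; condition-defined subgroups
exclude the defining condition's flag from the comorbidity count. Degenerate
subgroups (no events, < 2 clusters, single exposure group, separation) are
reported with a skip reason instead of aborting the table. Constant design
columns within a subgroup are dropped.

## Sensitivity analyses

**E-value.** `E = RR + sqrt(RR(RR − 1))`, applied to `1/RR` first when the
estimate is protective; the CI E-value uses the limit closer to the null and
is 1 when the interval crosses 1. The hazard ratio is used directly as the
risk ratio — a rare-outcome approximation (one-year mortality ≈ 4–8%) noted
in the output metadata.

**Moran's I.** `I = (n/S0) Σ w_ij z_i z_j / Σ z_i²` on area-averaged
martingale residuals (`event − expected events` per subject, averaged within
area; martingale residuals are the declared choice where the residual type
is conventionally unstated). Weights are row-standardized 5-nearest-
neighbour on centroid great-circle distance — polygon adjacency is out of
scope, so neighbourhood structure must come from centroids; rook/grid
weights are available for tests. Significance is a two-sided seeded
permutation test (999 permutations), so p-values are reproducible;
constant input is an explicit degenerate-input error.

**Relocation.** The full model suite is rerun with relocated beneficiaries
included and reported side by side with the primary fit. In the generator,
relocation affects inclusion only and is independent of the event process,
so the two columns should differ only by sampling noise — which is what the
comparison test asserts via mutual CI overlap.

## Synthetic data

The generator emulates the study conditions: a smooth storm track (quadratic
Bezier between configured endpoints, seeded curvature, 6-hourly fixes over
7 days), station-day rainfall `(background + peak · exp(−d/decay)) × noise`
with `d` the station's distance to that local day's track positions and
mean-one gamma noise (defaults: background 2 mm, peak 130 mm/day, decay
120 km, CV 0.5), and a cohort whose covariate marginals copy the published
composition of the Gulf-coast Medicare population this pipeline targets
(age mean 75.8 / SD 7.3 truncated at 65, 56.3% female, 7.7% dual, ADRD
12.5%, CHF 17.2%, COPD 13.9%, DM 30.8%, CKD 27.4%, rurality 77.8/11.9/10.3,
relocation 2.7%). Event times are exponential — the simplest PH-consistent
baseline; the analysis never uses baseline shape — with a daily hazard
calibrated to 4% one-year mortality at the reference profile, covariate
log-HRs (age 0.07/yr, male log 1.4, comorbidity log 1.10), a configurable
exposure effect (default log 1.05), and *log-normal* area frailty (sd 0.1).
The frailty is deliberately log-normal while the fitter assumes gamma:
recovering the exposure effect under that mild misspecification is itself a
useful robustness check, and at variance ~0.01 the two families are nearly
indistinguishable. A per-condition override of the exposure effect exists as
a test knob for subgroup-effect recovery.

What the generator does **not** emulate: spatial correlation of rainfall
beyond track-distance decay, correlated covariates (conditions are
independent Bernoulli draws), informative relocation, or migration. Passing
tests therefore demonstrate correctness of the *pipeline* under the assumed
model, not robustness to every feature of real claims data.

## Problem sizes

Defaults are 200,000 beneficiaries, 250 areas, 120 stations — the size used
by `scripts/acceptance.py` and by the parameter-recovery test (50
replicates). Module-level simulation tests use 6,000–120,000 beneficiaries
and 40–60 areas; the log-rank null calibration uses 200 subjects per group
over 1,000 replicates (large enough that the chi-square reference
distribution applies — at 60 per group with ~90% events the statistic is
measurably anti-conservative, ~0.054 at nominal 0.05); the Moran null
uniformity check uses 30 areas, 1,000 fields, 999 permutations each.

## Known limitations

* Breslow (not Efron) tie handling; fine at the default tie density, biased
  for heavily tied small risk sets.
* θ uncertainty is not in the CIs; coverage is slightly below nominal by
  construction.
* The IDW defaults (power, radius, minimum stations) are declared choices,
  not estimates; results for sparse gauge networks depend on them.
* Moran's I uses kNN weights on centroids; polygon contiguity would differ
  for irregular areas.
* No proportional-hazards diagnostics, time-varying effects, or competing
  risks — out of scope by design.
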