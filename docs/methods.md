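# Methods

## Overview

`surgecast` forecasts the nightly surgical bed census of a hospital by
composing three models: a per-case length-of-stay (LOS) regressor, a daily
surgical-volume forecaster, and a census forecaster that consumes both.  A
synthetic hospital-data generator with fully known latent parameters stands
in for the institutional EHR extract, so every stage can be validated
against ground truth.

## The synthetic hospital

One simulated year is a table of surgical encounters (one row per case) on a
0-based day index with a weekday cycle and a hospital holiday calendar.

**Daily volume.** Case counts are negative binomial around a regime mean —
weekday (default 320), weekend (170), holiday (120) — with size parameter 80
(variance ≈ μ + μ²/80; `None` gives Poisson, `0` deterministic counts).
The defaults put the daily median near 280 cases and produce the
characteristic period-7 cycle with holiday troughs.

**Case mix.** Surgery types follow a Zipf law (exponent 0.8 over 150 types,
so the four most common types carry roughly a quarter of the volume).  Each
type carries a latent outpatient propensity (Beta-distributed, recentred so
the volume-weighted mean equals the configured 72.4% outpatient fraction)
and belongs to one of 12 departments; the service line is the department
plus the case's inpatient/outpatient designation.  The *daily* admission-class
mix swings around the type propensities on the logit scale (SD 0.8 by
default): operating-room block schedules make some days inpatient-heavy
(e.g., joint-replacement blocks) and others ambulatory-heavy.  This
day-level mix variation is what makes schedule-aware census features
informative at short horizons.

**Length of stay.** LOS is zero-inflated: a point mass at 0 nights
(same-day discharge; default probability 0.30 for planned outpatients, 0.02
for planned inpatients) and otherwise `1 + Poisson(Gamma)` nights.  The
gamma–Poisson mixture is the discretization of choice because its mean is
*exactly* the configured positive-part mean — rounding a continuous gamma
biases small-mean types upward by up to ~10%, which would contaminate
parameter-recovery checks.  Per-type positive means are lognormal (median
1.8 d, log-SD 0.5, capped at 25 d); within a type, planned inpatients stay
4× longer than planned outpatients (normalized to preserve the type mean),
which mirrors the dominant role of planned admission class in real
perioperative data.  The defaults give an overall LOS median of 1 night with
quartiles (1, 2) and a long right tail.

**Comorbidities.** Each case draws a truncated-normal number of distinct
codes (mean 10.9, SD 11.2, range 1–160; the underlying location is solved
numerically so the clipped mean matches the configured mean) from a
2,000-code vocabulary with power-law inclusion weights (exponent 1.3),
sampled without replacement via the Gumbel top-k trick (Plackett–Luce).
The 100 most frequent codes carry effect weights (∝ 1/√rank); the
standardized per-case sum — the latent burden — shifts the log-mean positive
LOS with coefficient 0.7 (centered so the type mean is preserved).  The
burden is therefore recoverable from the code matrix, which is what gives
the SVD components genuine predictive content.

**Bookkeeping.** Patients are drawn with replacement from a pool of 0.66 ×
expected volume, so repeat patients occur.  The planned-same-day-discharge
flag equals `LOS == 0` flipped with 5% error (schedule errors, unplanned
admissions).  Missingness is injected per field (defaults: 2% ASA PS, 0.11%
LOS, 0% duration).  All randomness flows from one seed through named
substreams; an optional `structure_seed` freezes the latent hospital (type
laws, departments) while case-level sampling varies, which is how the
replicate-based fidelity tests pool across seeds.

What the generator does *not* emulate: real ICD-9/10 semantics (codes are
opaque strings), intra-day timing, ICU/ward bed types, non-surgical
admissions, seasonal (annual) trends, or regime shifts such as a pandemic
surge.  Passing tests therefore demonstrate that the pipeline recovers the
structure this generator encodes — weekly seasonality, holiday effects, and
observable LOS drivers — not that it would achieve any particular error on a
given institution's data.

## Preprocessing

Rows missing the surgery type are excluded (with a report).  The data are
split chronologically — 225 training, 70 validation, 70 test days; the
"225" is taken as the printed protocol even though 32 weeks is 224 days —
and every fitted statistic is a pure function of its fitting window.
Imputation: missing scheduled duration and LOS get the per-type mean,
missing ASA PS the per-type mode (ties broken to the smaller score); types
absent from the window fall back to the global mean (numeric) or the token
`"unknown"` (ASA).  Imputation is idempotent.

The comorbidity vocabulary is the top *n* most frequent training-window
codes (frequency-descending, lexicographic tie-break; default n = 1,750).
One-hot encoding is sparse end to end.  Three reductions to k components
(default k = 12) are provided: truncated SVD (scikit-learn, randomized with
fixed state); PCA computed without densifying, by running ARPACK on an
implicitly column-centered linear operator; and feature agglomeration by
average-linkage clustering of columns under cosine distance (computed from
the Gram matrix, again without densifying).  A tuner sweeps (method, n, k)
against downstream validation MSE, sequentially (k at the largest n, then n
at the best k) or jointly.

## The LOS model

A random forest (scikit-learn) on: age, scheduled duration, comorbidity
count, historic mean LOS of the surgery type (training window only, to
avoid target leakage), ASA PS as an ordinal with a separate "unknown"
indicator column, the k decomposition scores, and one-hot sex, service line
and planned admission class (unseen categories map to an all-zero block).
Tuned hyperparameters: at most 580 leaves per tree and 92% of the training
rows per tree (bootstrapped); 500 trees by default (reduced in scaled runs;
a sample fraction of exactly 1 disables resampling so a one-tree forest
equals a single decision tree).  Predictions are clipped at 0.  Evaluation
reports RMSE, MAE and errors stratified at 10 days; permutation importance
(MSE loss, 10 repeats by default) ranks features.  The comparison baseline
throughout is the per-type mean LOS.

## Volume forecasting

Daily counts are modelled on the raw scale with SARIMAX state-space maximum
likelihood.  Order identification follows the correlogram workflow: the ACF
band is the white-noise approximation ±1.96/√n; lag-7 structure motivates
one seasonal difference; the single surviving ACF spike at lag 7 motivates a
seasonal MA(1); the remaining spikes coincide with holidays, which enter as
a 0/1 calendar-known exogenous regressor.  Rolling one-week-ahead evaluation
refits on an expanding window at each weekly origin (a filter-only update
that keeps the first origin's parameters is available and is used in scaled
runs; on generator data the two agree to within a few percent).  Fit
failures raise explicit errors — at rolling origins they are recorded and
the origin skipped, never silently replaced by a naive forecast.
Near-converged fits (optimizer stopped without the strict tolerance) are
accepted at rolling origins provided the likelihood and forecasts are
finite; degenerate-but-exact fits on deterministic series otherwise fail
spuriously.

## Census forecasting

**Convention.** A case with surgery day d and LOS ℓ occupies one bed on
nights d … d+ℓ−1; ℓ = 0 occupies none; stays are truncated at the calendar
edge.  Total bed-nights therefore equal the sum of truncated LOS exactly —
asserted against a per-case-per-night double-loop oracle.

**Variants.** Five census arrays: observed (the forecast target), predicted
(forest LOS per case), adjusted (predictions overridden to 0 for planned
same-day discharges), perfect (oracle, identical to observed), and
surgery-mean (per-type mean LOS).  The observed/perfect arrays are integer
head counts.  The model-derived arrays default to *expected-count*
aggregation — a case with fractional LOS f + r contributes a full bed for f
nights and r of a bed on the next — because per-case half-up rounding of
conditional means quantizes whole surgery types across the 0.5 threshold
and injects seed-dependent level artifacts of several beds; per-case
rounding remains available (`aggregation="round"`, which is also the
contract of `build_census` itself).

**Horizon protocols.** `long_term`: one static multi-step forecast of the
whole test window from the end of the fitting window.  `two_week`: daily
rolling origins, day T forecast from data through T−14, scoring only day T
of each 14-step path.  `same_day`: daily origins, day T forecast from data
through T−1 plus day-T schedule information (the case list and its LOS
predictions are available before the operating-room day starts).

**No leakage, by construction and by audit.** Exogenous values dated after
an origin's cutoff are never read from the observed future.  Holidays are
calendar-known.  Schedule-derived census values are known only for past
days and (in the same-day protocol) the target day itself; for later days
they are fed forward: the exact contribution of already-scheduled cases
plus forecast daily counts times the fitting-window probability that a case
is still in a bed k nights after surgery.  Lagged surgery counts beyond the
cutoff come from the rolling volume forecaster.  Every consumed exogenous
value is logged with its provenance (calendar-known / observed-past /
schedule-known / forecast-fed) and the audit is re-verified after every
run; a feature whose future value would be needed but has no forecaster
raises a leakage error — the test suite plants the observed census itself
as a regressor to prove the audit trips.

**Models and metrics.** SARIMAX per the volume machinery (parameters are
estimated once at the first origin and filter-updated at later origins by
default; full refitting per origin is a switch), OLS of census on the
exogenous set plus intercept, and a VAR of (census, counts) with holiday
exogenous terms (lag order by AIC, long-term protocol only).  Each grid row
reports RMSE over the test window and SD, defined as the standard deviation
of the absolute daily errors — the only definition consistent with a
per-evaluation SD.  A relative-error report divides a chosen RMSE by a
bed-capacity reference (peak observed census by default); oracle-bound rows
(perfect, surgery-mean) are excluded when choosing the best model.

Under the census convention, the perfect-LOS same-day bound is ~0 beds:
schedule plus true LOS fully determines the night's census.  In a real
hospital the analogous bound is positive (transfers, non-surgical occupancy,
cancellations); the bound here is a statement about the generator's world.

## Problem sizes

Scaled runs — the test batteries and the acceptance script — use the default
per-case laws at roughly one-fifth volume (60/30/20 mean cases per
weekday/weekend/holiday, 300-code vocabulary, top-250 selection, 40 types,
200-tree forests).  Extreme-stay length scales with hospital size (the
rarest long-stay procedures are concentrated in large centers), so the
qualitative orderings — holiday benefit, the perfect ≤ predicted ≤
type-mean information sandwich, the same-day-discharge adjustment — are
evaluated as paired-seed win rates rather than as absolute RMSE values.

## Known limitations

- The SD definition and the census convention are package choices; reported
  numbers are only comparable across runs using the same conventions.
- The two-week and long-term horizons score similarly on generator data
  (its year is trend-stable by construction); distinguishing them requires
  injected level shifts, which the generator does not currently model.
- VAR supports only the long-term protocol.
- The feed-forward census estimate uses rounded nights for scheduled cases
  and an empirical survival profile for future cases; it is an expectation,
  not a distributional forecast.  No prediction intervals are produced
  anywhere.
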