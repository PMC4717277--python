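# Methods

This note documents the models, conventions and design choices behind
`vitalyears`, in the order data flows through the package.

## Cohort representation and units

A cohort is a long-format table (one row per subject per attended exam)
with a shared exam-wave calendar; the per-exam wave date is taken as the
median of per-subject exam dates, while per-subject dates are used
wherever they exist (ages, rates, annual series). Units are fixed to
mid-century US clinical conventions: mm Hg, mg/dL, inches, pounds, and
kg/m² with the imperial BMI constant 703·lb/in². Dates are fractional
calendar years; survival durations are converted at 365.25 days/year and
rounded to whole days.

Row-level validation (systolic must exceed diastolic, physiological values
positive, no exams after death) diverts bad rows into a rejects table with
reasons; they are never silently dropped. Subjects whose death date is
unknown are not assigned imputed lifespans: the analysis path requires
known deaths, and right-censored subjects are removed by the follow-up
exclusion. This is a deliberate policy choice for birth-decade cohorts
with near-complete mortality follow-up; it does not generalize to heavily
censored data.

## Exclusions

Criteria are applied in a fixed order — eligibility (age window at exam 1,
default 28–38), follow-up (no death date *and* no final-exam data),
completeness (any required variable missing at exam 1), outlier screen —
so each excluded subject carries exactly one primary reason and the report
satisfies `retained = eligible − lost − insufficient − outliers` on every
input. The outlier screen generalizes a manual removal of one extreme
systolic reading into a configurable rule: exclude when any panel
variable at exam 1 lies more than `outlier_z` (default 8.0) sample
standard deviations from the mean. "Insufficient data" is operationalized
as incompleteness at exam 1; stricter longitudinal completeness can be
requested via the criteria.

Blood-pressure-treatment adjustment adds the average treatment effect to
approximate untreated pressures. The default scope is `treated_only`;
`all` is also implemented because the alternative reading (shift every
subject) exists, but shifting untreated subjects is almost certainly
unintended, so it is not the default. Original values are retained so the
adjustment is invertible.

## Exam weighting and cumulative exposure

Each whole calendar year in a subject's span takes the value of the
nearest measured exam. Ties (a year equidistant from two exams) break
toward the earlier exam; this choice reproduces the canonical worked
example (120/130/140 in 1960/1966/1976 → 120 for 1956–1963, 130 for
1964–1971, 140 for 1972–1980) and is covered by a brute-force oracle
property test. Padding extends the span by `round(mean inter-exam gap /
2)` whole years on each side; a single-exam series has no gaps to average,
so it requires an explicit pad. Exams with missing values are dropped from
the nearest-exam search (the next-nearest measured exam fills those
years).

Cumulative exposure is the plain sum of annual values over a window of
`depth_years` ending at the focal year. Windows are specified in years
internally; the history sweep exposes depth in *exams* and converts via
the wave calendar. Windows reaching before a subject's padded span are
clipped to it (with a warning): subjects measured late simply contribute
shorter exposures, keeping the subject set fixed across depths.

## Rates of change

Three estimators are provided: successive difference, OLS slope over the
focal exam and two predecessors, and a moving-average variant that
averages `window` adjacent exams (values and dates alike) in two adjacent
blocks before differencing. All three return exactly the generating slope
on noise-free linear input, and the smoothed variant has strictly lower
sampling variance on noisy linear input (tested by Monte Carlo). Missing
required exams yield a missing value, not an error, so the estimators can
be mapped over ragged cohorts. Rate features were retained as first-class
citizens precisely so that a *negative* finding (rates unpredictive under
current- or cumulative-driven mortality) is testable rather than assumed.

## Survival and predictivity

Survival after a focal exam is `death date − focal wave date` in days,
over subjects alive at the focal date; measuring from the first exam
instead is available behind a flag. Composite risk scores are plain OLS
(no regularization, no nonlinearities — a deliberate overfitting guard
given seven free parameters against n ≈ 1300), with exact-collinearity
detection that names the dependent columns (the pulse-pressure identity
sbp − dbp = pp being the canonical case; pulse pressure therefore enters
univariate analyses only). Cross-validated r² uses seeded k-fold splits
and is computed once on the pooled out-of-fold predictions rather than
averaged per fold, because a single out-of-sample number is the quantity
of interest. Focal sweeps are complete-case per exam: a subject missing a
panel variable at one exam drops out of that exam's fit only. Sex
stratification is a filter applied before any fit, not an interaction
term. p-values are two-sided with no multiple-testing correction; traces
are descriptive.

## Synthetic cohorts

The generator emulates the statistical skeleton the analysis assumes: ~28
shared exam waves ~2 years apart starting in 1948, subjects sharing a
birth decade (entering at ages ~29–38), per-subject linear latent
trajectories `x(t) = baseline + drift·t` with Gaussian baseline/drift
across subjects, measurements = latent value at the nearest whole year
plus Gaussian noise, and a Gompertz hazard modulated by one driver
variable through the current deviation, its accumulated (left-Riemann)
integral, or its rate. Death times are drawn by exact inverse-CDF
sampling of the piecewise-constant yearly hazard — exponential
interpolation within the year rather than uniform — so the constant-hazard
limit is *exactly* exponential, which the suite verifies with a KS test.
Everyone dies by a hard cap age (default 120 years), guaranteeing a fully
deceased cohort for the no-censoring analysis path. Loss to follow-up
truncates a subject's record at a random wave and hides the death date;
missingness then knocks out individual measurements. All randomness
derives from one seed; identical seeds give byte-identical output files.

Default trajectory parameters are loosely anchored to printed exam-1
cohort summary statistics (e.g. systolic 126 ± 13 mm Hg) but the spreads,
drifts and noise levels are *testability choices*, not fitted quantities:
no public description of the real trajectory distributions exists.
Variables are simulated independently, which is known to be unrealistic —
systolic and diastolic pressure are strongly correlated in life, and the
independent simulation occasionally produces inverted pairs that the
reader rejects as malformed (visible as a handful of "insufficient data"
exclusions in default runs). Passing tests therefore demonstrate that the
pipeline recovers the *generative mechanisms it models* — they say nothing
about unmodeled features of real data such as cross-variable correlation,
secular trends, treatment effects on trajectories, or competing risks.

### Regime presets and their identifiability

The named presets in `regime_config` are the study conditions for regime
recovery, designed analytically around a limitation of linear
trajectories: when subjects differ in drift, mid-depth cumulative windows
weight drift more heavily than full-depth ones, so the history-depth trace
can peak and then fall even under a purely cumulative hazard. The presets
therefore separate the mechanisms:

- **cumulative** (β_cum = 0.0015 per unit-year): mild drift spread
  (0.15/yr) and large measurement noise (8) on a baseline spread of 10, so
  accumulated history keeps adding signal at every depth and the trace
  rises monotonically through 15 exams of history.
- **current** (β_cur = 0.04 per unit): zero drift spread and small noise
  (3), so past values carry no information beyond de-noising and the trace
  is flat beyond ~3 exams. The flatness tolerance used in tests (0.01 in
  r²) is several times the analytically expected residual de-noising gain
  (~0.002).
- **rate** (β_rate = 1.6 per unit/yr): wide baseline spread (15) masks
  cumulative features while smoothed rate estimates (window 4) recover the
  drift signal, so rate features dominate.
- **frailty** (β_cur = 0.10, age slope 0.085/yr): strong hazard
  heterogeneity for survivorship studies — selective mortality
  homogenizes the surviving cohort and the refit-focal r² trace declines
  with age.
- **age_only**: pure Gompertz, for null checks.

Recovery tests run 200 replicate cohorts of n = 1500 per regime and test
the mean trace against its Monte-Carlo standard-error bands (~2 minutes
per regime on one CPU); the survivorship check averages five replicate
focal sweeps.

## Numerical conventions

OLS fits go through a rank check on the unit-scaled design matrix
(SVD-based, threshold 1e-8 on null-vector loadings) before solving;
partial correlations residualize both sides on the covariates with
`lstsq`. Hazard computation refuses log-hazards above 50, naming the
dominating β term, rather than overflowing silently. Half-period padding
uses Python's banker's rounding on the half-gap, documented behaviour for
odd mean gaps. Pooled out-of-fold r² is nonnegative by construction; its
null distribution at n = 1000 concentrates near 1/n, which is how the
cross-validation sanity check frames "near zero" (within twice the
replicate spread).

## Known limitations

Single-driver hazards only (one variable modulates mortality at a time);
no cross-variable correlation, secular/cohort trends, or competing risks;
piecewise-constant interpolation only (no splines or continuous-time
models); no imputation; externally published clinical risk scores are
supported only through the `external` RiskModel hook, not reconstructed.
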