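# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of the `incimort` pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Cohort construction from claims

**Annual grain.** All claims carry a calendar year and no finer date: the
disease criteria are per-calendar-year counts, so a finer grain would add
machinery without information. A person's age in year `t` is `t - birth_year`
(completed calendar-year age), everywhere.

**Disease status.** A person-year is flagged diabetic when the year's count
of criterion-mode claims (outpatient visits, or refillable chronic
prescriptions "RP") with an ICD-9 code in family 250 — excluding the type-1
subcode families 250x1 and 250x3, by subcode membership rather than numeric
range — reaches the threshold. Defaults: `rp_count >= 1`, the criterion that
is easiest to confirm and empirically tracks the 4-outpatient-visit
definition; both are available, as are stricter thresholds (2-RP).

**Incidence and washout.** A flagged year is incident only when the person
was observed and unflagged in each of the two preceding years, mirroring
the two-year observation (probationary) period used in health-insurance
underwriting to control moral hazard and prevalent-case contamination.
Washout requires *observation*, not merely absence of flags: a person whose
history cannot be checked is excluded rather than assumed clean.

**Death inference.** The claims panel has no death register; deaths are
inferred from permanent claim cessation, which is informative only for
heavy utilizers — here persons aged 65+, who in the simulated regime average
six background outpatient visits a year. The rule: a person is dead in year
`t` (their last claim year) if they claimed in `t` and in each of the
`min_prior_utilization_years = 2` preceding years, every later observed year
is silent, and at least `silence_horizon = 2` silent years are observed
before the panel ends. Consequences, both deliberate:

* the death year is the *last year with claims*, so the person contributes
  that year's exposure and death count consistently;
* no deaths can be called in the panel's first two or last two years
  (prior utilization and silence are unverifiable there), so mortality
  surfaces span `[start+2, end-2]` — 2005–2011 for a 2003–2013 panel.

Against the generator's ground truth the rule's sensitivity (correct year,
callable window, ages 65+) is ~99% and its specificity is ~100%; the
acceptance suite asserts sensitivity >= 95%.

**Exposure accounting.** One person-year per observed year, death year
included. Incidence denominators are the washout-verified disease-free
person-years; mortality denominators are criterion-satisfying person-years
at 65+ (an `ever-flagged` denominator is available as an option); prevalence
uses all observed person-years. When a death table is supplied, observation
is truncated at the inferred death year for every rate kind: the registry
keeps dead persons enrolled (their claims simply stop — that is what makes
cessation informative), and without truncation the silent post-death years
would dilute denominators with person-years that cannot produce events. The
truncation is only as good as the inference: below 65 no deaths are
inferred, leaving a small downward bias in late-panel incidence at ages
45–64 (of order the cumulated sub-65 mortality, well under 1% per year).

## 2. Graduation

SMR, the heterogeneity estimator and partial-SMR graduation are implemented
exactly as stated in the README formulas. Numerical conventions:

* `d_x log(d_x/e_x) := 0` when `d_x = 0` — the limit that realizes the
  zero-death identity `v_x = SMR * u*_x`;
* if a whole column has zero events the graduation degenerates to
  `v = SMR * u* = 0` and carries a warning flag rather than an error;
* when the credibility denominator `d_x h2 + (1 - d_x/D)` is exactly zero
  (possible only when `h2 = 0` and one age carries all events), the
  `h2 -> 0+` limit is used: full weight on the local rate for that age;
* `u*_x` is the *reference-population* rate (the reading forced by the
  zero-death identity), supplied as a configurable rate table — in the
  pipeline, the generator's configured general-population schedule;
* `h2` is estimated per year-column when graduating a surface (the
  estimator is defined for one `d/e` vector); a user-settable floor
  defaults to 0, and no further heterogeneity inflation is applied.

`psmr_then_model` graduates a raw surface column-by-column and emits pseudo
counts `v * exposure`, so downstream model fitting consumes the graduated
surface like any other (the PSMR+LC row of the comparison tables).

## 3. GAPC estimation

All four models maximize the Poisson log-likelihood with mean
`E_xt * g^{-1}(eta_xt)` (log link; logit for CBD, with central exposure
standing in for initial exposure — at an annual grain nothing better is
available). Estimation is blockwise Newton: each parameter block gets its
one-step Newton update (closed form for every block), guarded by
step-halving so the log-likelihood is non-decreasing at every step; sweeps
repeat until the relative log-likelihood change falls below `tol = 1e-8` or
`max_iter = 500` sweeps. Updates are clipped at ±4 per step for stability.
Initialization is deterministic: `alpha` (or CBD's `k1`) from empirical
marginals, `beta` uniform `1/A`, period and cohort terms zero.

Identifiability constraints are imposed by invariance transformations
(applied lightly each sweep for conditioning and exactly at the end), so the
fitted surface is unchanged up to floating round-off (< 1e-12 relative; the
APC detrend iterates twice to cancel the large-cohort-value round-off).
CBD's fitted logits are affine in `(x - xbar)` by construction; grouped ages
use group midpoints (47, 52, ...) for `x` and `xbar`.

**Non-convergence is a state, not an exception.** Two honest failure modes
exist: `max_iter` exhaustion, and degeneracy — a zero-event cell pushes the
MLE of a bilinear term to infinity, which the fitter detects as a runaway
linear predictor (|eta| > 40 on a weighted cell) and reports as
`converged=False`. Comparison tables show such fits as NA and average over
the rest. RH, with its extra bilinear cohort term, is the most fragile
member, and on small grids RH (and to a lesser degree APC) has enough
parameters to nearly interpolate the data — an in-sample MAPE close to zero
there indicates saturation, not predictive merit.

The classical SVD route for LC (`fit(method="lc_svd")`) is kept as an
independent estimation path; on dense, large-count data it agrees with the
Poisson MLE within 2% MAPE (a regression guard in the test suite).

## 4. Evaluation and projection

MAPE is computed over cells with a defined, non-zero observed rate (the
percentage error is undefined at zero); the number of included cells is
recorded in the report. Fitting MAPE is in-sample — the comparison tables
measure goodness of fit, not forecast accuracy — over the layouts
single-age 45–89 / five-year 45–99 (incidence) and single-age 70–89 /
five-year 70–99 (mortality), with 90+ excluded from single-age layouts
because those populations are tiny. Lewis's interpretive bands (<10%
"highly accurate", >50% "unacceptable") are attached as labels only.

The LC period index is regressed on calendar year centred at its mean
(conditioning; the slope is unaffected and the intercept mapping is
recorded on the estimate). Annual increments `exp(b2_x * b)` are reported
per age group as factors and percentages.

## 5. The synthetic claims generator

The generator is the package's test bed: a one-million-person-style registry
at configurable scale (default 200,000 persons, 2003–2013, entry ages
35–99 uniform, half male) with per-person yearly simulation in a fixed
order — onset, death, claims — so that a person dying in year `t` still
emits that year's claims and death is left to be inferred from silence.

Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| incidence curve | logit-quadratic, peak 2% at age 75, curvature 1.5e-3 | reverse-U age profile peaking near 2% around 75; ~0.5% at 45 |
| incidence drift | +3% per year (log scale) | rising type-2 incidence, matching per-age increments of a few percent |
| baseline mortality | Gompertz `2e-5 * exp(0.10 x)` | q(75) ≈ 3.6%, an East-Asian-style elderly schedule |
| mortality drift | +2% per year | slowly worsening measured schedule, smaller than the incidence trend |
| treated multiplier | 1.0 | diabetics under regular care die like the general population |
| untreated multiplier | 1.5 | excess hazard for unmanaged disease |
| adherence | 0.8 | share of onset cases taking up regular care |
| background visits | Poisson(6) per year | heavy-utilizer elderly regime; makes claim silence informative |
| diabetes visits | max(Poisson(6), 4) per adherent year | guarantees the 4-visit criterion can see adherent cases |
| RP count | max(Poisson(2), 1), drawn once per person | care intensity is a stable trait; yearly redraws would let prevalent cases flicker below a 2-RP threshold and re-enter as spurious "incident" cases |
| type-1-coded fraction | 0.05 per diabetes event | excludable 250x1/250x3 subcodes are present but rare |

Non-adherent onset cases emit diabetes-coded outpatient events in the onset
year only (`1 + Poisson(2)` visits) — a declared stand-in, since the joint
visit distribution of unmanaged diabetics is not otherwise constrained.

**What the generator does not emulate** — and hence what passing tests do
not establish about real claims data: no within-year dates, costs, or
comorbidity coding; no enrollment churn (everyone is observed for the whole
panel); no prevalent cases at panel start (real washouts also remove
pre-existing cases; here the first flagged year *is* the onset year for
adherent cases); no care-seeking correlation with health state beyond the
adherence split; no coding error other than the type-1 subcode fraction.
Recovery of the configured curves by the pipeline demonstrates internal
consistency of the estimators, not robustness to these real-world features.

## 6. Problem sizes and determinism

The package's study runs use a 200,000-person panel; unit tests use 2,000 to
100,000 persons, and the model-recovery checks use controlled grids (about
10 ages x 8–10 years at 1e4–1e5 exposure per cell, 100 replications for the
stochastic drift-recovery check) — sizes at which every documented property
is measurable in seconds to a couple of minutes on one CPU. All randomness
flows from explicit seeds through `numpy.random.default_rng`; the pipeline
writes CSV with fixed float formatting, so a fixed (config, seed) pair
reproduces byte-identical outputs.

## 7. Known limitations

* In-sample MAPE rewards saturated models (RH on small grids); it is kept
  because the comparison is a goodness-of-fit audit, with NA propagation for
  non-convergence, not a model-selection criterion for forecasting.
* The κ drift is a deterministic linear trend; no ARIMA/random-walk forecast
  uncertainty is produced, and six to nine years of data support only
  short-horizon extrapolation (the drift r² on simulated panels is often
  modest — the reported increments are noisy at sparse ages).
* Death inference below age 65 is deliberately disabled, leaving a small
  undercount bias in sub-65 denominators late in the panel.
* The 1-RP vs 2-RP comparison reproduces a direction (stricter criterion,
  lower rates); the magnitude of the gap is a property of the simulated RP
  distribution, not a calibrated quantity.
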