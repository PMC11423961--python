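# incimort

Claims-based disease incidence and mortality modelling for insurance and
epidemiology: cohort construction from longitudinal health-claims panels,
standardized-mortality-ratio graduation, and the generalized age-period-cohort
(GAPC) family of stochastic mortality models, exercised end-to-end on a
synthetic claims generator with known ground truth.

## The problem

Health-insurance claims databases record who visited a doctor, when, and with
which diagnosis code — but not who "has" a chronic disease, and often not who
died. Building age- and year-specific incidence and mortality rates for a
condition such as type-2 diabetes from claims therefore requires a chain of
explicit, checkable decisions:

* **disease status** per calendar year from claim counts (e.g. at least 4
  diabetes-coded outpatient visits, or at least 1 refillable chronic
  prescription (RP) per year; ICD-9 family 250 with the type-1 subcode
  families 250x1/250x3 excluded);
* **incident cases** via a two-year washout (observation) window: a flagged
  year counts as new onset only if the person was observed and disease-free
  in both preceding years;
* **death inference** from permanent claim cessation: among persons aged 65+
  with ongoing utilization, a final claim year followed by nothing but
  silence through the end of the panel is read as the death year (the last
  two panel years are censored — silence there is unverifiable);
* **rate surfaces**: person-year exposures and event counts on an age x year
  grid, in single-age or five-year-group layouts.

The resulting raw surfaces are noisy at high ages, so two graduation devices
are applied and compared: the partial standardized mortality ratio (PSMR),
and stochastic mortality models.

## Models

With `m_xt` the central rate at age `x` in year `t` and `q_xt` its
probability-scale analogue, the four GAPC family members are

| model | structure |
|---|---|
| LC (Lee-Carter) | `log m_xt = b1_x + b2_x * k2_t` |
| APC (age-period-cohort) | `log m_xt = a_x + k_t + g_{t-x}` |
| CBD (Cairns-Blake-Dowd) | `logit q_xt = k1_t + k2_t (x - xbar)` |
| RH (Renshaw-Haberman) | `log m_xt = b1_x + b2_x k2_t + b3_x g_{t-x}` |

fitted by Poisson maximum likelihood (blockwise Newton with step-halving) with
the standard identifiability constraints (`sum b2 = 1`, `sum k2 = 0`;
`sum g = 0`, `sum c*g = 0` for APC; both sets for RH) imposed by invariance
transformations that leave the fitted rates unchanged. Model fit is compared
by in-sample MAPE, `mean |Y - Yhat| / Y * 100%`, across models, sexes, age
layouts and data periods; non-converged fits (a real possibility for RH, and
for any bilinear model facing zero-event cells) appear as NA.

PSMR graduation shrinks each age's raw rate toward the SMR-scaled reference
schedule in log space,

```
SMR = sum d_x / sum e_x,    e_x = exposure_x * u*_x
v_x = u*_x exp{ [d_x h2 log(d_x/e_x) + (1 - d_x/D) log SMR] / [d_x h2 + (1 - d_x/D)] }
h2  = max{ [sum (d_x - e_x SMR)^2 - sum d_x] / (SMR^2 sum e_x^2), 0 }
```

so ages with few events borrow strength from the reference population, and an
age with zero events gets exactly `SMR * u*_x`.

For trend projection the LC period index is summarized by a linear drift
`k2_t = a + b t`; the rate at age `x` then multiplies by `exp(b2_x * b)` per
calendar year — the per-age annual increment.

## Worked example

Simulate a 200,000-person panel (2003–2013) under the package's default
study conditions, build male incidence surfaces under the 1-RP criterion,
and fit a Lee-Carter trend to the five-year age groups:

```python
import incimort as im

cfg = im.PanelConfig()            # 200k persons, study defaults
panel = im.generate_panel(cfg, seed=42)
status = im.classify_diabetic(panel, im.DiseaseCriterion(mode="rp_count", threshold=1))
deaths = im.infer_deaths(panel, min_age=65)

inc = im.rate_surfaces(panel, status, "incidence", sex="M", ages=(45, 99),
                       years=(2005, 2013), deaths=deaths)
grouped = im.group_ages(inc, "five_45_99")
res = im.GAPCModel(grouped, kind="LC").fit()
print(res.summary())
drift = im.kappa_drift(res)
print(f"kappa drift: b = {drift.b:+.4f} per year (r^2 = {drift.r_squared:.2f})")
print(im.annual_increments(res, drift).table[["age_or_group", "factor", "percent"]]
      .tail(5).to_string(index=False))
print("fitting MAPE: %.2f%%" % im.mape(grouped, res.fitted_surface))
```

prints

```
GAPC results — LC (poisson_mle)
  converged   True
  iterations  8
  loglik      25810.8454
  grid        11 ages x 9 years
  alpha   len 11  sum -4.9909e+01
  beta2   len 11  sum +1.0000e+00
  kappa2  len 9  sum -1.1102e-16
kappa drift: b = +0.1241 per year (r^2 = 0.76)
age_or_group   factor   percent
       75-79 1.042662  4.266173
       80-84 1.058415  5.841521
       85-89 1.029152  2.915176
       90-94 0.990985 -0.901461
       95-99 0.922820 -7.717958
fitting MAPE: 11.35%
```

The constraint sums (`beta2` to 1, `kappa2` to 0) hold at machine precision;
the positive drift reflects the generator's rising incidence, and the per-age
increments are a few percent per year at ages where events are plentiful
(the oldest groups carry few events and correspondingly noisy `beta2`).

The same workflow is available from the shell:

```
incimort run-study --config study.yaml --out results/
```

writes incidence/mortality surfaces, MAPE comparison tables for all six
model rows (LC, APC, PSMR, PSMR+LC, CBD, RH), annual-increment tables, a
1-RP vs 2-RP criterion comparison, and a log of every parameter choice.
A fixed config and seed reproduce byte-identical outputs.

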