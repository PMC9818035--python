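# copsurv

Archimedean-copula survival models for **paired right-censored event
times** — built for paired-organ studies such as time to blindness of the
left and right eyes in glaucoma patients, where the two times per patient
are strongly dependent and standard univariate survival tools (Cox,
Kaplan–Meier) cannot express that dependence.

The joint model is a survival copula over parametric
proportional-hazards margins,

```
S(t1, t2 | z) = C_eta( S1(t1|z), S2(t2|z) ),   Sj(t|z) = exp(-H0(t) e^{z'B})
```

with four one-parameter Archimedean families — Clayton, Gumbel–Hougaard,
Frank, Joe — whose parameter `eta` maps to Kendall's tau (Clayton:
`tau = eta/(eta+2)`), and Weibull / Gompertz / log-logistic baselines
`H0`.  Fitting is by two-stage pseudo-maximum-likelihood (margins first,
then `eta`) or full maximum likelihood over all parameters; non-nested
candidates are ranked by AIC.  Diagnostics include Kendall-function Q-Q
data, pseudo-observation scatter and a parametric-bootstrap
Cramér–von Mises goodness-of-fit test.  A calibrated synthetic-cohort
generator reproduces the statistical structure of a 315-patient glaucoma
cohort (66.9% blind, 33.1% censored, 1–60 month follow-up, `tau ≈ 0.83`,
12-month median) so the whole pipeline is runnable and testable without
access to patient records.

See `docs/methods.md` for the model, numerical choices and calibrations.

## Worked example

```bash
copsurv simulate --seed 1 -o cohort.csv --truth-out truth.json
copsurv km cohort.csv
copsurv fit cohort.csv --family clayton --margin weibull
copsurv compare cohort.csv
copsurv diagnose cohort.csv --n-boot 200 --seed 1 -o gof.json
```

`simulate` writes a 315-subject cohort CSV (one row per patient: two
observed times in months, two 0/1 blindness indicators, nine covariates).
`km` prints

```
median time to blindness (both eye(s)): 12 months
event times: 44, events: 417
```

— the pooled-eyes Kaplan–Meier median (12 months, matching the
generator's calibration target).  `fit` prints the fitted dependence and
the coefficient table:

```
clayton copula, weibull margin (full_ml): loglik=-1152.243 aic=2336.486
eta = 10.42 (Kendall tau = 0.839)
          parameter  estimate       hr  hr_rounded       se             p
                lam  0.031431      NaN         NaN 0.011136  4.763792e-03
                  k  1.665902      NaN         NaN 0.072303 1.828088e-117
                age  0.001024 1.001024        1.00 0.004039  7.999201e-01
        gender_male  0.056938 1.058590        1.06 0.105403  5.890627e-01
                ...
                eta 10.421083      NaN         NaN 1.055639  5.515371e-23
```

`eta ≈ 10.4` means Kendall's `tau ≈ 0.84`: a patient's two eyes go blind
at strongly dependent times, and ignoring that dependence would badly
misstate joint risk.  Each covariate row's `hr = exp(beta)` is the
multiplicative effect on both eyes' hazards (e.g. a coefficient of
`-2.48` would print `hr_rounded = 0.084`).  `compare` fits all 4 x 3
family/margin combinations and ranks them by AIC; on data simulated from
a Clayton–Weibull model it reports, as expected:

```
best by AIC: clayton copula with weibull margin (AIC=2336.486, tau=0.839)
```

`diagnose` writes the empirical-vs-model tau, Kendall Q-Q points and the
bootstrap goodness-of-fit p-value as JSON (`--plot` adds scatter/Q-Q
figures).

The same pipeline is available as a library:

```python
from copsurv import synth, joint_fit

cohort, truth = synth.generate_cohort(synth.CohortConfig(), seed=1)
data = joint_fit.BivariateData.from_cohort(cohort)
fit = joint_fit.fit_full_ml(data, family="clayton", dist="weibull")
print(fit.eta, fit.tau, fit.aic)
```

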