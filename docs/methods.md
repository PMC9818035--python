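# Methods

`copsurv` models the joint distribution of two right-censored event times
per subject — the motivating application is time to blindness of the left
and right eyes in glaucoma patients — with an Archimedean survival copula
over parametric proportional-hazards margins:

    S(t1, t2 | z) = C_eta( S1(t1 | z), S2(t2 | z) ),
    Sj(t | z) = exp( -H0(t) * exp(z' beta) ).

This note records the model, its assumptions, the numerical choices, the
calibration of the synthetic cohort generator, and the limits of what the
test suite shows.

## The joint model and its likelihood

Each subject contributes observed times `y_j = min(T_j, c_j)` and event
indicators `d_j = 1(T_j < c_j)` for the two eyes, plus one covariate
vector `z` shared by both eyes.  Writing `u = S1(y1|z)`, `v = S2(y2|z)`,
the log-likelihood term per subject is, by censoring pattern:

| (d1, d2) | contribution |
|---|---|
| (1, 1) | `log c(u,v) + log f1(y1) + log f2(y2)` |
| (1, 0) | `log dC/du + log f1(y1)` |
| (0, 1) | `log dC/dv + log f2(y2)` |
| (0, 0) | `log C(u,v)` |

The copula is applied to **survival** functions (a survival copula), which
fixes all sign conventions above.  Censoring is assumed independent of the
event times given covariates (the generator enforces this), and both eyes
share one censoring time — clinically, a patient exits follow-up once.

Four exchangeable one-parameter families are implemented: Clayton
(`eta > 0`, lower-tail dependence, Kendall `tau = eta/(eta+2)`),
Gumbel–Hougaard (`eta >= 1`, upper-tail, `tau = 1 - 1/eta`), Frank
(`eta != 0`, radially symmetric, `tau` via the first Debye function, by
adaptive quadrature to 1e-10) and Joe (`eta >= 1`, `tau` by adaptive
quadrature of the generator identity `tau = 1 + 4 ∫ phi/phi'`, tolerance
1e-8; the test suite cross-checks it against the series
`1 - 4 Σ 1/[k(eta k+2)(eta(k-1)+2)]`).

## Margins

Three baselines share one parameterisation: a rate-like `lam > 0` and a
shape `k > 0` with cumulative hazards

    weibull      H0(t) = lam t^k
    gompertz     H0(t) = (lam/k)(e^{kt} - 1)
    loglogistic  H0(t) = log(1 + lam t^k)

Covariates act proportionally on the cumulative hazard for **all three**
families.  For the log-logistic this is a deliberate modelling choice (the
family is not closed under proportional hazards); it buys one uniform
hazard-ratio reading of every coefficient.  Times are months throughout,
and cohort I/O rejects non-positive times (follow-up starts at 1 month).

A note on conventions: published Weibull parameter pairs are notoriously
ambiguous between (rate, shape), (scale, shape) and their reciprocals.
`copsurv` fixes `S0(t) = exp(-lam t^k)` — `lam` is a rate on the
`t^k` scale — and all defaults and recovered estimates are reported in
this convention.

## Estimation

* **Two-stage pseudo-ML (IFM).**  Stage 1 fits the margin(s) by censored
  univariate ML — by default one shared `(lam, k, beta)` for both eyes,
  pooling the stacked records, since the package's reference analyses
  report a single margin; per-eye margins are a flag.  Stage 2 maximises
  the joint likelihood over `eta` alone with multi-start (from the
  `eta` values implied by `tau in {0.2, 0.5, 0.8}`).  The `eta` standard
  error comes from the stage-2 curvature only and is flagged as ignoring
  stage-1 noise.  A rank-based variant (`pseudo="rank"`) replaces stage 1
  with Kaplan–Meier pseudo-observations.
* **Full ML** maximises over `(log lam, log k, beta, t(eta))` jointly,
  initialised from the two-stage fit, with `t(eta) = log eta` (Clayton),
  `log(eta - 1)` (Gumbel, Joe) or the identity with the origin excluded
  (Frank).  Gradients are analytic in all margin parameters (the chain
  rule through `u`, `v` uses closed-form `d log(term)/du` per family);
  the `eta` component uses a central difference of the copula term at
  fixed pseudo-observations.  Standard errors come from the
  central-difference observed information (step `1e-4 * max(1, |theta|)`),
  delta-mapped to the natural scale; a non-positive-definite Hessian sets
  a warning note rather than failing.  The full-ML log-likelihood is
  floored at the two-stage value: if the optimizer cannot improve on its
  own starting point the two-stage solution is returned with a note.
* **Model selection** fits every requested family x margin pair and ranks
  by AIC (`-2 loglik + 2p`), ties broken toward fewer parameters then
  lexicographic family name; per-cell failures are recorded in the table,
  not raised.

Margin ML runs L-BFGS-B on `(log lam, log k, beta)` with analytic
gradients, multi-start over shape values (Gompertz starts near the
exponential limit `k -> 0` because `e^{kt}` explodes at months scales),
and declares convergence when the gradient sup-norm falls below
`1e-5 * max(1, |loglik|)` — an absolute 1e-6 is not attainable on
likelihoods of magnitude ~1e3 with double precision.

## Marginal analyses

Kaplan–Meier curves (lifelines under the surface) report the median as the
smallest event time with `S(t) <= 0.5`, undefined (NaN) when the curve
never reaches 0.5.  The multivariable semi-parametric model stacks both
eyes and fits a marginal Cox model with a robust sandwich variance
clustered by subject (Efron ties by default — months-resolution data are
heavily tied; Breslow via statsmodels as an option).  Univariable
screening fits each covariate block alone and retains it when any level's
Wald p falls below the threshold (default 0.25).

## Diagnostics

* Kendall's tau, empirical (tau-b on complete pairs, or on fitted-margin
  pseudo-observations) versus model-implied.
* A Kendall-function Q-Q plot: quantiles of `W = C(u, v)` against the
  quantiles of `K(w) = w - phi(w)/phi'(w)`.
* A Cramér–von Mises GOF statistic between the empirical copula of the
  (rank-transformed) pseudo-observations and the fitted family, with a
  parametric bootstrap: simulate from the fitted copula, re-estimate the
  dependence parameter (Kendall-tau inversion by default; 1-D pseudo-ML
  optional), recompute.  Margins are not refit inside the bootstrap.

**Calibration caveat.**  The Q-Q identity and the bootstrap level are
exact for complete pairs (measured: rejection rate 5% at alpha = 0.05 and
KS-uniform p-values over 100 level replicates).  Censored records enter
only through pseudo-observations evaluated at their censoring times,
which are not draws from the copula, and conditioning on both events
being observed also selects on the dependence; with ~33% censoring the
all-records and complete-pairs versions are both approximations, useful
for detecting gross misspecification (the suite shows full power against
a Gumbel/Clayton swap at tau = 0.8) but not as exact tests.

## Synthetic cohort generator

The generator emulates a hospital-based glaucoma cohort whose published
summary statistics serve as calibration targets: n = 315 patients,
follow-up support 1–60 months, 211 blind (66.9%) / 104 censored (33.1%),
a 12-month median time to blindness, Clayton dependence `eta = 9.57`
(`tau ≈ 0.83`), Weibull baseline `(lam, k) = (0.28, 1.65)` and a
13-coefficient vector on age (uniform over 40–84 years) plus eight
categorical covariates drawn independently at the published frequencies
(no cross-tabulation is available to emulate their joint distribution).

Generation: draw covariates; draw `(u, v)` from the copula (gamma
frailty for Clayton, positive-stable for Gumbel, closed-form conditional
inversion for Frank, vectorised bisection for Joe); invert the shared
margin at each subject's covariates; censor by the minimum of an
exponential dropout and an administrative Uniform[1, 60] window, one
censoring time per patient; optionally round observed times up to whole
months.  Output is reproducible byte-for-byte under a fixed seed and
carries a truth sidecar (true times, censoring times, every parameter).

Two calibrations, each a deterministic function of the configuration via
a fixed-seed internal Monte-Carlo sample:

* **Dropout rate** is root-found so the expected per-eye censoring
  fraction equals `target_censor_frac` (default 0.331).  The real
  mechanism (administrative versus loss to follow-up) is unpublished;
  this mixture is a stand-in.  An unreachable target (administrative
  censoring alone already exceeds it) raises with the achieved fraction.
* **Time scale.**  The published baseline and coefficients are mutually
  inconsistent with the published median: `S0(t) = exp(-0.28 t^{1.65})`
  has a baseline median of 1.7 months, and no standard reading of the
  parameter pair moves the cohort median (~2–3 months once covariates
  are applied) anywhere near 12 months.  Rather than silently altering
  the published parameters, the generator applies one global time-scale
  factor — chosen so the continuous cohort median is `median_months - 0.5`
  and the ceil-rounded Kaplan–Meier median lands exactly on
  `median_months` (default 12) — and records it in the truth sidecar.
  Shape, coefficients and dependence are untouched (a Weibull time scaling
  only remaps `lam`).  Setting `median_months=None` disables the scaling;
  parameter-recovery studies do that so the simulated truth is exactly
  `(0.28, 1.65, 9.57)`.

What the generator does **not** emulate: covariate dependence (drawn
independently), per-eye covariate differences, missing data, and any
within-cohort structure beyond the published margins.  Because both eyes
share one covariate vector, covariate heterogeneity alone induces
unconditional dependence between the eyes; a zero-coefficient margin is
the right configuration when a truly independent benchmark is needed.
Passing tests therefore demonstrate correct self-consistent behaviour
under this stylised data-generating process, not fidelity to the original
patient records, which are not publicly deposited.

## Problem sizes used by the test suite

Stochastic suites are sized for a single CPU: margin parameter recovery
uses 8 replicates of n = 2000 per distribution; joint full-ML recovery 20
cohorts of n = 2000 (requiring >= 18 to cover `lam`, `k`, `eta` within 3
standard errors); AIC family recovery 25 cohorts of n = 315 (requiring
>= 20 Clayton–Weibull wins across the 12-cell grid); the GOF level check
100 replicates of n = 150 complete pairs with 200 bootstrap draws.  All
stochastic tests are seeded.

## Known limitations

* Dependence parameter SEs from the two-stage fit understate uncertainty
  (stage-1 noise is not propagated); full-ML SEs are the ones to report.
* The GOF and Q-Q diagnostics are exactly calibrated only for complete
  pairs (above).
* Rounding times to whole months before fitting the continuous likelihood
  introduces a small bias when the median is only a few months; the
  generator's default median of 12 months keeps it negligible, but
  recovery studies use unrounded times.
* Frank near `eta = 0` and Gumbel/Joe near `eta = 1` sit on the boundary
  of their transforms; fits on genuinely independent data will report
  `tau ≈ 0` but the SE of `eta` there is not trustworthy.
* Left truncation, interval censoring, time-varying covariates and more
  than two events per subject are out of scope.
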