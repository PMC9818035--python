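"""Parametric marginal survival models with proportional-hazards covariates.

Three baselines are supported, each parameterised by a rate-like ``lam``
(> 0) and a shape ``k`` (> 0), with covariates acting multiplicatively on
the cumulative hazard:

    S(t | z) = exp(-H0(t) * exp(z' beta))

    weibull      H0(t) = lam * t**k
    gompertz     H0(t) = (lam / k) * (exp(k t) - 1)
    loglogistic  H0(t) = log(1 + lam * t**k)

For the log-logistic this proportional-cumulative-hazards link is a
modelling choice (the family is not closed under PH); it keeps one
uniform hazard-ratio interpretation of ``beta`` across all baselines.
Times are in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._numeric import central_hessian

__all__ = [
    "DISTRIBUTIONS",
    "MarginSpec",
    "MarginFit",
    "survival",
    "density",
    "hazard",
    "cumulative_hazard",
    "quantile",
    "fit_univariate",
]

DISTRIBUTIONS = ("weibull", "gompertz", "loglogistic")


@dataclass(frozen=True)
class MarginSpec:
    """Baseline distribution tag, (lam, k) parameters and PH coefficients."""

    dist: str
    lam: float
    k: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        d = str(self.dist).lower()
        if d not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.dist!r}; choose one of {DISTRIBUTIONS}")
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValueError(f"lam must be positive, got {self.lam!r}")
        if not (self.k > 0 and np.isfinite(self.k)):
            raise ValueError(f"k must be positive, got {self.k!r}")
        object.__setattr__(self, "dist", d)
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))

    @property
    def n_params(self) -> int:
        return 2 + self.beta.size


@dataclass
class MarginFit:
    """Result of a univariate censored ML fit."""

    spec: MarginSpec
    se: np.ndarray          # on (lam, k, beta) scale, delta method for lam, k
    loglik: float
    n_events: int
    converged: bool = True
    message: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.spec.n_params


def _lp(spec: MarginSpec, z):
    """Linear predictor z' beta; z may be None, a vector, or an (n,p) matrix."""
    if z is None or spec.beta.size == 0:
        return 0.0
    z = np.asarray(z, dtype=float)
    if z.ndim == 0:
        return float(z) * spec.beta[0] if spec.beta.size == 1 else 0.0
    return z @ spec.beta


def _h0_H0(dist: str, lam: float, k: float, t):
    """Baseline hazard and cumulative hazard at t > 0."""
    t = np.asarray(t, dtype=float)
    if dist == "weibull":
        H0 = lam * np.power(t, k)
        h0 = lam * k * np.power(t, k - 1.0)
    elif dist == "gompertz":
        H0 = (lam / k) * np.expm1(k * t)
        h0 = lam * np.exp(k * t)
    else:  # loglogistic
        ltk = lam * np.power(t, k)
        H0 = np.log1p(ltk)
        h0 = lam * k * np.power(t, k - 1.0) / (1.0 + ltk)
    return h0, H0


def cumulative_hazard(spec: MarginSpec, z, t):
    """H(t | z) = H0(t) * exp(z' beta)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    _, H0 = _h0_H0(spec.dist, spec.lam, spec.k, t)
    out = H0 * np.exp(_lp(spec, z))
    return out if out.ndim else float(out)


def survival(spec: MarginSpec, z, t):
    """S(t | z) = exp(-H0(t) exp(z' beta)); S(0 | z) = 1."""
    out = np.exp(-cumulative_hazard(spec, z, t))
    return out if np.ndim(out) else float(out)


def hazard(spec: MarginSpec, z, t):
    """h(t | z) for t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    h0, _ = _h0_H0(spec.dist, spec.lam, spec.k, t)
    out = h0 * np.exp(_lp(spec, z))
    return out if out.ndim else float(out)


def density(spec: MarginSpec, z, t):
    """f(t | z) = h(t | z) * S(t | z)."""
    out = hazard(spec, z, t) * survival(spec, z, t)
    return out if np.ndim(out) else float(out)


def log_density(spec: MarginSpec, z, t):
    t = np.asarray(t, dtype=float)
    h0, H0 = _h0_H0(spec.dist, spec.lam, spec.k, t)
    lp = _lp(spec, z)
    return np.log(h0) + lp - H0 * np.exp(lp)


def quantile(spec: MarginSpec, z, p):
    """t with F(t | z) = p, i.e. S(t | z) = 1 - p (exact inversion)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")
    w = -np.log1p(-p) * np.exp(-_lp(spec, z))  # target value of H0(t)
    lam, k = spec.lam, spec.k
    if spec.dist == "weibull":
        t = np.power(w / lam, 1.0 / k)
    elif spec.dist == "gompertz":
        t = np.log1p(k * w / lam) / k
    else:
        t = np.power(np.expm1(w) / lam, 1.0 / k)
    return t if t.ndim else float(t)


def survival_inverse(spec: MarginSpec, z, s):
    """t with S(t | z) = s."""
    s = np.asarray(s, dtype=float)
    return quantile(spec, z, 1.0 - s)


# ---------------------------------------------------------------------------
# censored maximum likelihood
# ---------------------------------------------------------------------------

def _h0_H0_grads(dist: str, lam: float, k: float, t):
    """(h0, H0, dH0/dloglam, dH0/dlogk, dlogh0/dloglam, dlogh0/dlogk)."""
    t = np.asarray(t, dtype=float)
    lt = np.log(t)
    if dist == "weibull":
        H0 = lam * np.power(t, k)
        h0 = lam * k * np.power(t, k - 1.0)
        return h0, H0, H0, H0 * k * lt, 1.0, 1.0 + k * lt
    if dist == "gompertz":
        H0 = (lam / k) * np.expm1(k * t)
        h0 = lam * np.exp(k * t)
        return h0, H0, H0, lam * t * np.exp(k * t) - H0, 1.0, k * t
    # loglogistic
    w = lam * np.power(t, k)
    H0 = np.log1p(w)
    h0 = lam * k * np.power(t, k - 1.0) / (1.0 + w)
    r = w / (1.0 + w)
    return h0, H0, r, k * lt * r, 1.0 - r, 1.0 + k * lt * (1.0 - r)


def _neg_loglik(x, times, events, design, dist):
    if np.any(np.abs(x[:2]) > 30.0) or np.any(np.abs(x[2:]) > 50.0):
        return 1e12
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        lam, k = np.exp(x[0]), np.exp(x[1])
        beta = x[2:]
        h0, H0 = _h0_H0(dist, lam, k, times)
        lp = design @ beta if design is not None else 0.0
        ll = np.sum(events * (np.log(h0) + lp)) - np.sum(H0 * np.exp(lp))
    return -ll if np.isfinite(ll) else 1e12


def _neg_loglik_and_grad(x, times, events, design, dist):
    if np.any(np.abs(x[:2]) > 30.0) or np.any(np.abs(x[2:]) > 50.0):
        return 1e12, np.zeros_like(x)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        lam, k = np.exp(x[0]), np.exp(x[1])
        beta = x[2:]
        h0, H0, dH0_ds, dH0_dr, dlh_ds, dlh_dr = _h0_H0_grads(dist, lam, k, times)
        lp = design @ beta if design is not None else np.zeros_like(times)
        e = np.exp(lp)
        ll = np.sum(events * (np.log(h0) + lp)) - np.sum(H0 * e)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(x)
        g = np.empty_like(x)
        g[0] = np.sum(events * dlh_ds) - np.sum(e * dH0_ds)
        g[1] = np.sum(events * dlh_dr) - np.sum(e * dH0_dr)
        if design is not None:
            g[2:] = design.T @ (events - H0 * e)
        if not np.all(np.isfinite(g)):
            return 1e12, np.zeros_like(x)
    return -ll, -g


def _grad_ok(res, times, events, design, dist) -> bool:
    """Relative sup-norm check on the analytic gradient at the optimum."""
    _, g = _neg_loglik_and_grad(res.x, times, events, design, dist)
    return np.max(np.abs(g)) <= 1e-5 * max(1.0, abs(res.fun))


def fit_univariate(times, events, design=None, dist="weibull", init=None) -> MarginFit:
    """Censored ML fit of one parametric margin.

    Maximises ``sum[d log f(t|z) + (1-d) log S(t|z)]`` over
    (log lam, log k, beta) with BFGS; standard errors come from the
    observed information (central-difference Hessian), mapped back to the
    (lam, k) scale by the delta method.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    events = events.astype(float)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("cannot fit a margin with zero events (all censored)")
    if design is not None:
        design = np.asarray(design, dtype=float)
        if design.ndim == 1:
            design = design[:, None]
        p = design.shape[1]
    else:
        p = 0
    if dist not in DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {dist!r}")

    lam0 = n_events / times.sum()  # exponential-rate starting point
    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    elif dist == "gompertz":
        # k multiplies t inside an exponential: start near-exponential
        starts = [np.concatenate([[np.log(lam0), np.log(k0)], np.zeros(p)])
                  for k0 in (0.02, 0.1, 0.5)]
    else:
        starts = [np.concatenate([[np.log(lam0), np.log(k0)], np.zeros(p)])
                  for k0 in (1.0, 0.5, 2.0)]

    bounds = [(-30.0, 10.0), (-30.0, 10.0)] + [(-50.0, 50.0)] * p
    res = None
    for x0 in starts:
        cand = optimize.minimize(
            _neg_loglik_and_grad, x0, args=(times, events, design, dist),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-7},
        )
        if res is None or cand.fun < res.fun:
            res = cand
        if _grad_ok(cand, times, events, design, dist):
            res = cand
            break
    if not _grad_ok(res, times, events, design, dist):
        polish = optimize.minimize(
            _neg_loglik, res.x, args=(times, events, design, dist),
            method="Nelder-Mead",
            options={"maxiter": 3000, "xatol": 1e-9, "fatol": 1e-10})
        if polish.fun <= res.fun:
            res = polish
        if not _grad_ok(res, times, events, design, dist):
            raise RuntimeError(f"margin ML did not converge ({dist}): {res.message}")

    x = res.x
    H = central_hessian(lambda y: _neg_loglik(y, times, events, design, dist), x)
    try:
        cov = np.linalg.inv(H)
        se_x = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_x = np.full(x.size, np.nan)
    lam, k = np.exp(x[0]), np.exp(x[1])
    se = se_x.copy()
    se[0] *= lam  # delta method, log lam -> lam
    se[1] *= k
    spec = MarginSpec(dist, lam, k, x[2:])
    return MarginFit(spec=spec, se=se, loglik=-res.fun, n_events=n_events,
                     converged=bool(res.success), message=str(res.message))


def margin_loglik(spec: MarginSpec, times, events, design=None) -> float:
    """Censored log-likelihood of a margin at the given parameters."""
    x = np.concatenate([[np.log(spec.lam), np.log(spec.k)], spec.beta])
    d = None
    if design is not None:
        d = np.asarray(design, dtype=float)
        if d.ndim == 1:
            d = d[:, None]
    return -_neg_loglik(x, np.asarray(times, float), np.asarray(events, float), d, spec.dist)
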