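"""Archimedean copula primitives.

Four exchangeable one-parameter families — Clayton, Gumbel–Hougaard,
Frank and Joe — with everything a censored bivariate likelihood needs:
the CDF ``C_eta(u, v)``, its mixed density, the partial derivatives
``dC/du`` (the conditional distribution of V given U), the Kendall's-tau
maps in both directions, the Kendall distribution function
``K(w) = w - phi(w)/phi'(w)`` and random-pair generation.

All numeric entry points are vectorised over ``u``/``v`` and work in log
space where the family is prone to overflow (large dependence, survival
probabilities numerically at 0 or 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "FAMILIES",
    "CopulaSpec",
    "copula_cdf",
    "copula_density",
    "copula_logdensity",
    "copula_partial_u",
    "copula_partial_v",
    "copula_log_partial_u",
    "tau_from_eta",
    "eta_from_tau",
    "sample_pairs",
    "kendall_function",
    "kendall_function_inverse",
]

FAMILIES = ("clayton", "frank", "gumbel", "joe")

#: clamp applied to u, v inside log/power expressions; censored margins can
#: hand us survival probabilities numerically equal to 0 or 1.
EPS = 1e-12

# family -> (eta domain description, validity predicate)
_DOMAIN = {
    "clayton": ("eta > 0", lambda e: e > 0),
    "gumbel": ("eta >= 1", lambda e: e >= 1),
    "frank": ("eta != 0", lambda e: e != 0),
    "joe": ("eta >= 1", lambda e: e >= 1),
}


def _check_family(family: str) -> str:
    fam = str(family).lower()
    if fam not in _DOMAIN:
        raise ValueError(
            f"unknown copula family {family!r}; choose one of {FAMILIES}"
        )
    return fam


def _check_eta(family: str, eta: float) -> float:
    desc, ok = _DOMAIN[family]
    eta = float(eta)
    if not np.isfinite(eta) or not ok(eta):
        raise ValueError(
            f"{family} copula requires {desc}; got eta={eta!r}"
        )
    return eta


@dataclass(frozen=True)
class CopulaSpec:
    """An Archimedean family tag plus its dependence parameter eta."""

    family: str
    eta: float

    def __post_init__(self) -> None:
        fam = _check_family(self.family)
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "eta", _check_eta(fam, self.eta))

    @property
    def tau(self) -> float:
        return tau_from_eta(self)


def _clip01(x, lo=EPS, hi=1.0 - EPS):
    return np.clip(np.asarray(x, dtype=float), lo, hi)


# ---------------------------------------------------------------------------
# CDF
# ---------------------------------------------------------------------------

def _clayton_logcdf(eta, u, v):
    # log A with A = u^-eta + v^-eta - 1, computed without overflow
    a = -eta * np.log(u)
    b = -eta * np.log(v)
    m = np.maximum(a, b)
    log_a = m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))
    return -log_a / eta


def _gumbel_logcdf(eta, u, v):
    x = np.power(-np.log(u), eta)
    y = np.power(-np.log(v), eta)
    return -np.power(x + y, 1.0 / eta)


def _frank_cdf(eta, u, v):
    gu = np.expm1(-eta * u)
    gv = np.expm1(-eta * v)
    d = np.expm1(-eta)
    return -np.log1p(gu * gv / d) / eta


def _joe_T(eta, u, v):
    a = np.exp(eta * np.log1p(-u))
    b = np.exp(eta * np.log1p(-v))
    return a + b - a * b, a, b


def _joe_cdf(eta, u, v):
    T, _, _ = _joe_T(eta, u, v)
    return 1.0 - np.power(T, 1.0 / eta)


def copula_cdf(spec: CopulaSpec, u, v):
    """Evaluate ``C_eta(u, v)`` for ``u, v`` in [0, 1] (vectorised)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u > 1) | (v < 0) | (v > 1)):
        raise ValueError("u and v must lie in [0, 1]")
    uc, vc = _clip01(u), _clip01(v)
    eta = spec.eta
    if spec.family == "clayton":
        c = np.exp(_clayton_logcdf(eta, uc, vc))
    elif spec.family == "gumbel":
        c = np.exp(_gumbel_logcdf(eta, uc, vc))
    elif spec.family == "frank":
        c = _frank_cdf(eta, uc, vc)
    else:
        c = _joe_cdf(eta, uc, vc)
    # exact boundary behaviour, unaffected by the interior clamp
    c = np.where(u <= 0, 0.0, np.where(v <= 0, 0.0, c))
    c = np.where(u >= 1, np.minimum(v, 1.0), np.where(v >= 1, np.minimum(u, 1.0), c))
    out = np.clip(c, 0.0, 1.0)
    return out if out.ndim else float(out)


def copula_logcdf(spec: CopulaSpec, u, v):
    """log C(u, v) with inputs clamped into the open unit square."""
    u = _clip01(u)
    v = _clip01(v)
    eta = spec.eta
    if spec.family == "clayton":
        return _clayton_logcdf(eta, u, v)
    if spec.family == "gumbel":
        return _gumbel_logcdf(eta, u, v)
    if spec.family == "frank":
        c = _frank_cdf(eta, u, v)
    else:
        c = _joe_cdf(eta, u, v)
    return np.log(np.clip(c, 1e-300, None))


# ---------------------------------------------------------------------------
# density  c(u,v) = d2 C / du dv
# ---------------------------------------------------------------------------

def copula_logdensity(spec: CopulaSpec, u, v):
    """log of the copula density; inputs clamped into the open square."""
    u = _clip01(u)
    v = _clip01(v)
    eta = spec.eta
    lu, lv = np.log(u), np.log(v)
    if spec.family == "clayton":
        a, b = -eta * lu, -eta * lv
        m = np.maximum(a, b)
        log_a = m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))
        return np.log1p(eta) - (eta + 1.0) * (lu + lv) - (2.0 + 1.0 / eta) * log_a
    if spec.family == "gumbel":
        llu, llv = np.log(-lu), np.log(-lv)
        s = np.power(-lu, eta) + np.power(-lv, eta)
        s_pow = np.power(s, 1.0 / eta)
        return (
            -s_pow
            + (1.0 / eta - 2.0) * np.log(s)
            + (eta - 1.0) * (llu + llv)
            - lu
            - lv
            + np.log(s_pow + eta - 1.0)
        )
    if spec.family == "frank":
        gu = np.expm1(-eta * u)
        gv = np.expm1(-eta * v)
        d = np.expm1(-eta)
        denom = d + gu * gv
        return (
            np.log(np.abs(eta)) + np.log(np.abs(d)) - eta * (u + v)
            - 2.0 * np.log(np.abs(denom))
        )
    # joe
    T, _, _ = _joe_T(eta, u, v)
    return (
        (1.0 / eta - 2.0) * np.log(T)
        + (eta - 1.0) * (np.log1p(-u) + np.log1p(-v))
        + np.log(eta - 1.0 + T)
    )


def copula_density(spec: CopulaSpec, u, v):
    """Copula density on the open unit square; boundary inputs are rejected."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
        raise ValueError("copula_density requires u, v in the open interval (0, 1)")
    out = np.exp(copula_logdensity(spec, u, v))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# partial derivative dC/du (conditional CDF of V | U = u)
# ---------------------------------------------------------------------------

def copula_log_partial_u(spec: CopulaSpec, u, v):
    u = _clip01(u)
    v = _clip01(v)
    eta = spec.eta
    if spec.family == "clayton":
        lu, lv = np.log(u), np.log(v)
        a, b = -eta * lu, -eta * lv
        m = np.maximum(a, b)
        log_a = m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))
        return -(eta + 1.0) * lu - (1.0 + 1.0 / eta) * log_a
    if spec.family == "gumbel":
        lu, lv = np.log(u), np.log(v)
        s = np.power(-lu, eta) + np.power(-lv, eta)
        return (
            -np.power(s, 1.0 / eta)
            + (1.0 / eta - 1.0) * np.log(s)
            + (eta - 1.0) * np.log(-lu)
            - lu
        )
    if spec.family == "frank":
        gu = np.expm1(-eta * u)
        gv = np.expm1(-eta * v)
        d = np.expm1(-eta)
        val = np.exp(-eta * u) * gv / (d + gu * gv)
        return np.log(np.clip(val, 1e-300, None))
    # joe
    T, _, b = _joe_T(eta, u, v)
    return (1.0 / eta - 1.0) * np.log(T) + np.log1p(-b) + (eta - 1.0) * np.log1p(-u)


def copula_partial_u(spec: CopulaSpec, u, v):
    """``dC/du`` in [0, 1]; ``u`` must be interior, ``v`` may hit 0/1."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("copula_partial_u requires u in the open interval (0, 1)")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("v must lie in [0, 1]")
    p = np.exp(copula_log_partial_u(spec, u, v))
    p = np.where(v <= 0, 0.0, np.where(v >= 1, 1.0, p))
    out = np.clip(p, 0.0, 1.0)
    return out if out.ndim else float(out)


def copula_partial_v(spec: CopulaSpec, u, v):
    """``dC/dv``; the families here are exchangeable, so swap arguments."""
    return copula_partial_u(spec, v, u)


def copula_log_partial_v(spec: CopulaSpec, u, v):
    return copula_log_partial_u(spec, v, u)


# ---------------------------------------------------------------------------
# derivatives of the log likelihood terms with respect to (u, v)
# (used to build analytic gradients of the censored bivariate likelihood)
# ---------------------------------------------------------------------------

def dlog_cdf_duv(spec: CopulaSpec, u, v):
    """(d/du, d/dv) of log C(u, v)."""
    u = _clip01(u)
    v = _clip01(v)
    eta = spec.eta
    if spec.family == "clayton":
        lu, lv = np.log(u), np.log(v)
        a, b = -eta * lu, -eta * lv
        m = np.maximum(a, b)
        log_a = m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))
        gu = np.exp(-(eta + 1.0) * lu - log_a)
        gv = np.exp(-(eta + 1.0) * lv - log_a)
        return gu, gv
    if spec.family == "gumbel":
        lu, lv = -np.log(u), -np.log(v)
        x, y = np.power(lu, eta), np.power(lv, eta)
        s = x + y
        fac = np.power(s, 1.0 / eta - 1.0)
        return fac * x / (u * lu), fac * y / (v * lv)
    if spec.family == "frank":
        c = np.clip(_frank_cdf(eta, u, v), 1e-300, None)
        gu = np.expm1(-eta * u)
        gv = np.expm1(-eta * v)
        d = np.expm1(-eta)
        denom = d + gu * gv
        return (np.exp(-eta * u) * gv / denom / c,
                np.exp(-eta * v) * gu / denom / c)
    # joe
    T, a, b = _joe_T(eta, u, v)
    C = np.clip(1.0 - np.power(T, 1.0 / eta), 1e-300, None)
    fac = np.power(T, 1.0 / eta - 1.0) / C
    return fac * a * (1.0 - b) / (1.0 - u), fac * b * (1.0 - a) / (1.0 - v)


def dlog_partial_u_duv(spec: CopulaSpec, u, v):
    """(d/du, d/dv) of log dC/du."""
    u = _clip01(u)
    v = _clip01(v)
    eta = spec.eta
    if spec.family == "clayton":
        lu, lv = np.log(u), np.log(v)
        a, b = -eta * lu, -eta * lv
        m = np.maximum(a, b)
        log_a = m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))
        pu = np.exp(-(eta + 1.0) * lu - log_a)
        pv = np.exp(-(eta + 1.0) * lv - log_a)
        return -(eta + 1.0) / u + (eta + 1.0) * pu, (eta + 1.0) * pv
    if spec.family == "gumbel":
        lu, lv = -np.log(u), -np.log(v)
        x, y = np.power(lu, eta), np.power(lv, eta)
        s = x + y
        dxdu = -eta * x / (u * lu)
        dydv = -eta * y / (v * lv)
        dlogC_du = np.power(s, 1.0 / eta - 1.0) * x / (u * lu)
        dlogC_dv = np.power(s, 1.0 / eta - 1.0) * y / (v * lv)
        gu = dlogC_du + (1.0 / eta - 1.0) * dxdu / s - (eta - 1.0) / (u * lu) - 1.0 / u
        gv = dlogC_dv + (1.0 / eta - 1.0) * dydv / s
        return gu, gv
    if spec.family == "frank":
        gu = np.expm1(-eta * u)
        gv = np.expm1(-eta * v)
        d = np.expm1(-eta)
        denom = d + gu * gv
        dgu = -eta * np.exp(-eta * u)
        dgv = -eta * np.exp(-eta * v)
        return (-eta - dgu * gv / denom,
                dgv / gv - gu * dgv / denom)
    # joe
    T, a, b = _joe_T(eta, u, v)
    dTdu = -eta * a * (1.0 - b) / (1.0 - u)
    dTdv = -eta * b * (1.0 - a) / (1.0 - v)
    gu = (1.0 / eta - 1.0) * dTdu / T - (eta - 1.0) / (1.0 - u)
    gv = (1.0 / eta - 1.0) * dTdv / T + eta * b / ((1.0 - v) * (1.0 - b))
    return gu, gv


def dlog_density_duv(spec: CopulaSpec, u, v):
    """(d/du, d/dv) of the log copula density."""
    u = _clip01(u)
    v = _clip01(v)
    eta = spec.eta
    if spec.family == "clayton":
        lu, lv = np.log(u), np.log(v)
        a, b = -eta * lu, -eta * lv
        m = np.maximum(a, b)
        log_a = m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))
        pu = np.exp(-(eta + 1.0) * lu - log_a)
        pv = np.exp(-(eta + 1.0) * lv - log_a)
        return (-(eta + 1.0) / u + (2.0 * eta + 1.0) * pu,
                -(eta + 1.0) / v + (2.0 * eta + 1.0) * pv)
    if spec.family == "gumbel":
        lu, lv = -np.log(u), -np.log(v)
        x, y = np.power(lu, eta), np.power(lv, eta)
        s = x + y
        p = np.power(s, 1.0 / eta)
        dxdu = -eta * x / (u * lu)
        dydv = -eta * y / (v * lv)
        dpdu = (1.0 / eta) * np.power(s, 1.0 / eta - 1.0) * dxdu
        dpdv = (1.0 / eta) * np.power(s, 1.0 / eta - 1.0) * dydv
        gu = (-dpdu + (1.0 / eta - 2.0) * dxdu / s - (eta - 1.0) / (u * lu)
              - 1.0 / u + dpdu / (p + eta - 1.0))
        gv = (-dpdv + (1.0 / eta - 2.0) * dydv / s - (eta - 1.0) / (v * lv)
              - 1.0 / v + dpdv / (p + eta - 1.0))
        return gu, gv
    if spec.family == "frank":
        gu = np.expm1(-eta * u)
        gv = np.expm1(-eta * v)
        d = np.expm1(-eta)
        denom = d + gu * gv
        dgu = -eta * np.exp(-eta * u)
        dgv = -eta * np.exp(-eta * v)
        return -eta - 2.0 * dgu * gv / denom, -eta - 2.0 * gu * dgv / denom
    # joe
    T, a, b = _joe_T(eta, u, v)
    dTdu = -eta * a * (1.0 - b) / (1.0 - u)
    dTdv = -eta * b * (1.0 - a) / (1.0 - v)
    gu = ((1.0 / eta - 2.0) * dTdu / T - (eta - 1.0) / (1.0 - u)
          + dTdu / (eta - 1.0 + T))
    gv = ((1.0 / eta - 2.0) * dTdv / T - (eta - 1.0) / (1.0 - v)
          + dTdv / (eta - 1.0 + T))
    return gu, gv


# ---------------------------------------------------------------------------
# Kendall's tau
# ---------------------------------------------------------------------------

def _debye1(x: float) -> float:
    """First Debye function D1(x) = (1/x) * int_0^x t/(e^t - 1) dt."""
    if x == 0:
        return 1.0
    val, _ = integrate.quad(lambda t: t / np.expm1(t) if t != 0 else 1.0, 0.0, x,
                            epsabs=1e-12, epsrel=1e-12, limit=200)
    return val / x


def _joe_tau(eta: float) -> float:
    # general Archimedean identity tau = 1 + 4 * int_0^1 phi(t)/phi'(t) dt
    # phi(t) = -log(1 - (1-t)^eta); phi/phi' = log(1-a) * (1-a) / (eta (1-t)^(eta-1))
    def integrand(t):
        one_m = 1.0 - t
        a = one_m**eta
        if a >= 1.0:
            return 0.0
        return np.log1p(-a) * (1.0 - a) / (eta * one_m ** (eta - 1.0))

    val, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-10, epsrel=1e-10,
                            limit=400)
    return 1.0 + 4.0 * val


def tau_from_eta(spec: CopulaSpec) -> float:
    """Kendall's tau implied by the family's dependence parameter."""
    eta = spec.eta
    if spec.family == "clayton":
        return eta / (eta + 2.0)
    if spec.family == "gumbel":
        return 1.0 - 1.0 / eta
    if spec.family == "frank":
        # odd in eta: tau(-eta) = -tau(eta)
        x = abs(eta)
        tau = 1.0 - (4.0 / x) * (1.0 - _debye1(x))
        return float(np.sign(eta) * tau)
    return float(_joe_tau(eta))


_TAU_RANGE = {
    # open intervals of achievable tau per family
    "clayton": (0.0, 1.0),
    "gumbel": (0.0, 1.0),
    "frank": (-1.0, 1.0),
    "joe": (0.0, 1.0),
}


def eta_from_tau(family: str, tau: float) -> float:
    """Invert the tau map (closed form where available, else root-finding)."""
    fam = _check_family(family)
    tau = float(tau)
    lo, hi = _TAU_RANGE[fam]
    closed_at_zero = fam in ("gumbel", "joe")  # tau = 0 at eta = 1
    if not (lo < tau < hi) and not (closed_at_zero and tau == 0.0):
        raise ValueError(
            f"tau={tau} is not achievable by the {fam} family "
            f"(achievable range: ({lo}, {hi})"
            + (", incl. 0" if closed_at_zero else "") + ")"
        )
    if fam == "clayton":
        return 2.0 * tau / (1.0 - tau)
    if fam == "gumbel":
        return 1.0 / (1.0 - tau)
    if fam == "frank":
        if tau == 0.0:
            raise ValueError("frank requires eta != 0; tau=0 is the excluded limit")
        f = lambda e: tau_from_eta(CopulaSpec("frank", e)) - tau
        x = abs(tau)
        hi_b = 1.0
        while tau_from_eta(CopulaSpec("frank", hi_b)) < x:
            hi_b *= 2.0
            if hi_b > 1e6:  # pragma: no cover
                raise ValueError(f"tau={tau} out of reach for frank")
        root = optimize.brentq(
            lambda e: tau_from_eta(CopulaSpec("frank", e)) - x, 1e-8, hi_b,
            xtol=1e-12, rtol=1e-14)
        return float(np.sign(tau) * root)
    # joe
    if tau == 0.0:
        return 1.0
    hi_b = 2.0
    while _joe_tau(hi_b) < tau:
        hi_b *= 2.0
        if hi_b > 1e6:  # pragma: no cover
            raise ValueError(f"tau={tau} out of reach for joe")
    return float(optimize.brentq(lambda e: _joe_tau(e) - tau, 1.0 + 1e-10, hi_b,
                                 xtol=1e-12, rtol=1e-14))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_clayton(eta, n, rng):
    # gamma frailty (Marshall–Olkin): psi(s) = (1+s)^(-1/eta)
    g = rng.gamma(1.0 / eta, 1.0, size=n)
    e = rng.exponential(size=(2, n))
    return np.power(1.0 + e[0] / g, -1.0 / eta), np.power(1.0 + e[1] / g, -1.0 / eta)


def _sample_gumbel(eta, n, rng):
    # positive-stable frailty, Chambers–Mallows–Stuck; psi(s) = exp(-s^(1/eta))
    alpha = 1.0 / eta
    w = rng.uniform(0.0, np.pi, size=n)
    e0 = rng.exponential(size=n)
    s = (
        np.sin(alpha * w) / np.power(np.sin(w), 1.0 / alpha)
        * np.power(np.sin((1.0 - alpha) * w) / e0, (1.0 - alpha) / alpha)
    )
    e = rng.exponential(size=(2, n))
    return np.exp(-np.power(e[0] / s, alpha)), np.exp(-np.power(e[1] / s, alpha))


def _sample_frank(eta, n, rng):
    # closed-form conditional inversion
    u = rng.uniform(size=n)
    p = rng.uniform(size=n)
    d = np.expm1(-eta)
    gu = np.expm1(-eta * u)
    gv = p * d / (np.exp(-eta * u) - p * gu)
    v = -np.log1p(gv) / eta
    return u, np.clip(v, EPS, 1.0 - EPS)


def _sample_conditional(spec, n, rng):
    # generic conditional inversion: solve dC/du(u, v) = p in v by bisection
    u = rng.uniform(EPS, 1.0 - EPS, size=n)
    p = rng.uniform(size=n)
    lo = np.full(n, EPS)
    hi = np.full(n, 1.0 - EPS)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = np.exp(copula_log_partial_u(spec, u, mid)) < p
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return u, 0.5 * (lo + hi)


def sample_pairs(spec: CopulaSpec, n: int, seed=None):
    """Draw ``n`` dependent Uniform(0,1) pairs from the copula.

    Clayton and Gumbel use exact frailty constructions, Frank its
    closed-form conditional inverse, and Joe generic conditional
    inversion by vectorised bisection.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.family == "clayton":
        u, v = _sample_clayton(spec.eta, n, rng)
    elif spec.family == "gumbel":
        u, v = _sample_gumbel(spec.eta, n, rng)
    elif spec.family == "frank":
        u, v = _sample_frank(spec.eta, n, rng)
    else:
        u, v = _sample_conditional(spec, n, rng)
    u = np.clip(u, EPS, 1.0 - EPS)
    v = np.clip(v, EPS, 1.0 - EPS)
    return np.column_stack([u, v])


# ---------------------------------------------------------------------------
# Kendall distribution function K(w) = w - phi(w)/phi'(w)
# ---------------------------------------------------------------------------

def _phi_ratio(spec: CopulaSpec, w):
    """phi(w) / phi'(w) for the family generator (negative on (0,1))."""
    eta = spec.eta
    w = _clip01(w)
    if spec.family == "clayton":
        # phi = (w^-eta - 1)/eta, phi' = -w^-(eta+1)
        return -(w - np.power(w, eta + 1.0)) / eta
    if spec.family == "gumbel":
        # phi = (-log w)^eta, phi' = -eta (-log w)^(eta-1) / w
        return w * np.log(w) / eta
    if spec.family == "frank":
        # phi = -log[(e^{-eta w} - 1)/(e^{-eta} - 1)]
        gw = np.expm1(-eta * w)
        d = np.expm1(-eta)
        phi = -(np.log(np.abs(gw)) - np.log(np.abs(d)))
        dphi = eta * np.exp(-eta * w) / gw
        return phi / dphi
    # joe: phi = -log(1 - (1-w)^eta); phi' = -eta (1-w)^(eta-1)/(1-(1-w)^eta)
    a = np.exp(eta * np.log1p(-w))
    phi = -np.log1p(-a)
    dphi = -eta * np.power(1.0 - w, eta - 1.0) / (1.0 - a)
    return phi / dphi


def kendall_function(spec: CopulaSpec, w):
    """Kendall distribution function, the CDF of W = C(U, V)."""
    w_arr = np.asarray(w, dtype=float)
    if np.any((w_arr <= 0) | (w_arr >= 1)):
        raise ValueError("kendall_function requires w in the open interval (0, 1)")
    out = np.clip(w_arr - _phi_ratio(spec, w_arr), 0.0, 1.0)
    return out if out.ndim else float(out)


def kendall_function_inverse(spec: CopulaSpec, p):
    """Quantile function of W = C(U, V), by bisection (K is increasing)."""
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("probabilities must lie in (0, 1)")
    lo = np.full(p_arr.shape, EPS)
    hi = np.full(p_arr.shape, 1.0 - EPS)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = kendall_function(spec, mid) < p_arr
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    return out if np.asarray(p).ndim else float(out[0])
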