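"""Bivariate right-censored copula likelihood and its maximisation.

The joint survival model is the survival copula

    S(t1, t2 | z) = C_eta( S1(t1 | z), S2(t2 | z) )

with parametric PH margins (see :mod:`copsurv.margins`).  With
``u = S1(y1|z)``, ``v = S2(y2|z)`` a subject contributes, by censoring
pattern (d1, d2):

    (1,1)  log c(u,v)   + log f1(y1) + log f2(y2)
    (1,0)  log dC/du    + log f1(y1)
    (0,1)  log dC/dv    + log f2(y2)
    (0,0)  log C(u,v)

Two estimators are provided: two-stage pseudo-ML (margins first, then the
dependence parameter with margins frozen) and full ML over all parameters
jointly, plus an AIC comparison across the family x margin grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from . import copulas as cop
from . import io as cohort_io
from . import margins as mg
from ._numeric import central_hessian

__all__ = [
    "BivariateData",
    "JointFitResult",
    "joint_loglik",
    "fit_two_stage",
    "fit_full_ml",
    "compare_models",
    "hazard_ratio_table",
]


@dataclass
class BivariateData:
    """Paired (time, indicator) observations plus an encoded design matrix."""

    y1: np.ndarray
    y2: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    Z: np.ndarray | None = None
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=float)
        self.y2 = np.asarray(self.y2, dtype=float)
        self.d1 = np.asarray(self.d1, dtype=int)
        self.d2 = np.asarray(self.d2, dtype=int)
        if self.y1.size == 0:
            raise ValueError("empty data")
        if np.any(self.y1 <= 0) or np.any(self.y2 <= 0):
            raise ValueError("observed times must be strictly positive")
        for d in (self.d1, self.d2):
            if not np.isin(d, (0, 1)).all():
                raise ValueError("event indicators must be 0/1")
        if self.Z is not None:
            self.Z = np.asarray(self.Z, dtype=float)
            if self.Z.ndim == 1:
                self.Z = self.Z[:, None]
            if not self.names:
                self.names = [f"x{i}" for i in range(self.Z.shape[1])]

    @property
    def n(self) -> int:
        return self.y1.size

    @property
    def n_covariates(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    @classmethod
    def from_cohort(cls, df: pd.DataFrame) -> "BivariateData":
        X, names = cohort_io.design_matrix(df)
        return cls(df["y_left"].to_numpy(), df["y_right"].to_numpy(),
                   df["d_left"].to_numpy(), df["d_right"].to_numpy(),
                   Z=X, names=names)


@dataclass
class JointFitResult:
    copula: cop.CopulaSpec
    margin1: mg.MarginSpec
    margin2: mg.MarginSpec
    shared_margins: bool
    method: str                  # "two_stage" | "full_ml"
    param_names: list
    estimates: np.ndarray        # natural scale, same order as param_names
    se: np.ndarray               # natural scale; two-stage: only eta's SE is
                                 # meaningful and ignores stage-1 noise
    loglik: float
    n: int
    converged: bool
    notes: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def tau(self) -> float:
        return cop.tau_from_eta(self.copula)

    @property
    def eta(self) -> float:
        return self.copula.eta

    def se_for(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])

    def estimate_for(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _loglik_terms(spec: cop.CopulaSpec, m1: mg.MarginSpec, m2: mg.MarginSpec,
                  data: BivariateData) -> np.ndarray:
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        return _loglik_terms_raw(spec, m1, m2, data)


def _loglik_terms_raw(spec, m1, m2, data):
    z = data.Z
    u = np.exp(-mg.cumulative_hazard(m1, z, data.y1))
    v = np.exp(-mg.cumulative_hazard(m2, z, data.y2))
    d1 = data.d1.astype(bool)
    d2 = data.d2.astype(bool)
    out = np.empty(data.n)

    b11 = d1 & d2
    b10 = d1 & ~d2
    b01 = ~d1 & d2
    b00 = ~d1 & ~d2
    if b11.any():
        out[b11] = (
            cop.copula_logdensity(spec, u[b11], v[b11])
            + mg.log_density(m1, _rows(z, b11), data.y1[b11])
            + mg.log_density(m2, _rows(z, b11), data.y2[b11])
        )
    if b10.any():
        out[b10] = (
            cop.copula_log_partial_u(spec, u[b10], v[b10])
            + mg.log_density(m1, _rows(z, b10), data.y1[b10])
        )
    if b01.any():
        out[b01] = (
            cop.copula_log_partial_v(spec, u[b01], v[b01])
            + mg.log_density(m2, _rows(z, b01), data.y2[b01])
        )
    if b00.any():
        out[b00] = cop.copula_logcdf(spec, u[b00], v[b00])
    return out


def _rows(Z, mask):
    return None if Z is None else Z[mask]


def joint_loglik(copula_spec: cop.CopulaSpec, margin, data: BivariateData) -> float:
    """Censored bivariate log-likelihood.

    ``margin`` is a single :class:`~copsurv.margins.MarginSpec` shared by
    both eyes or a (margin1, margin2) pair.
    """
    m1, m2 = (margin, margin) if isinstance(margin, mg.MarginSpec) else margin
    terms = _loglik_terms(copula_spec, m1, m2, data)
    bad = ~np.isfinite(terms)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"non-finite log-likelihood contribution at record index {idx} "
            f"(y1={data.y1[idx]}, y2={data.y2[idx]}, d1={data.d1[idx]}, d2={data.d2[idx]})"
        )
    return float(terms.sum())


def _copula_term_sum(spec, u, v, b11, b10, b01, b00):
    """Sum of the copula part of the likelihood at fixed pseudo-observations."""
    tot = 0.0
    if b11.any():
        tot += cop.copula_logdensity(spec, u[b11], v[b11]).sum()
    if b10.any():
        tot += cop.copula_log_partial_u(spec, u[b10], v[b10]).sum()
    if b01.any():
        tot += cop.copula_log_partial_v(spec, u[b01], v[b01]).sum()
    if b00.any():
        tot += cop.copula_logcdf(spec, u[b00], v[b00]).sum()
    return tot


def _nll_and_grad_shared(x, data: BivariateData, family: str, dist: str):
    """Joint negative log-likelihood and its gradient, shared margins.

    Margin-parameter components are analytic; the eta component uses a
    central difference of the copula term at fixed pseudo-observations.
    """
    n_cov = data.n_covariates
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        lam, k = np.exp(x[0]), np.exp(x[1])
        beta = x[2:2 + n_cov]
        t_eta = x[2 + n_cov]
        eta = _eta_from_t(family, t_eta)
        if not np.isfinite(lam) or not np.isfinite(k) or np.abs(x[:2]).max() > 30:
            return 1e12, np.zeros_like(x)
        spec = cop.CopulaSpec(family, eta)

        lp = data.Z @ beta if data.Z is not None else np.zeros(data.n)
        e = np.exp(lp)
        h01, H01, dH0s1, dH0r1, dlhs1, dlhr1 = mg._h0_H0_grads(dist, lam, k, data.y1)
        h02, H02, dH0s2, dH0r2, dlhs2, dlhr2 = mg._h0_H0_grads(dist, lam, k, data.y2)
        H1, H2 = H01 * e, H02 * e
        u = np.exp(-H1)
        v = np.exp(-H2)

        d1 = data.d1.astype(bool)
        d2 = data.d2.astype(bool)
        b11, b10 = d1 & d2, d1 & ~d2
        b01, b00 = ~d1 & d2, ~d1 & ~d2

        ll = _copula_term_sum(spec, u, v, b11, b10, b01, b00)
        ll += (mg.log_density(mg.MarginSpec(dist, lam, k, beta),
                              _rows(data.Z, d1), data.y1[d1]).sum()
               + mg.log_density(mg.MarginSpec(dist, lam, k, beta),
                                _rows(data.Z, d2), data.y2[d2]).sum())
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(x)

        # coefficients of du and dv per record, by censoring pattern
        cu = np.zeros(data.n)
        cv = np.zeros(data.n)
        if b11.any():
            cu[b11], cv[b11] = cop.dlog_density_duv(spec, u[b11], v[b11])
        if b10.any():
            cu[b10], cv[b10] = cop.dlog_partial_u_duv(spec, u[b10], v[b10])
        if b01.any():
            gv, gu = cop.dlog_partial_u_duv(spec, v[b01], u[b01])
            cu[b01], cv[b01] = gu, gv
        if b00.any():
            cu[b00], cv[b00] = cop.dlog_cdf_duv(spec, u[b00], v[b00])

        # du/dtheta = -u * dH1/dtheta etc.; event records add dlog f/dtheta
        au = -cu * u  # coefficient of dH1/dtheta
        av = -cv * v
        df1 = d1.astype(float)
        df2 = d2.astype(float)
        g = np.zeros_like(x)
        g[0] = (np.sum(au * e * dH0s1 + av * e * dH0s2)
                + np.sum(df1 * (dlhs1 - e * dH0s1) + df2 * (dlhs2 - e * dH0s2)))
        g[1] = (np.sum(au * e * dH0r1 + av * e * dH0r2)
                + np.sum(df1 * (dlhr1 - e * dH0r1) + df2 * (dlhr2 - e * dH0r2)))
        if n_cov:
            w = au * H1 + av * H2 + df1 * (1.0 - H1) + df2 * (1.0 - H2)
            g[2:2 + n_cov] = data.Z.T @ w

        # eta component: central difference at fixed (u, v)
        h = 1e-5 * max(1.0, abs(t_eta))
        cp_p = _copula_term_sum(cop.CopulaSpec(family, _eta_from_t(family, t_eta + h)),
                                u, v, b11, b10, b01, b00)
        cp_m = _copula_term_sum(cop.CopulaSpec(family, _eta_from_t(family, t_eta - h)),
                                u, v, b11, b10, b01, b00)
        g[2 + n_cov] = (cp_p - cp_m) / (2.0 * h)

        if not np.all(np.isfinite(g)):
            return 1e12, np.zeros_like(x)
    return -ll, -g


# ---------------------------------------------------------------------------
# eta transforms (optimizer works on an unconstrained scale)
# ---------------------------------------------------------------------------

_ETA_CAP = {"clayton": 200.0, "gumbel": 150.0, "joe": 150.0, "frank": 500.0}


def _eta_from_t(family: str, t: float) -> float:
    if family == "clayton":
        return min(np.exp(t), _ETA_CAP[family])
    if family in ("gumbel", "joe"):
        return min(1.0 + np.exp(t), _ETA_CAP[family])
    # frank: untransformed with the eta=0 point excluded
    if abs(t) < 1e-6:
        return 1e-6 if t >= 0 else -1e-6
    return float(np.clip(t, -_ETA_CAP["frank"], _ETA_CAP["frank"]))


def _t_from_eta(family: str, eta: float) -> float:
    if family == "clayton":
        return float(np.log(eta))
    if family in ("gumbel", "joe"):
        return float(np.log(max(eta - 1.0, 1e-10)))
    return float(eta)


# ---------------------------------------------------------------------------
# two-stage pseudo-ML (IFM)
# ---------------------------------------------------------------------------

def _stage1(data: BivariateData, dist: str, shared_margins: bool):
    if shared_margins:
        times = np.concatenate([data.y1, data.y2])
        events = np.concatenate([data.d1, data.d2])
        Z = None if data.Z is None else np.vstack([data.Z, data.Z])
        fit = mg.fit_univariate(times, events, Z, dist)
        return fit, fit
    f1 = mg.fit_univariate(data.y1, data.d1, data.Z, dist)
    f2 = mg.fit_univariate(data.y2, data.d2, data.Z, dist)
    return f1, f2


_TAU_STARTS = (0.2, 0.5, 0.8)


def _optimize_eta(objective, family: str):
    """Multi-start 1-D maximisation of the profile in eta."""
    best = None
    for tau0 in _TAU_STARTS:
        if family == "frank":
            t0 = _t_from_eta(family, cop.eta_from_tau(family, tau0))
        else:
            t0 = _t_from_eta(family, cop.eta_from_tau(family, tau0))
        res = optimize.minimize(lambda t: -objective(_eta_from_t(family, t[0])),
                                np.array([t0]), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_two_stage(data: BivariateData, family: str = "clayton",
                  dist: str = "weibull", shared_margins: bool = True,
                  pseudo: str = "parametric", _margin_fits=None) -> JointFitResult:
    """Two-stage pseudo maximum likelihood (inference-functions-for-margins).

    Stage 1 fits the margins — parametrically by censored ML (default) or
    nonparametrically via Kaplan–Meier pseudo-observations
    (``pseudo="rank"``).  Stage 2 maximises the joint likelihood over the
    dependence parameter alone.  The eta standard error comes from the
    stage-2 curvature only and does not propagate stage-1 noise.
    """
    if not (data.d1 & data.d2).any():
        raise ValueError("two-stage fit needs at least one doubly-uncensored pair")

    notes = ["eta SE from stage-2 curvature only (stage-1 noise not propagated)"]
    if pseudo == "rank":
        from .marginal_analysis import kaplan_meier
        km1 = kaplan_meier(data.y1, data.d1)
        km2 = kaplan_meier(data.y2, data.d2)
        u = np.clip(km1.survival_at(data.y1), cop.EPS, 1.0 - cop.EPS)
        v = np.clip(km2.survival_at(data.y2), cop.EPS, 1.0 - cop.EPS)

        def objective(eta):
            spec = cop.CopulaSpec(family, eta)
            d1 = data.d1.astype(bool)
            d2 = data.d2.astype(bool)
            term = np.where(
                d1 & d2, cop.copula_logdensity(spec, u, v),
                np.where(d1, cop.copula_log_partial_u(spec, u, v),
                         np.where(d2, cop.copula_log_partial_v(spec, u, v),
                                  cop.copula_logcdf(spec, u, v))))
            val = term.sum()
            return val if np.isfinite(val) else -1e12

        mfit1 = mfit2 = None
        notes.append("rank (KM pseudo-observation) margins; joint loglik not "
                     "comparable with parametric fits")
    elif pseudo == "parametric":
        mfit1, mfit2 = _margin_fits or _stage1(data, dist, shared_margins)

        def objective(eta):
            spec = cop.CopulaSpec(family, eta)
            try:
                val = _loglik_terms(spec, mfit1.spec, mfit2.spec, data).sum()
            except FloatingPointError:  # pragma: no cover
                return -1e12
            return val if np.isfinite(val) else -1e12
    else:
        raise ValueError("pseudo must be 'parametric' or 'rank'")

    best = _optimize_eta(objective, family)
    t_hat = float(best.x[0])
    eta_hat = _eta_from_t(family, t_hat)
    ll_joint = -float(best.fun)

    # curvature of the stage-2 objective on the natural eta scale
    h = 1e-4 * max(1.0, abs(eta_hat))
    try:
        d2 = (objective(eta_hat + h) - 2.0 * objective(eta_hat)
              + objective(eta_hat - h)) / h**2
        se_eta = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.inf
    except ValueError:
        se_eta = np.inf
    if not np.isfinite(se_eta):
        notes.append("flat stage-2 likelihood: eta SE unavailable")

    if mfit1 is None:
        spec1 = spec2 = mg.MarginSpec(dist, 1.0, 1.0, np.zeros(data.n_covariates))
        names = ["eta"]
        est = np.array([eta_hat])
        se = np.array([se_eta])
    else:
        spec1, spec2 = mfit1.spec, mfit2.spec
        names = _param_names(data, dist, shared_margins) + ["eta"]
        if shared_margins:
            est = np.concatenate([[spec1.lam, spec1.k], spec1.beta, [eta_hat]])
            se = np.concatenate([mfit1.se, [se_eta]])
        else:
            est = np.concatenate([[spec1.lam, spec1.k], spec1.beta,
                                  [spec2.lam, spec2.k], spec2.beta, [eta_hat]])
            se = np.concatenate([mfit1.se, mfit2.se, [se_eta]])

    converged = np.isfinite(se_eta) and bool(best.success)
    if not converged and not np.isfinite(se_eta):
        raise RuntimeError("stage-2 likelihood is flat in eta; fit did not converge")
    return JointFitResult(
        copula=cop.CopulaSpec(family, eta_hat), margin1=spec1, margin2=spec2,
        shared_margins=shared_margins, method="two_stage", param_names=names,
        estimates=est, se=se, loglik=ll_joint, n=data.n, converged=converged,
        notes=notes,
    )


def _param_names(data: BivariateData, dist: str, shared: bool) -> list:
    base = ["lam", "k"] + list(data.names)
    if shared:
        return base
    return [f"{n}_1" for n in base] + [f"{n}_2" for n in base]


# ---------------------------------------------------------------------------
# full ML
# ---------------------------------------------------------------------------

def _pack(data, family, dist, shared, m1: mg.MarginSpec, m2: mg.MarginSpec, eta):
    if shared:
        x = np.concatenate([[np.log(m1.lam), np.log(m1.k)], m1.beta])
    else:
        x = np.concatenate([[np.log(m1.lam), np.log(m1.k)], m1.beta,
                            [np.log(m2.lam), np.log(m2.k)], m2.beta])
    return np.concatenate([x, [_t_from_eta(family, eta)]])


def _unpack(x, data, family, dist, shared):
    p = data.n_covariates
    m1 = mg.MarginSpec(dist, np.exp(x[0]), np.exp(x[1]), x[2:2 + p])
    if shared:
        m2 = m1
        off = 2 + p
    else:
        off = 2 + p
        m2 = mg.MarginSpec(dist, np.exp(x[off]), np.exp(x[off + 1]),
                           x[off + 2:off + 2 + p])
        off = 2 * (2 + p)
    eta = _eta_from_t(family, x[off])
    return m1, m2, eta


def fit_full_ml(data: BivariateData, family: str = "clayton",
                dist: str = "weibull", shared_margins: bool = True,
                init_from_two_stage: bool = True,
                compute_se: bool = True, _margin_fits=None,
                gtol: float = 1e-5) -> JointFitResult:
    """Simultaneous ML over margin parameters and the copula parameter.

    Optimisation runs on (log lam, log k, beta, transformed eta); standard
    errors come from the central-difference observed information at the
    optimum, delta-mapped back to the natural scale.
    """
    notes = []
    if init_from_two_stage:
        ts = fit_two_stage(data, family, dist, shared_margins,
                           _margin_fits=_margin_fits)
        x0 = _pack(data, family, dist, shared_margins, ts.margin1, ts.margin2, ts.eta)
        ll_ts = ts.loglik
    else:
        p = data.n_covariates
        m0 = mg.MarginSpec(dist, float(np.mean(np.r_[data.d1, data.d2]))
                           / float(np.mean(np.r_[data.y1, data.y2])), 1.0, np.zeros(p))
        x0 = _pack(data, family, dist, shared_margins, m0, m0,
                   cop.eta_from_tau(family, 0.5))
        ll_ts = -np.inf

    def nll(x):
        m1, m2, eta = _unpack(x, data, family, dist, shared_margins)
        try:
            val = _loglik_terms(cop.CopulaSpec(family, eta), m1, m2, data).sum()
        except (FloatingPointError, ValueError):  # pragma: no cover
            return 1e12
        return -val if np.isfinite(val) else 1e12

    if shared_margins:
        res = optimize.minimize(_nll_and_grad_shared, x0,
                                args=(data, family, dist), jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": 1000, "ftol": 1e-11,
                                         "gtol": gtol})
    else:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 1000, "ftol": 1e-11,
                                         "gtol": gtol})
    # polish: L-BFGS-B with numeric gradients occasionally stops early
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-8,
                                          "fatol": 1e-10})
        if res2.fun < res.fun:
            res = res2
    loglik = -float(res.fun)
    if loglik < ll_ts - 1e-6:
        # the joint optimum can never be worse than the two-stage point
        res.x = x0
        loglik = ll_ts
        notes.append("optimizer failed to improve on the two-stage start")

    m1, m2, eta = _unpack(res.x, data, family, dist, shared_margins)
    names = _param_names(data, dist, shared_margins) + ["eta"]

    se = np.full(len(names), np.nan)
    if compute_se:
        H = central_hessian(nll, res.x)
        try:
            cov = np.linalg.inv(H)
            dse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            bad_hess = np.any(np.linalg.eigvalsh(H) <= 0)
        except np.linalg.LinAlgError:
            dse = np.full(len(names), np.nan)
            bad_hess = True
        if bad_hess:
            notes.append("observed information not positive definite; SEs unreliable")
        se = dse.copy()
        # delta method back to natural scale
        se[0] *= m1.lam
        se[1] *= m1.k
        off = 2 + data.n_covariates
        if not shared_margins:
            se[off] *= m2.lam
            se[off + 1] *= m2.k
        t_eta = res.x[-1]
        if family == "clayton":
            se[-1] *= np.exp(t_eta)
        elif family in ("gumbel", "joe"):
            se[-1] *= np.exp(t_eta)
        # frank: identity

    if shared_margins:
        est = np.concatenate([[m1.lam, m1.k], m1.beta, [eta]])
    else:
        est = np.concatenate([[m1.lam, m1.k], m1.beta, [m2.lam, m2.k], m2.beta, [eta]])

    return JointFitResult(
        copula=cop.CopulaSpec(family, eta), margin1=m1, margin2=m2,
        shared_margins=shared_margins, method="full_ml", param_names=names,
        estimates=est, se=se, loglik=loglik, n=data.n,
        converged=bool(res.success) or loglik >= ll_ts, notes=notes,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(data: BivariateData, families=cop.FAMILIES,
                   dists=mg.DISTRIBUTIONS, method: str = "full",
                   shared_margins: bool = True) -> pd.DataFrame:
    """Fit every (copula family, margin distribution) pair and rank by AIC.

    Ties break toward fewer parameters, then lexicographic family name.
    Per-cell failures are recorded in the ``error`` column, not raised.
    """
    families = list(dict.fromkeys(families))
    dists = list(dict.fromkeys(dists))
    if not families or not dists:
        raise ValueError("need at least one family and one margin distribution")
    rows = []
    fits = {}
    for dist in dists:
        try:
            stage1 = _stage1(data, dist, shared_margins)
        except (RuntimeError, ValueError) as exc:
            stage1 = exc
        for fam in families:
            try:
                if isinstance(stage1, Exception):
                    raise RuntimeError(f"margin fit failed: {stage1}")
                if method == "full":
                    fit = fit_full_ml(data, fam, dist, shared_margins,
                                      compute_se=False, _margin_fits=stage1,
                                      gtol=1e-4)
                elif method == "two_stage":
                    fit = fit_two_stage(data, fam, dist, shared_margins,
                                        _margin_fits=stage1)
                else:
                    raise ValueError("method must be 'full' or 'two_stage'")
                fits[(fam, dist)] = fit
                rows.append({
                    "family": fam, "dist": dist, "loglik": fit.loglik,
                    "n_params": fit.n_params, "aic": fit.aic, "eta": fit.eta,
                    "tau": fit.tau, "converged": fit.converged, "error": "",
                })
            except (RuntimeError, ValueError, FloatingPointError) as exc:
                rows.append({
                    "family": fam, "dist": dist, "loglik": np.nan,
                    "n_params": np.nan, "aic": np.inf, "eta": np.nan,
                    "tau": np.nan, "converged": False, "error": str(exc),
                })
    tbl = pd.DataFrame(rows).sort_values(
        ["aic", "n_params", "family"], kind="mergesort").reset_index(drop=True)
    tbl.attrs["fits"] = fits
    return tbl


def hazard_ratio_table(fit: JointFitResult) -> pd.DataFrame:
    """Per-covariate estimate, hazard ratio exp(beta) and Wald p-value."""
    if not fit.converged:
        raise ValueError("fit did not converge; no hazard-ratio table")
    rows = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, est, se in zip(fit.param_names, fit.estimates, fit.se):
            is_cov = name not in ("lam", "k", "eta") and not name.startswith(
                ("lam_", "k_"))
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            rows.append({
                "parameter": name,
                "estimate": est,
                "hr": np.exp(est) if is_cov else np.nan,
                "hr_rounded": format_hr(np.exp(est)) if is_cov else np.nan,
                "se": se,
                "p": 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            })
    return pd.DataFrame(rows)


def format_hr(hr: float) -> float:
    """Round a hazard ratio for reporting: 2 decimals, 3 when below 0.095."""
    return round(float(hr), 3 if hr < 0.095 else 2)
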