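"""Nonparametric and semi-parametric marginal analyses.

Kaplan–Meier product-limit estimation (with the "smallest time where the
curve drops to or below one half" median convention) and Cox
proportional-hazards regression.  Eyes from the same patient are
correlated, so the default Cox fit stacks both eyes and uses a robust
sandwich variance clustered by subject; a per-eye option exists.

Kaplan–Meier and the Efron-ties Cox fit are delegated to lifelines;
Breslow ties go through statsmodels' PHReg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from . import io as cohort_io

__all__ = [
    "KMEstimate",
    "CoxFit",
    "kaplan_meier",
    "median_survival",
    "cox_fit",
    "cox_fit_cohort",
    "univariable_screen",
]


@dataclass
class KMEstimate:
    """Stepwise survival curve with risk-set bookkeeping."""

    event_times: np.ndarray   # distinct times with >= 1 event, ascending
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray       # n at risk at each event time
    n_events_at: np.ndarray   # events at each event time
    median: float             # np.nan when the curve never reaches 0.5

    def survival_at(self, t):
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if np.ndim(t) else float(out)


@dataclass
class CoxFit:
    names: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    ties: str
    warnings: list

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def p(self) -> np.ndarray:
        from scipy.stats import norm
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2.0 * norm.sf(np.abs(z))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.names,
            "beta": self.beta,
            "hr": self.hr,
            "se": self.se,
            "p": self.p,
        })


def kaplan_meier(times, events) -> KMEstimate:
    """Product-limit estimate; ties share one factor, subjects censored at an
    event time are still counted at risk there."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    event_times = ev.index.to_numpy(dtype=float)
    s_at = surv.loc[ev.index].to_numpy(dtype=float)
    med = _median_from_curve(event_times, s_at)
    return KMEstimate(
        event_times=event_times,
        survival=s_at,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events_at=ev["observed"].to_numpy(dtype=int),
        median=med,
    )


def _median_from_curve(event_times, survival):
    below = survival <= 0.5
    if not below.any():
        return float("nan")
    return float(event_times[np.argmax(below)])


def median_survival(km: KMEstimate) -> float:
    """Smallest event time with S(t) <= 0.5; NaN when undefined."""
    return _median_from_curve(km.event_times, km.survival)


def cox_fit(times, events, design, names=None, ties: str = "efron",
            cluster=None) -> CoxFit:
    """Cox partial-likelihood fit.

    ``ties`` is "efron" (default; months-resolution data are heavily tied)
    or "breslow".  ``cluster`` (subject ids) requests a robust sandwich
    variance for stacked paired-organ data.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if events.sum() < 1:
        raise ValueError("need at least one event")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]

    warns: list[str] = []
    const = np.ptp(X, axis=0) == 0
    keep = ~const
    if const.any():
        warns.append(
            "degenerate (constant) covariates excluded, coefficient 0 with "
            f"infinite SE: {[n for n, c in zip(names, const) if c]}"
        )
    Xk = X[:, keep]
    kept_names = [n for n, c in zip(names, const) if not c]

    if ties == "efron":
        df = pd.DataFrame(Xk, columns=kept_names)
        df["time"] = times
        df["event"] = events
        kwargs = {}
        if cluster is not None:
            df["_cluster"] = np.asarray(cluster)
            kwargs["cluster_col"] = "_cluster"
        cph = CoxPHFitter(penalizer=0.0)
        import warnings as _warnings
        with _warnings.catch_warnings(record=True) as wlist:
            _warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event", **kwargs)
            warns += [str(w.message) for w in wlist
                      if "convergence" in str(w.message).lower()
                      or "complete separation" in str(w.message).lower()]
        beta_k = cph.params_.to_numpy()
        se_k = cph.standard_errors_.to_numpy()
        loglik = float(cph.log_likelihood_)
    elif ties == "breslow":
        from statsmodels.duration.hazard_regression import PHReg
        mod = PHReg(times, Xk, status=events, ties="breslow")
        res = mod.fit()
        beta_k = np.asarray(res.params)
        se_k = np.asarray(res.bse)
        loglik = float(mod.loglike(res.params))
    else:
        raise ValueError("ties must be 'efron' or 'breslow'")

    beta = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.inf)
    beta[keep] = beta_k
    se[keep] = se_k
    return CoxFit(names=names, beta=beta, se=se, loglik=loglik, ties=ties,
                  warnings=warns)


def cox_fit_cohort(df: pd.DataFrame, ties: str = "efron", eye: str = "both") -> CoxFit:
    """Table-2-style multivariable Cox fit on a cohort table.

    ``eye``: "both" stacks left+right records with cluster-robust SEs
    (default), or "left"/"right" for a single-eye fit.
    """
    if eye == "both":
        long = cohort_io.stack_eyes(df)
        X, names = cohort_io.design_matrix(long)
        return cox_fit(long["time"], long["event"], X, names=names, ties=ties,
                       cluster=long["subject_id"])
    X, names = cohort_io.design_matrix(df)
    return cox_fit(df[f"y_{eye}"], df[f"d_{eye}"], X, names=names, ties=ties)


def univariable_screen(df: pd.DataFrame, alpha: float = 0.25,
                       ties: str = "efron") -> list:
    """Retain covariates whose single-covariate Cox fit has Wald p < alpha.

    Each covariate (age, or one categorical with its full dummy block) is
    fit alone on the stacked-eyes data; a categorical is retained when any
    of its level contrasts passes the threshold.
    """
    long = cohort_io.stack_eyes(df)
    X, names = cohort_io.design_matrix(long)
    retained = []
    blocks = {"age": ["age"]}
    for cov, levels in cohort_io.CATEGORIES.items():
        blocks[cov] = [f"{cov}_{lvl}" for lvl in levels[1:]]
    for cov, cols in blocks.items():
        idx = [names.index(c) for c in cols]
        fit = cox_fit(long["time"], long["event"], X[:, idx], names=cols,
                      ties=ties, cluster=long["subject_id"])
        if np.any(fit.p < alpha):
            retained.append(cov)
    return retained
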