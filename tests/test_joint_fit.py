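"""Joint censored copula likelihood, two-stage and full ML, AIC comparison."""

import numpy as np
import pytest
from scipy import integrate

from copsurv import copulas as cp
from copsurv import joint_fit as jf
from copsurv import margins as mg
from copsurv import synth


def _mixed_records(n=8, seed=3):
    rng = np.random.default_rng(seed)
    spec = mg.MarginSpec("weibull", 0.3, 1.4, np.array([0.5]))
    Z = rng.binomial(1, 0.5, n).reshape(-1, 1).astype(float)
    y1 = mg.quantile(spec, Z, rng.uniform(0.05, 0.95, n))
    y2 = mg.quantile(spec, Z, rng.uniform(0.05, 0.95, n))
    d1 = np.array([1, 1, 0, 0, 1, 0, 1, 0])[:n]
    d2 = np.array([1, 0, 1, 0, 0, 1, 1, 0])[:n]
    return jf.BivariateData(y1, y2, d1, d2, Z=Z), spec


def _oracle_loglik(cspec, mspec, data):
    """Brute force: numerically integrated margins + finite differences of C."""
    def s_num(t, z):
        val, _ = integrate.quad(lambda x: mg.density(mspec, z, x), 0.0, t,
                                limit=200)
        return 1.0 - val

    def joint_s(t1, t2, z):
        return cp.copula_cdf(cspec, s_num(t1, z), s_num(t2, z))

    h = 1e-4
    total = 0.0
    for i in range(data.n):
        y1, y2, z = data.y1[i], data.y2[i], data.Z[i]
        d1, d2 = data.d1[i], data.d2[i]
        if d1 and d2:
            val = (joint_s(y1 + h, y2 + h, z) - joint_s(y1 + h, y2 - h, z)
                   - joint_s(y1 - h, y2 + h, z)
                   + joint_s(y1 - h, y2 - h, z)) / (4 * h * h)
        elif d1:
            val = -(joint_s(y1 + h, y2, z) - joint_s(y1 - h, y2, z)) / (2 * h)
        elif d2:
            val = -(joint_s(y1, y2 + h, z) - joint_s(y1, y2 - h, z)) / (2 * h)
        else:
            val = joint_s(y1, y2, z)
        total += np.log(val)
    return total


@pytest.mark.parametrize("family,eta", [("clayton", 3.0), ("gumbel", 2.0),
                                        ("frank", 4.0), ("joe", 2.2)])
def test_joint_loglik_matches_brute_force_oracle(family, eta):
    data, mspec = _mixed_records()
    cspec = cp.CopulaSpec(family, eta)
    assert jf.joint_loglik(cspec, mspec, data) == pytest.approx(
        _oracle_loglik(cspec, mspec, data), abs=1e-4)


def test_joint_loglik_factorizes_at_independence():
    data, mspec = _mixed_records()
    near_indep = cp.CopulaSpec("frank", 1e-8)
    expected = (mg.margin_loglik(mspec, data.y1, data.d1, data.Z)
                + mg.margin_loglik(mspec, data.y2, data.d2, data.Z))
    assert jf.joint_loglik(near_indep, mspec, data) == pytest.approx(
        expected, abs=1e-5)


def test_joint_loglik_single_censored_record_is_log_cdf():
    mspec = mg.MarginSpec("weibull", 0.3, 1.4)
    data = jf.BivariateData([2.0], [5.0], [0], [0])
    cspec = cp.CopulaSpec("clayton", 2.0)
    u = mg.survival(mspec, None, 2.0)
    v = mg.survival(mspec, None, 5.0)
    assert jf.joint_loglik(cspec, mspec, data) == pytest.approx(
        np.log(cp.copula_cdf(cspec, u, v)), abs=1e-12)


def test_joint_loglik_all_events_uses_only_density_branch():
    data, mspec = _mixed_records()
    data = jf.BivariateData(data.y1, data.y2, np.ones(data.n, int),
                            np.ones(data.n, int), Z=data.Z)
    cspec = cp.CopulaSpec("clayton", 3.0)
    u = mg.survival(mspec, data.Z, data.y1)
    v = mg.survival(mspec, data.Z, data.y2)
    expected = (cp.copula_logdensity(cspec, u, v).sum()
                + mg.log_density(mspec, data.Z, data.y1).sum()
                + mg.log_density(mspec, data.Z, data.y2).sum())
    assert jf.joint_loglik(cspec, mspec, data) == pytest.approx(expected)


def test_two_stage_near_zero_tau_on_independent_data(rng):
    spec = mg.MarginSpec("weibull", 0.3, 1.3)
    n = 600
    y1 = mg.quantile(spec, None, rng.uniform(1e-9, 1 - 1e-9, n))
    y2 = mg.quantile(spec, None, rng.uniform(1e-9, 1 - 1e-9, n))
    data = jf.BivariateData(y1, y2, np.ones(n, int), np.ones(n, int))
    fit = jf.fit_two_stage(data, "frank", "weibull")
    assert abs(fit.tau) < 0.05


def test_two_stage_objective_peaks_at_estimate(continuous_data):
    fit = jf.fit_two_stage(continuous_data, "clayton", "weibull")
    margins = (fit.margin1, fit.margin2)
    at_hat = jf.joint_loglik(fit.copula, margins, continuous_data)
    at_truth = jf.joint_loglik(cp.CopulaSpec("clayton", 9.57), margins,
                               continuous_data)
    assert at_hat >= at_truth - 1e-8
    assert np.isfinite(fit.se_for("eta"))


def test_two_stage_rank_pseudo_mode(continuous_data):
    fit = jf.fit_two_stage(continuous_data, "clayton", "weibull", pseudo="rank")
    assert fit.tau == pytest.approx(0.827, abs=0.08)


def test_two_stage_requires_a_complete_pair():
    data = jf.BivariateData([1.0, 2.0], [1.0, 2.0], [1, 0], [0, 1])
    with pytest.raises(ValueError, match="doubly-uncensored"):
        jf.fit_two_stage(data)


@pytest.mark.parametrize("family", cp.FAMILIES)
def test_full_ml_never_below_two_stage(continuous_data, family):
    ts = jf.fit_two_stage(continuous_data, family, "weibull")
    full = jf.fit_full_ml(continuous_data, family, "weibull", compute_se=False)
    assert full.loglik >= ts.loglik - 1e-6


def test_full_ml_profile_unimodal_near_truth(continuous_data):
    """Profile of the joint likelihood in eta peaks near the simulated truth."""
    fit = jf.fit_full_ml(continuous_data, "clayton", "weibull", compute_se=False)
    margins = (fit.margin1, fit.margin2)
    etas = np.linspace(4.0, 20.0, 17)
    prof = [jf.joint_loglik(cp.CopulaSpec("clayton", e), margins,
                            continuous_data) for e in etas]
    peak = etas[int(np.argmax(prof))]
    assert 6.0 <= peak <= 14.0  # truth eta = 9.57
    diffs = np.sign(np.diff(prof))
    assert np.sum(np.diff(diffs) != 0) <= 1  # one sign change: unimodal


def test_aic_identity_and_tie_breaking(continuous_data):
    tbl = jf.compare_models(continuous_data, families=["clayton", "clayton"],
                            dists=["weibull"])
    assert len(tbl) == 1  # duplicates removed
    row = tbl.iloc[0]
    assert row["aic"] == pytest.approx(-2 * row["loglik"] + 2 * row["n_params"])
    assert row["n_params"] == 2 + 13 + 1


def test_compare_models_requires_nonempty_sets(continuous_data):
    with pytest.raises(ValueError):
        jf.compare_models(continuous_data, families=[], dists=["weibull"])


def test_hazard_ratio_table_rounding_and_zero():
    assert jf.format_hr(np.exp(-0.23)) == 0.79
    assert jf.format_hr(np.exp(-0.33)) == 0.72
    assert jf.format_hr(np.exp(-2.48)) == 0.084
    assert jf.format_hr(np.exp(0.0)) == 1.0


def test_hazard_ratio_table_contents(continuous_data):
    fit = jf.fit_full_ml(continuous_data, "clayton", "weibull")
    tbl = jf.hazard_ratio_table(fit)
    assert list(tbl["parameter"])[:2] == ["lam", "k"]
    assert list(tbl["parameter"])[-1] == "eta"
    cov = tbl[~tbl["parameter"].isin(["lam", "k", "eta"])]
    np.testing.assert_allclose(cov["hr"], np.exp(cov["estimate"]))
    assert ((cov["p"].dropna() >= 0) & (cov["p"].dropna() <= 1)).all()


def test_full_ml_null_covariate_centred_on_zero(rng):
    """A covariate with no true effect gets coefficients centred on 0."""
    beta = synth.default_beta()
    beta[1] = 0.0  # null out the gender effect
    cfg = synth.CohortConfig(
        n=400, margin=mg.MarginSpec("weibull", 0.28, 1.65, beta),
        median_months=None, rounding="none")
    vals = []
    for s in range(6):
        df, _ = synth.generate_cohort(cfg, seed=900 + s)
        fit = jf.fit_full_ml(jf.BivariateData.from_cohort(df),
                             compute_se=False)
        vals.append(fit.estimate_for("gender_male"))
    assert abs(np.mean(vals)) < 0.1
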