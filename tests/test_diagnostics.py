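"""Diagnostics: empirical tau, Kendall Q-Q, CvM bootstrap, scatter."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from copsurv import copulas as cp
from copsurv import diagnostics as dg
from copsurv import joint_fit as jf


@pytest.fixture(scope="module")
def fitted(continuous_data_module):
    data = continuous_data_module
    return data, jf.fit_full_ml(data, "clayton", "weibull", compute_se=False)


@pytest.fixture(scope="module")
def continuous_data_module():
    from copsurv import synth
    df, _ = synth.generate_cohort(synth.CohortConfig(rounding="none"), seed=11)
    return jf.BivariateData.from_cohort(df)


def _brute_force_tau(x, y):
    n = len(x)
    num = den1 = den2 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[i] - x[j])
            sy = np.sign(y[i] - y[j])
            num += sx * sy
            den1 += sx != 0
            den2 += sy != 0
    return num / np.sqrt(den1 * den2)


def test_empirical_tau_perfect_concordance():
    data = jf.BivariateData([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                            [1, 1, 1], [1, 1, 1])
    assert dg.empirical_tau(data) == 1.0


def test_empirical_tau_matches_brute_force(rng):
    y1 = rng.exponential(1.0, 40)
    y2 = 0.5 * y1 + rng.exponential(1.0, 40)
    data = jf.BivariateData(y1, y2, np.ones(40, int), np.ones(40, int))
    assert dg.empirical_tau(data) == pytest.approx(
        _brute_force_tau(y1, y2), abs=1e-12)


def test_empirical_tau_recovers_simulated_dependence():
    spec = cp.CopulaSpec("clayton", cp.eta_from_tau("clayton", 0.83))
    pairs = cp.sample_pairs(spec, 5000, seed=17)
    data = jf.BivariateData(pairs[:, 0] + 0.01, pairs[:, 1] + 0.01,
                            np.ones(5000, int), np.ones(5000, int))
    assert dg.empirical_tau(data) == pytest.approx(0.83, abs=0.03)


def test_empirical_tau_needs_two_pairs():
    data = jf.BivariateData([1.0, 2.0], [1.0, 2.0], [1, 0], [1, 1])
    with pytest.raises(ValueError, match="2 usable pairs"):
        dg.empirical_tau(data, "complete_pairs")


def test_fitted_pseudo_tau_close_to_model_tau(fitted):
    data, fit = fitted
    t_pseudo = dg.empirical_tau(data, "fitted_pseudo", fit=fit)
    assert t_pseudo == pytest.approx(fit.tau, abs=0.06)


def test_kendall_qq_identity_when_well_specified():
    # on complete (uncensored) data from the fitted model the W = C(u, v)
    # quantiles hug the identity line; censoring distorts the W distribution
    from copsurv import synth
    cfg = synth.CohortConfig(rounding="none", target_censor_frac=0.0,
                             admin_window=(1.0, np.inf))
    df, _ = synth.generate_cohort(cfg, seed=11)
    data = jf.BivariateData.from_cohort(df)
    fit = jf.fit_full_ml(data, "clayton", "weibull", compute_se=False)
    qq = dg.kendall_qq(data, fit, grid=50)
    assert qq.shape == (50, 2)
    assert np.all(np.diff(qq[:, 0]) >= 0) and np.all(np.diff(qq[:, 1]) > 0)
    assert np.max(np.abs(qq[:, 0] - qq[:, 1])) < 0.08


def test_kendall_qq_detects_gross_misspecification(fitted):
    data, fit = fitted
    wrong = jf.JointFitResult(
        copula=cp.CopulaSpec("clayton", 0.05), margin1=fit.margin1,
        margin2=fit.margin2, shared_margins=True, method="full_ml",
        param_names=fit.param_names, estimates=fit.estimates, se=fit.se,
        loglik=np.nan, n=fit.n, converged=True)
    qq = dg.kendall_qq(data, wrong, grid=50)
    assert np.max(np.abs(qq[:, 0] - qq[:, 1])) > 0.15


def test_kendall_qq_grid_one_is_the_median(fitted):
    data, fit = fitted
    qq = dg.kendall_qq(data, fit, grid=1)
    u, v = dg.pseudo_observations(data, fit)
    w = np.asarray(cp.copula_cdf(fit.copula, u, v))
    assert qq.shape == (1, 2)
    assert qq[0, 0] == pytest.approx(np.median(w))


def test_cvm_statistic_zero_against_itself(rng):
    u, v = rng.uniform(size=50), rng.uniform(size=50)
    stat = dg.cvm_statistic(u, v, lambda a, b: dg.empirical_copula(u, v, a, b))
    assert stat == 0.0


def test_gof_accepts_true_family_rejects_wrong_one():
    spec = cp.CopulaSpec("gumbel", cp.eta_from_tau("gumbel", 0.8))
    pairs = cp.sample_pairs(spec, 315, seed=8)
    _, p_true, _ = dg.gof_bootstrap_pobs(pairs[:, 0], pairs[:, 1], "gumbel",
                                         n_boot=100, seed=1)
    _, p_wrong, _ = dg.gof_bootstrap_pobs(pairs[:, 0], pairs[:, 1], "clayton",
                                          n_boot=100, seed=1)
    assert p_true > 0.05
    assert p_wrong <= 0.02


def test_gof_bootstrap_on_cohort_complete_pairs(fitted):
    data, fit = fitted
    stat, p, failed = dg.gof_bootstrap(data, fit, n_boot=60, seed=4,
                                       pairs="complete")
    assert stat >= 0 and 0 <= p <= 1
    assert failed <= 12


def test_scatter_data_counts_and_tail_clustering(fitted):
    data, fit = fitted
    sc = dg.scatter_data(data, fit, seed=0)
    assert sc["pseudo"].shape == (data.n, 2)
    assert sc["simulated"].shape == (data.n, 2)
    # Clayton lower-tail dependence: mass in [0,0.2]^2 far above independence
    corner = np.mean((sc["simulated"][:, 0] < 0.2) & (sc["simulated"][:, 1] < 0.2))
    assert corner > 0.10  # independence would give 0.04
    sc2 = dg.scatter_data(data, fit, seed=0)
    np.testing.assert_array_equal(sc["simulated"], sc2["simulated"])


def test_diagnose_report(fitted):
    data, fit = fitted
    rep = dg.diagnose(data, fit, n_boot=30, grid=20, seed=2)
    assert rep.n_boot == 30
    assert 0 <= rep.gof_p <= 1
    assert rep.qq_points.shape == (20, 2)
    assert rep.tau_model == pytest.approx(fit.tau)
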