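"""Copula core: closed forms, differential consistency, tau maps, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import kendalltau, kstest

from copsurv import copulas as cp

SPECS = [
    ("clayton", 2.0), ("clayton", 9.57),
    ("gumbel", 1.5), ("gumbel", 4.0),
    ("frank", 5.0), ("frank", -3.0),
    ("joe", 2.5), ("joe", 6.0),
]

GRID = np.array([0.05, 0.2, 0.5, 0.8, 0.95])


@pytest.fixture(params=SPECS, ids=[f"{f}-{e}" for f, e in SPECS])
def spec(request):
    return cp.CopulaSpec(*request.param)


def test_boundary_conditions(spec):
    for t in GRID:
        assert cp.copula_cdf(spec, t, 0.0) == 0.0
        assert cp.copula_cdf(spec, 0.0, t) == 0.0
        assert cp.copula_cdf(spec, t, 1.0) == pytest.approx(t, abs=1e-9)
        assert cp.copula_cdf(spec, 1.0, t) == pytest.approx(t, abs=1e-9)


def test_frechet_bounds_and_two_increasing(spec):
    uu, vv = np.meshgrid(GRID, GRID)
    c = cp.copula_cdf(spec, uu, vv)
    assert np.all(c >= np.maximum(uu + vv - 1.0, 0.0) - 1e-12)
    assert np.all(c <= np.minimum(uu, vv) + 1e-12)
    # rectangle mass nonnegative on every grid rectangle
    vol = c[1:, 1:] - c[1:, :-1] - c[:-1, 1:] + c[:-1, :-1]
    assert np.all(vol >= -1e-12)


def test_cdf_closed_form_values():
    clay = cp.CopulaSpec("clayton", 2.0)
    assert cp.copula_cdf(clay, 1.0, 0.4) == pytest.approx(0.4)
    # (0.5^-2 + 0.5^-2 - 1)^(-1/2) = 7^(-1/2)
    assert cp.copula_cdf(clay, 0.5, 0.5) == pytest.approx(7.0 ** -0.5, abs=1e-12)
    near_indep = cp.CopulaSpec("frank", 1e-6)
    assert cp.copula_cdf(near_indep, 0.3, 0.6) == pytest.approx(0.18, abs=1e-4)


def test_density_matches_mixed_finite_difference(spec):
    h = 1e-4
    for u in (0.3, 0.6):
        for v in (0.25, 0.7):
            fd = (cp.copula_cdf(spec, u + h, v + h)
                  - cp.copula_cdf(spec, u + h, v - h)
                  - cp.copula_cdf(spec, u - h, v + h)
                  + cp.copula_cdf(spec, u - h, v - h)) / (4 * h * h)
            assert cp.copula_density(spec, u, v) == pytest.approx(fd, abs=1e-5)


def test_density_near_independence_is_one():
    for fam, eta in [("clayton", 1e-8), ("gumbel", 1.0 + 1e-8),
                     ("frank", 1e-8), ("joe", 1.0 + 1e-8)]:
        d = cp.copula_density(cp.CopulaSpec(fam, eta), 0.5, 0.5)
        assert d == pytest.approx(1.0, abs=1e-3)


def test_density_quadrature_matches_cdf_mass():
    # int over [a,b]^2 of c(u,v) equals the inclusion-exclusion C mass
    spec = cp.CopulaSpec("clayton", 2.0)
    a, b = 0.001, 0.999
    val, _ = integrate.dblquad(lambda v, u: cp.copula_density(spec, u, v),
                               a, b, a, b, epsabs=1e-8)
    mass = (cp.copula_cdf(spec, b, b) - cp.copula_cdf(spec, b, a)
            - cp.copula_cdf(spec, a, b) + cp.copula_cdf(spec, a, a))
    assert val == pytest.approx(mass, abs=1e-6)


def test_partial_u_matches_finite_difference(spec):
    h = 1e-6
    for u, v in [(0.4, 0.6), (0.2, 0.35), (0.7, 0.15)]:
        fd = (cp.copula_cdf(spec, u + h, v) - cp.copula_cdf(spec, u - h, v)) / (2 * h)
        assert cp.copula_partial_u(spec, u, v) == pytest.approx(fd, abs=1e-6)


def test_partial_u_boundaries_and_independence():
    assert cp.copula_partial_u(cp.CopulaSpec("clayton", 2.0), 0.5, 1.0) == 1.0
    assert cp.copula_partial_u(cp.CopulaSpec("clayton", 2.0), 0.5, 0.0) == 0.0
    near_indep = cp.CopulaSpec("frank", 1e-6)
    assert cp.copula_partial_u(near_indep, 0.2, 0.35) == pytest.approx(0.35, abs=1e-4)


def test_partial_u_nondecreasing_in_v(spec):
    vals = np.asarray(cp.copula_partial_u(spec, 0.4, np.linspace(0.01, 0.99, 50)))
    assert np.all(np.diff(vals) >= -1e-10)


def test_uv_derivative_helpers_match_finite_difference(spec):
    h = 1e-6
    for u, v in [(0.3, 0.7), (0.15, 0.2), (0.8, 0.45)]:
        for fn, dfn in [(cp.copula_logcdf, cp.dlog_cdf_duv),
                        (cp.copula_log_partial_u, cp.dlog_partial_u_duv),
                        (cp.copula_logdensity, cp.dlog_density_duv)]:
            gu, gv = dfn(spec, u, v)
            fdu = (fn(spec, u + h, v) - fn(spec, u - h, v)) / (2 * h)
            fdv = (fn(spec, u, v + h) - fn(spec, u, v - h)) / (2 * h)
            assert gu == pytest.approx(fdu, rel=1e-4, abs=1e-6)
            assert gv == pytest.approx(fdv, rel=1e-4, abs=1e-6)


# ---------------------------------------------------------------------------
# Kendall's tau maps
# ---------------------------------------------------------------------------

def test_tau_closed_forms():
    assert cp.tau_from_eta(cp.CopulaSpec("clayton", 9.57)) == pytest.approx(
        9.57 / 11.57, abs=1e-12)
    assert round(cp.tau_from_eta(cp.CopulaSpec("clayton", 9.57)), 2) == 0.83
    assert cp.tau_from_eta(cp.CopulaSpec("gumbel", 1.0)) == 0.0
    assert cp.tau_from_eta(cp.CopulaSpec("gumbel", 2.0)) == pytest.approx(0.5)


def test_frank_tau_against_direct_debye_quadrature():
    # independent oracle: direct numerical integration of the Debye integrand
    for eta in (0.5, 5.0, 12.0):
        d1, _ = integrate.quad(lambda t: t / np.expm1(t), 0, eta, limit=200)
        expected = 1.0 - (4.0 / eta) * (1.0 - d1 / eta)
        assert cp.tau_from_eta(cp.CopulaSpec("frank", eta)) == pytest.approx(
            expected, abs=1e-6)
        assert cp.tau_from_eta(cp.CopulaSpec("frank", -eta)) == pytest.approx(
            -expected, abs=1e-6)


def test_joe_tau_against_series_oracle():
    # independent oracle: tau = 1 - 4 sum_k 1/[k(eta k+2)(eta(k-1)+2)]
    for eta in (1.5, 2.5, 6.0):
        k = np.arange(1, 200000)
        expected = 1.0 - 4.0 * np.sum(1.0 / (k * (eta * k + 2) * (eta * (k - 1) + 2)))
        assert cp.tau_from_eta(cp.CopulaSpec("joe", eta)) == pytest.approx(
            expected, abs=1e-6)


def test_tau_strictly_increasing_in_eta():
    grids = {"clayton": np.linspace(0.2, 15, 12), "gumbel": np.linspace(1.01, 8, 12),
             "frank": np.linspace(-8, 8, 12), "joe": np.linspace(1.01, 10, 12)}
    for fam, etas in grids.items():
        etas = etas[np.abs(etas) > 1e-6] if fam == "frank" else etas
        taus = [cp.tau_from_eta(cp.CopulaSpec(fam, e)) for e in etas]
        assert np.all(np.diff(taus) > 0)
        assert np.all(np.abs(taus) < 1.0)


def test_eta_from_tau_closed_forms_and_roundtrip():
    assert cp.eta_from_tau("clayton", 0.83) == pytest.approx(2 * 0.83 / 0.17)
    assert cp.eta_from_tau("gumbel", 0.5) == pytest.approx(2.0)
    for fam in cp.FAMILIES:
        for tau in np.arange(0.05, 0.91, 0.05):
            eta = cp.eta_from_tau(fam, tau)
            assert cp.tau_from_eta(cp.CopulaSpec(fam, eta)) == pytest.approx(
                tau, abs=1e-8)


def test_unreachable_tau_raises():
    for fam in ("clayton", "gumbel", "joe"):
        with pytest.raises(ValueError, match="not achievable"):
            cp.eta_from_tau(fam, -0.4)


def test_domain_errors_name_family_and_range():
    with pytest.raises(ValueError, match="clayton.*eta > 0"):
        cp.CopulaSpec("clayton", -1.0)
    with pytest.raises(ValueError, match="gumbel.*eta >= 1"):
        cp.CopulaSpec("gumbel", 0.5)
    with pytest.raises(ValueError, match="frank.*eta != 0"):
        cp.CopulaSpec("frank", 0.0)
    with pytest.raises(ValueError, match="joe"):
        cp.CopulaSpec("joe", 0.99)
    with pytest.raises(ValueError, match="open interval"):
        cp.copula_density(cp.CopulaSpec("clayton", 1.0), 0.0, 0.5)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("family", cp.FAMILIES)
@pytest.mark.parametrize("tau", [0.2, 0.5, 0.83])
def test_sampler_tau_consistency(family, tau):
    spec = cp.CopulaSpec(family, cp.eta_from_tau(family, tau))
    pairs = cp.sample_pairs(spec, 20_000, seed=1234)
    emp = kendalltau(pairs[:, 0], pairs[:, 1]).statistic
    assert emp == pytest.approx(tau, abs=0.02)


def test_sampler_near_independence_tau():
    pairs = cp.sample_pairs(cp.CopulaSpec("frank", 1e-6), 20_000, seed=7)
    assert abs(kendalltau(pairs[:, 0], pairs[:, 1]).statistic) < 0.02


@pytest.mark.parametrize("family", cp.FAMILIES)
def test_sampler_uniform_margins(family):
    spec = cp.CopulaSpec(family, cp.eta_from_tau(family, 0.6))
    pairs = cp.sample_pairs(spec, 20_000, seed=2)
    assert kstest(pairs[:, 0], "uniform").pvalue > 0.01
    assert kstest(pairs[:, 1], "uniform").pvalue > 0.01


def test_sampler_reproducible():
    spec = cp.CopulaSpec("joe", 3.0)
    a = cp.sample_pairs(spec, 100, seed=5)
    b = cp.sample_pairs(spec, 100, seed=5)
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# Kendall distribution function
# ---------------------------------------------------------------------------

def test_kendall_function_hand_values():
    # generator-ratio hand evaluation: K(w) = w + (w - w^(eta+1))/eta
    clay = cp.CopulaSpec("clayton", 2.0)
    assert cp.kendall_function(clay, 0.5) == pytest.approx(
        0.5 + (0.5 - 0.5 ** 3) / 2.0, abs=1e-12)  # = 0.6875
    # independence limit phi = -log w: K(w) = w - w log w
    ind = cp.CopulaSpec("gumbel", 1.0)
    assert cp.kendall_function(ind, 0.5) == pytest.approx(
        0.5 - 0.5 * np.log(0.5), abs=1e-10)
    w = np.linspace(0.05, 0.95, 19)
    for fam, eta in SPECS:
        k = np.asarray(cp.kendall_function(cp.CopulaSpec(fam, eta), w))
        assert np.all(k >= w - 1e-12)


def test_kendall_function_is_cdf_of_w(spec):
    # Monte-Carlo oracle: W = C(U,V) has CDF K
    pairs = cp.sample_pairs(spec, 30_000, seed=321)
    w = np.asarray(cp.copula_cdf(spec, pairs[:, 0], pairs[:, 1]))
    for q in (0.25, 0.5, 0.75):
        assert np.mean(w <= q) == pytest.approx(
            cp.kendall_function(spec, q), abs=0.015)


def test_kendall_function_inverse_roundtrip(spec):
    for p in (0.1, 0.5, 0.9):
        w = cp.kendall_function_inverse(spec, p)
        assert cp.kendall_function(spec, w) == pytest.approx(p, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    fam=st.sampled_from(cp.FAMILIES),
    tau=st.floats(0.05, 0.9),
    u1=st.floats(0.01, 0.98), du=st.floats(0.001, 0.5),
    v1=st.floats(0.01, 0.98), dv=st.floats(0.001, 0.5),
)
def test_property_rectangle_mass_nonnegative(fam, tau, u1, du, v1, dv):
    spec = cp.CopulaSpec(fam, cp.eta_from_tau(fam, tau))
    u2, v2 = min(u1 + du, 1.0), min(v1 + dv, 1.0)
    vol = (cp.copula_cdf(spec, u2, v2) - cp.copula_cdf(spec, u2, v1)
           - cp.copula_cdf(spec, u1, v2) + cp.copula_cdf(spec, u1, v1))
    assert vol >= -1e-10
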