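"""Likelihood, score, profile-MLE and interval checks."""

import numpy as np
import pytest
from scipy import optimize

from egmo.baselines import get_baseline
from egmo.family import EGMODistribution
from egmo.frequentist import (StressStrengthData, StressStrengthFit,
                              asymptotic_ci, bootstrap_ci, fit_mle,
                              log_likelihood, profile_b_hats, score_vector)


def test_loglik_baseline_collapse_single_obs():
    """At a=b1=b2=theta=1, Exp(1): log L(x={1}, y={2}) = −1 + −2."""
    data = StressStrengthData([1.0], [2.0])
    ll = log_likelihood(data, 1.0, 1.0, 1.0, 1.0, get_baseline("exponential", [1.0]))
    assert ll == pytest.approx(-3.0, abs=1e-12)


def test_loglik_equals_sum_of_logpdfs(small_data, weibull_baseline):
    b1, b2, theta, a = 0.7, 1.2, 0.8, 1.5
    dx = EGMODistribution(a, b1, theta, weibull_baseline)
    dy = EGMODistribution(a, b2, theta, weibull_baseline)
    direct = dx.logpdf(small_data.x).sum() + dy.logpdf(small_data.y).sum()
    ll = log_likelihood(small_data, b1, b2, theta, a, weibull_baseline)
    assert ll == pytest.approx(direct, abs=1e-10)


def test_loglik_infeasible_returns_minus_inf(small_data, weibull_baseline):
    assert log_likelihood(small_data, -1.0, 1.0, 1.0, 1.0, weibull_baseline) == -np.inf


@pytest.mark.parametrize("baseline,point", [
    ("weibull", [0.7, 1.2, 0.8, 1.5, 1.3, 0.9]),
    ("exponential", [0.7, 1.2, 0.8, 1.5, 0.8]),
    ("weibull", [1.4, 0.6, 3.2, 0.4, 2.1, 1.4]),
])
def test_score_matches_finite_differences(small_data, baseline, point):
    """Every analytic score component agrees with a central difference."""
    point = np.asarray(point)
    base = get_baseline(baseline, point[4:])

    def ll(v):
        return log_likelihood(small_data, v[0], v[1], v[2], v[3],
                              get_baseline(baseline, v[4:]))

    g = score_vector(small_data, *point[:4], base)
    for i in range(point.size):
        h = 1e-6 * point[i]
        e = np.zeros(point.size)
        e[i] = h
        fd = (ll(point + e) - ll(point - e)) / (2 * h)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_score_baseline_collapse_rate_component(small_data):
    """At a=b1=b2=theta=1 the lambda-score is the plain exponential score."""
    lam = 0.8
    g = score_vector(small_data, 1.0, 1.0, 1.0, 1.0,
                     get_baseline("exponential", [lam]))
    n, m = small_data.n, small_data.m
    expected = n / lam - small_data.x.sum() + m / lam - small_data.y.sum()
    assert g[4] == pytest.approx(expected, abs=1e-9)


def test_profile_b_hats_match_1d_maximization(small_data, weibull_baseline):
    """Closed-form profile b's equal a scalar numeric maximization."""
    theta, a = 0.8, 1.5
    b1h, b2h = profile_b_hats(small_data, theta, a, weibull_baseline)
    res = optimize.minimize_scalar(
        lambda lb: -log_likelihood(small_data, np.exp(lb), b2h, theta, a,
                                   weibull_baseline),
        bounds=(np.log(b1h) - 2, np.log(b1h) + 2), method="bounded",
        options={"xatol": 1e-12})
    assert b1h == pytest.approx(np.exp(res.x), rel=1e-8)
    # stationarity: the b-components of the score vanish at the profile values
    g = score_vector(small_data, b1h, b2h, theta, a, weibull_baseline)
    assert abs(g[0]) < 1e-9 and abs(g[1]) < 1e-9


def test_profile_b_direct_substitution():
    """b-hat = −n / Σ log{…}: arranged so the sum of log terms is known."""
    data = StressStrengthData([1.0, 1.0, 1.0, 1.0], [1.0])
    base = get_baseline("exponential", [1.0])
    b1h, _ = profile_b_hats(data, 1.0, 1.0, base)
    term = np.log1p(-np.exp(-1.0))          # log{1 − e^{−1}} per observation
    assert b1h == pytest.approx(-4 / (4 * term), rel=1e-12)


def test_fit_recovers_reliability_on_synthetic_data(synthetic_exp_pair):
    """R and the outer powers are recovered within 3 SE at n=m=1000.

    Only (b1, b2, R) are asserted: the shared (theta, a, lambda) trade off
    along a near-flat likelihood manifold and are not separately identified.
    """
    fit = fit_mle(synthetic_exp_pair, baseline="exponential", starts=8, seed=0)
    assert fit.converged
    se = fit.bse
    assert abs(fit.b1_hat - 1.0) < 3 * se[0]
    assert abs(fit.b2_hat - 1.0) < 3 * se[1]
    se_R = fit.b1_hat * fit.b2_hat / (fit.b1_hat + fit.b2_hat) ** 2 \
        * np.sqrt(1 / fit.n + 1 / fit.m)
    assert abs(fit.R_hat - 0.5) < 3 * se_R
    assert fit.info_matrix is not None
    assert np.allclose(fit.info_matrix, fit.info_matrix.T)


def test_R_hat_identity_and_swap(small_data, weibull_baseline):
    """R = b1/(b1+b2) exactly; swapping the samples maps R to 1−R."""
    theta, a = 0.8, 1.5
    b1h, b2h = profile_b_hats(small_data, theta, a, weibull_baseline)
    swapped = StressStrengthData(small_data.y, small_data.x)
    c1, c2 = profile_b_hats(swapped, theta, a, weibull_baseline)
    assert c1 == pytest.approx(b2h, rel=1e-12)
    R = b1h / (b1h + b2h)
    assert c1 / (c1 + c2) == pytest.approx(1 - R, rel=1e-12)
    assert 0 < R < 1


def test_asymptotic_ci_closed_form():
    """b1=b2, n=m=50 at 95%: half-width 1.96·0.25·√(2/50)."""
    fit = StressStrengthFit(b1_hat=1.0, b2_hat=1.0, theta_hat=1.0, a_hat=1.0,
                            lambda_hat=np.array([1.0]), loglik=0.0,
                            baseline_name="exponential", n=50, m=50,
                            converged=True, n_restarts_used=1)
    ci = asymptotic_ci(fit, level=0.95)
    half = 1.959963984540054 * 0.25 * np.sqrt(2 / 50)
    assert ci.upper - ci.lower == pytest.approx(2 * half, rel=1e-9)
    assert ci.lower == pytest.approx(0.5 - half, rel=1e-9)
    with pytest.raises(ValueError):
        asymptotic_ci(fit, level=1.2)


def test_asymptotic_ci_clipping():
    fit = StressStrengthFit(b1_hat=1.0, b2_hat=1.0, theta_hat=1.0, a_hat=1.0,
                            lambda_hat=np.array([1.0]), loglik=0.0,
                            baseline_name="exponential", n=3, m=3,
                            converged=True, n_restarts_used=1)
    ci = asymptotic_ci(fit, level=0.99)
    assert 0.0 <= ci.lower <= ci.upper <= 1.0


def test_bootstrap_deterministic_and_sane(synthetic_exp_pair):
    """Same seed → identical interval; the interval covers the b1=b2 truth."""
    data = StressStrengthData(synthetic_exp_pair.x[:40], synthetic_exp_pair.y[:40])
    fit = fit_mle(data, baseline="exponential", starts=4, seed=0)
    ci1 = bootstrap_ci(data, baseline="exponential", B=100, level=0.95,
                       seed=5, full_fit=fit)
    ci2 = bootstrap_ci(data, baseline="exponential", B=100, level=0.95,
                       seed=5, full_fit=fit)
    assert (ci1.lower, ci1.upper) == (ci2.lower, ci2.upper)
    assert ci1.lower <= 0.5 <= ci1.upper
    with pytest.raises(ValueError):
        bootstrap_ci(data, B=50)


def test_data_validation():
    with pytest.raises(ValueError):
        StressStrengthData([1.0, -2.0], [1.0])
    with pytest.raises(ValueError):
        StressStrengthData([], [1.0])
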