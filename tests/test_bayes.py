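"""Posterior hyperparameters, samplers, closed form and credible intervals."""

import numpy as np
import pytest

from egmo.baselines import get_baseline
from egmo.bayes import (PosteriorDraws, PriorSpec, bayes_estimate_sel,
                        closed_form_bayes, credible_interval_empirical,
                        credible_interval_F, gibbs_mh_sampler,
                        posterior_hyper, _posterior_mean_quadrature)
from egmo.frequentist import StressStrengthData, profile_b_hats

import pandas as pd


def _draws_from_R(R):
    chain = pd.DataFrame({"b1": R, "b2": 1 - np.asarray(R), "R": R})
    return PosteriorDraws(chain=chain, T=len(R), seed=0, mode="test")


def test_posterior_hyper_direct_substitution():
    """With xi1=0 and a single x whose log term is −log(1−e^{−1}) the
    rate H1 is that magnitude; and b̂1 = n/H1 reproduces the profile MLE."""
    data = StressStrengthData([1.0], [1.0])
    base = get_baseline("exponential", [1.0])
    prior = PriorSpec.noninformative(1)
    hyp = posterior_hyper(data, 1.0, 1.0, base, prior)
    assert hyp.H1 == pytest.approx(-np.log1p(-np.exp(-1)), rel=1e-12)
    b1h, b2h = profile_b_hats(data, 1.0, 1.0, base)
    assert b1h == pytest.approx(data.n / hyp.H1, rel=1e-12)
    assert b2h == pytest.approx(data.m / hyp.H2, rel=1e-12)
    assert hyp.H1 > 0 and hyp.H2 > 0


def test_bayes_estimate_is_chain_mean():
    assert bayes_estimate_sel(_draws_from_R([0.4, 0.6])) == pytest.approx(0.5)
    assert bayes_estimate_sel(_draws_from_R([0.375] * 10)) == pytest.approx(0.375)


def test_credible_interval_nested_and_quantile_rule():
    R = np.linspace(0.1, 1.0, 10)
    draws = _draws_from_R(R)
    ci80 = credible_interval_empirical(draws, 0.80)
    # numpy's linear interpolation of the order statistics
    lo, hi = np.quantile(R, [0.10, 0.90])
    assert (ci80.lower, ci80.upper) == (pytest.approx(lo), pytest.approx(hi))
    big = credible_interval_empirical(_draws_from_R(np.random.default_rng(0)
                                                    .uniform(size=500)), 0.95)
    small = credible_interval_empirical(_draws_from_R(np.random.default_rng(0)
                                                      .uniform(size=500)), 0.90)
    assert big.lower <= small.lower and small.upper <= big.upper


def test_closed_form_symmetric_cases():
    """Equal posterior shapes and rates → 1/2; equal rates → Beta mean."""
    data = StressStrengthData([1.0] * 4, [1.0] * 4)
    base = "exponential"
    prior = PriorSpec.noninformative(1)
    assert closed_form_bayes(data, prior, 1.0, 1.0, base, [1.0]) == \
        pytest.approx(0.5, abs=1e-12)
    # equal rates reduce to the Beta(alpha1, alpha2) mean: direct check of the
    # hypergeometric formula at psi=0 via the quadrature representation
    assert _posterior_mean_quadrature(2, 3, 0.0) == pytest.approx(0.4, abs=1e-9)


def test_closed_form_matches_quadrature_oracle():
    """2F1 closed form vs adaptive quadrature for unequal gamma rates."""
    rng = np.random.default_rng(2)
    for alpha1, alpha2, H1, H2 in [(5, 7, 2.0, 0.5), (45, 45, 16.6, 4.1),
                                   (12, 30, 0.7, 3.3)]:
        psi = 1 - H1 / H2
        c = alpha1 + alpha2
        from scipy import special
        if psi < 0:
            val = (alpha1 / c) * np.exp(-alpha2 * np.log1p(-psi)) \
                * special.hyp2f1(c, alpha2, c + 1.0, psi / (psi - 1.0))
        else:
            val = (alpha1 / c) * np.exp(alpha1 * np.log1p(-psi)) \
                * special.hyp2f1(c, alpha1 + 1.0, c + 1.0, psi)
        oracle = _posterior_mean_quadrature(alpha1, alpha2, psi)
        assert val == pytest.approx(oracle, abs=1e-8)
        # and against a big Monte-Carlo draw
        b1 = rng.gamma(alpha1, 1 / H1, 200000)
        b2 = rng.gamma(alpha2, 1 / H2, 200000)
        assert val == pytest.approx((b1 / (b1 + b2)).mean(), abs=5e-3)


def test_closed_form_from_data_route():
    """The data-facing wrapper agrees with the direct gamma-moment oracle."""
    data = StressStrengthData([0.5, 1.2, 0.8], [1.5, 2.2])
    prior = PriorSpec(np.full(5, 1.0), np.full(5, 2.0))
    base = get_baseline("exponential", [1.0])
    hyp = posterior_hyper(data, 0.7, 1.4, base, prior)
    val = closed_form_bayes(data, prior, 0.7, 1.4, "exponential", [1.0])
    rng = np.random.default_rng(3)
    b1 = rng.gamma(data.n + 2.0, 1 / hyp.H1, 400000)
    b2 = rng.gamma(data.m + 2.0, 1 / hyp.H2, 400000)
    assert val == pytest.approx((b1 / (b1 + b2)).mean(), abs=3e-3)


def test_F_interval_symmetry_and_mc_oracle():
    """n=m, eta1=eta2, H1=H2 → lower = 1−upper; endpoints match 10^6-draw
    product-gamma quantiles to 3 decimals."""
    data = StressStrengthData([1.0, 2.0, 0.7], [1.0, 2.0, 0.7])
    prior = PriorSpec(np.full(5, 0.5), np.full(5, 1.5))
    ci = credible_interval_F(data, prior, 1.0, 1.0, "exponential", [1.0],
                             level=0.95)
    assert ci.lower == pytest.approx(1 - ci.upper, abs=1e-12)

    base = get_baseline("exponential", [1.3])
    data2 = StressStrengthData([0.4, 1.1, 2.0, 0.9], [0.8, 1.6])
    hyp = posterior_hyper(data2, 0.8, 1.2, base, prior)
    ci2 = credible_interval_F(data2, prior, 0.8, 1.2, "exponential", [1.3],
                              level=0.95)
    rng = np.random.default_rng(4)
    b1 = rng.gamma(data2.n + 1.5, 1 / hyp.H1, 1_000_000)
    b2 = rng.gamma(data2.m + 1.5, 1 / hyp.H2, 1_000_000)
    lo, hi = np.quantile(b1 / (b1 + b2), [0.025, 0.975])
    assert ci2.lower == pytest.approx(lo, abs=1e-3)
    assert ci2.upper == pytest.approx(hi, abs=1e-3)


def test_case2_sampler_matches_closed_form(synthetic_exp_pair):
    """With shared parameters fixed, the chain's R mean equals the 2F1
    closed form within Monte-Carlo error."""
    data = StressStrengthData(synthetic_exp_pair.x[:60], synthetic_exp_pair.y[:60])
    prior = PriorSpec.noninformative(1)
    truth = [1.0, 1.0, 1.0, 1.0, 1.0]
    draws = gibbs_mh_sampler(data, prior=prior, T=10000, seed=9,
                             baseline="exponential", init=truth,
                             fix_shared=True)
    exact = closed_form_bayes(data, prior, 1.0, 1.0, "exponential", [1.0])
    mc_se = draws.R.std() / np.sqrt(draws.T)
    assert bayes_estimate_sel(draws) == pytest.approx(exact, abs=3 * mc_se)
    # chain invariant: every R record is b1/(b1+b2) of its row
    c = draws.chain
    assert np.allclose(c["R"], c["b1"] / (c["b1"] + c["b2"]), atol=1e-14)


def test_sampler_deterministic_under_seed(synthetic_exp_pair):
    data = StressStrengthData(synthetic_exp_pair.x[:30], synthetic_exp_pair.y[:30])
    prior = PriorSpec(np.full(5, 1.0), np.full(5, 2.0))
    kw = dict(prior=prior, T=200, baseline="exponential",
              init=[1.0, 1.0, 1.0, 1.0, 1.0], proposal_scale=[0.3])
    with pytest.warns(UserWarning):
        d1 = gibbs_mh_sampler(data, seed=3, **kw)
        d2 = gibbs_mh_sampler(data, seed=3, **kw)
    assert d1.chain.equals(d2.chain)
    assert np.all((d1.acceptance_rate_lambda >= 0)
                  & (d1.acceptance_rate_lambda <= 1))


def test_exact_mh_mode_runs_and_differs(synthetic_exp_pair):
    data = StressStrengthData(synthetic_exp_pair.x[:30], synthetic_exp_pair.y[:30])
    prior = PriorSpec(np.full(5, 1.0), np.full(5, 2.0))
    kw = dict(prior=prior, T=300, baseline="exponential",
              init=[1.0, 1.0, 1.0, 1.0, 1.0], proposal_scale=[0.3], seed=3)
    with pytest.warns(UserWarning):
        lit = gibbs_mh_sampler(data, mode="paper-conditionals", **kw)
    ex = gibbs_mh_sampler(data, mode="exact-mh", **kw)
    assert not lit.chain.equals(ex.chain)
    assert 0.0 < bayes_estimate_sel(ex) < 1.0


def test_sampler_input_validation(synthetic_exp_pair):
    data = StressStrengthData(synthetic_exp_pair.x[:20], synthetic_exp_pair.y[:20])
    with pytest.raises(ValueError):
        gibbs_mh_sampler(data, T=50, baseline="exponential")
    with pytest.raises(ValueError):
        gibbs_mh_sampler(data, T=200, baseline="exponential", mode="other")
    with pytest.raises(ValueError):
        credible_interval_empirical(_draws_from_R(np.full(200, 0.5)), 1.5)


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        PriorSpec([-1.0] * 5, [1.0] * 5)
    p = PriorSpec.constant(2.0, 3.0, 1)
    assert p.xi.tolist() == [2, 2, 2, 2, 0]
    assert p.eta.tolist() == [3, 3, 3, 3, 0]
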