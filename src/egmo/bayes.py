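"""Bayesian inference for R = b1/(b1+b2) under independent gamma priors.

Priors are Gamma(shape=η, rate=ξ) for every parameter; the pair (0, 0)
denotes the improper non-informative limit π(·) ∝ 1/·.  Conditional on the
shared parameters, the outer powers have exact gamma posteriors

    b1 | ·  ~  Gamma(n + η1, H1),      H1 = ξ1 − Σ log{1 − r(xi)^a},
    b2 | ·  ~  Gamma(m + η2, H2),      H2 = ξ2 − Σ log{1 − r(yj)^a},

which drive both the MCMC scheme and the Case II (known shared parameters)
closed form via the Gauss hypergeometric function.

Two sampler modes are provided.  ``"paper-conditionals"`` (default) cycles
the literal gamma conditionals ϑ|· ~ Gamma(a(n+m)+η3, ξ3) and
a|· ~ Gamma(n+m+η4, H3) plus a random-walk Metropolis-Hastings step for the
baseline parameters; these ϑ and a conditionals drop likelihood factors, so
the mode reproduces published estimates rather than the exact posterior.
``"exact-mh"`` replaces them with Metropolis-Hastings steps on the exact
full conditionals (joint likelihood × prior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .baselines import get_baseline
from .frequentist import (IntervalEstimate, StressStrengthData, fit_mle,
                          _pieces)

__all__ = [
    "PriorSpec", "PosteriorHyper", "PosteriorDraws", "posterior_hyper",
    "gibbs_mh_sampler", "bayes_estimate_sel", "credible_interval_empirical",
    "credible_interval_F", "closed_form_bayes",
]


@dataclass
class PriorSpec:
    """Gamma prior rates ξ and shapes η in the order (b1, b2, ϑ, a, λk…)."""

    xi: np.ndarray
    eta: np.ndarray

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.xi.shape != self.eta.shape:
            raise ValueError("xi and eta must have the same length")
        if np.any(self.xi < 0) or np.any(self.eta < 0):
            raise ValueError("prior rates and shapes must be nonnegative")

    @classmethod
    def noninformative(cls, n_baseline=1):
        """ξi = ηi = 0 for all parameters (improper limit)."""
        z = np.zeros(4 + n_baseline)
        return cls(z, z.copy())

    @classmethod
    def constant(cls, xi, eta, n_baseline=1, baseline_xi=None, baseline_eta=None):
        """Common (ξ, η) for (b1, b2, ϑ, a); baseline priors default to (0, 0)."""
        xiv = np.r_[np.full(4, float(xi)),
                    np.full(n_baseline, 0.0 if baseline_xi is None else baseline_xi)]
        etav = np.r_[np.full(4, float(eta)),
                     np.full(n_baseline, 0.0 if baseline_eta is None else baseline_eta)]
        return cls(xiv, etav)


@dataclass
class PosteriorHyper:
    """The data-dependent posterior rates H1–H4 at given shared parameters."""

    H1: float
    H2: float
    H3: float
    H4: float


@dataclass
class PosteriorDraws:
    """MCMC output: one row per sweep with (b1, b2, ϑ, a, λk…, R)."""

    chain: pd.DataFrame
    T: int
    seed: int
    mode: str
    acceptance_rate_lambda: np.ndarray = field(default_factory=lambda: np.array([]))
    n_held_a: int = 0

    @property
    def R(self):
        return self.chain["R"].to_numpy()


def _sample_sums(baseline, theta, a, x):
    p = _pieces(baseline, theta, a, x)
    return {"logg": p["logg"].sum(), "logsbar": p["logsbar"].sum(),
            "logw": np.log(p["w"]).sum(), "L1": p["L1"].sum(),
            "logr": p["logr"].sum()}


def posterior_hyper(data, theta, a, baseline, prior: PriorSpec):
    """Compute H1–H4 at the current shared parameters."""
    sx = _sample_sums(baseline, theta, a, data.x)
    sy = _sample_sums(baseline, theta, a, data.y)
    if not np.isfinite(sx["L1"]) or not np.isfinite(sy["L1"]):
        raise FloatingPointError("degenerate data: log posterior term is not finite")
    H1 = prior.xi[0] - sx["L1"]
    H2 = prior.xi[1] - sy["L1"]
    H3 = (prior.xi[3] - sx["logsbar"] - sy["logsbar"]
          + sx["logw"] + sy["logw"])
    H4 = (sx["logg"] - sx["logsbar"] - sx["logw"] - sx["L1"]
          + sy["logg"] - sy["logsbar"] - sy["logw"] - sy["L1"])
    return PosteriorHyper(H1, H2, H3, H4)


def _log_target_lambda_paper(lam_k, eta_k, xi_k, H4):
    """Literal Π5*(λk) ∝ λk^{η5k−1} e^{−ξ5k λk + H4}."""
    return (eta_k - 1.0) * np.log(lam_k) - xi_k * lam_k + H4


def _joint_loglik_from_sums(sx, sy, b1, b2, theta, a, n, m):
    # cancellation-safe: a·logϑ + (a−1)logḠ − (a+1)logw ≡ a·logr − logḠ − logw
    return (n * (np.log(a) + np.log(b1)) + m * (np.log(a) + np.log(b2))
            + sx["logg"] + a * sx["logr"] - sx["logsbar"] - sx["logw"]
            + (b1 - 1) * sx["L1"]
            + sy["logg"] + a * sy["logr"] - sy["logsbar"] - sy["logw"]
            + (b2 - 1) * sy["L1"])


def _gamma_logprior(v, eta, xi):
    """log Gamma(shape=η, rate=ξ) density up to constants; (0,0) → ∝ 1/v."""
    return (eta - 1.0) * np.log(v) - xi * v


def gibbs_mh_sampler(data, prior=None, T=10000, seed=0, baseline="weibull",
                     mode="paper-conditionals", init=None, proposal_scale=None,
                     fix_shared=False, fix_baseline=None, adapt_frac=0.0,
                     starts=20):
    """Gibbs-within-Metropolis-Hastings sampler for (b1, b2, ϑ, a, λk, R).

    Parameters
    ----------
    data : StressStrengthData or (x, y)
    prior : PriorSpec, optional
        Defaults to the non-informative limit ξ = η = 0.
    T : int
        Number of recorded sweeps (all are averaged; no burn-in is
        discarded, matching the estimator R̂_B = T⁻¹ Σ R^(t)).
    mode : {"paper-conditionals", "exact-mh"}
    init : StressStrengthFit or sequence (b1, b2, ϑ, a, λk…), optional
        Chain start; defaults to the joint MLE.
    proposal_scale : array, optional
        Random-walk sd per baseline parameter; defaults to the MLE
        asymptotic standard errors (fallback: 10% of the current value).
    fix_shared : bool
        Case II reduction — hold (ϑ, a, λk) fixed and draw only the exact
        gamma conditionals of b1, b2.
    fix_baseline : bool, optional
        Hold the baseline parameters λk at their initial (MLE) values.
        Default (None) resolves automatically: True in paper-conditionals
        mode when every baseline prior pair is the improper (0, 0) — the
        "baseline handled separately" reading of a non-informative run
        whose prior list covers only (b1, b2, ϑ, a) — else False.  The
        literal λk pseudo-target drifts under an improper pair because it
        omits the likelihood factors that anchor it.
    adapt_frac : float
        Fraction of the chain over which the MH proposal scales are tuned
        toward a 20–45% acceptance rate (0 disables tuning).
    """
    if T < 100:
        raise ValueError("T must be at least 100")
    if mode not in ("paper-conditionals", "exact-mh"):
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(data, StressStrengthData):
        data = StressStrengthData(*data)
    baseline_cls = get_baseline(baseline)
    l = len(baseline_cls.param_names)
    if prior is None:
        prior = PriorSpec.noninformative(l)
    if prior.xi.size != 4 + l:
        raise ValueError(f"prior must have length {4 + l} for baseline {baseline}")

    if init is None:
        init = fit_mle(data, baseline=baseline, seed=seed, starts=starts)
    if hasattr(init, "params_full"):
        mle = init
        cur = np.asarray(init.params_full, dtype=float)
        if proposal_scale is None and mle.bse is not None:
            ps = mle.bse[4:]
            proposal_scale = np.where(np.isfinite(ps) & (ps > 0),
                                      ps, 0.1 * np.abs(cur[4:]))
    else:
        cur = np.asarray(init, dtype=float)
    b1, b2, theta, a = cur[:4]
    lam = cur[4:].copy()
    if proposal_scale is None:
        proposal_scale = 0.1 * np.abs(lam)
    scale = np.array(proposal_scale, dtype=float)

    theta_frozen = fix_shared
    if mode == "paper-conditionals" and prior.xi[2] == 0 and not fix_shared:
        warnings.warn("xi3 = 0 makes the printed theta-conditional improper; "
                      "theta is held at its initial value", stacklevel=2)
        theta_frozen = True
    if fix_baseline is None:
        fix_baseline = (mode == "paper-conditionals"
                        and np.all(prior.xi[4:] == 0)
                        and np.all(prior.eta[4:] == 0))
    lambda_frozen = bool(fix_baseline) or fix_shared
    if mode == "paper-conditionals":
        warnings.warn("paper-conditionals mode samples the literal printed "
                      "conditionals, not the exact posterior", stacklevel=2)

    n, m = data.n, data.m
    rng = np.random.default_rng(seed)
    rec = np.empty((T, 5 + l))
    acc = np.zeros(l)
    n_held_a = 0
    adapt_until = int(adapt_frac * T)

    baseline_inst = baseline_cls(lam)
    sx = _sample_sums(baseline_inst, theta, a, data.x)
    sy = _sample_sums(baseline_inst, theta, a, data.y)

    def hypers(sx, sy):
        return (prior.xi[0] - sx["L1"], prior.xi[1] - sy["L1"],
                prior.xi[3] - sx["logsbar"] - sy["logsbar"]
                + sx["logw"] + sy["logw"],
                sx["logg"] - sx["logsbar"] - sx["logw"] - sx["L1"]
                + sy["logg"] - sy["logsbar"] - sy["logw"] - sy["L1"])

    for t in range(T):
        H1, H2, H3, H4 = hypers(sx, sy)
        # exact gamma conditionals for the outer powers; the floor keeps a
        # drifted chain (huge H) representable instead of underflowing to 0
        b1 = max(rng.gamma(n + prior.eta[0], 1.0 / H1), 1e-300)
        b2 = max(rng.gamma(m + prior.eta[1], 1.0 / H2), 1e-300)

        if not fix_shared:
            # -- theta update
            if not theta_frozen:
                if mode == "paper-conditionals":
                    theta = max(rng.gamma(a * (n + m) + prior.eta[2],
                                          1.0 / prior.xi[2]), 1e-12)
                    sx = _sample_sums(baseline_inst, theta, a, data.x)
                    sy = _sample_sums(baseline_inst, theta, a, data.y)
                else:
                    prop = theta + _rw_scale(theta) * rng.standard_normal()
                    if prop > 0:
                        sxp = _sample_sums(baseline_inst, prop, a, data.x)
                        syp = _sample_sums(baseline_inst, prop, a, data.y)
                        d = (_joint_loglik_from_sums(sxp, syp, b1, b2, prop, a, n, m)
                             + _gamma_logprior(prop, prior.eta[2], prior.xi[2])
                             - _joint_loglik_from_sums(sx, sy, b1, b2, theta, a, n, m)
                             - _gamma_logprior(theta, prior.eta[2], prior.xi[2]))
                        if np.log(rng.uniform()) < d:
                            theta, sx, sy = prop, sxp, syp
            # -- a update
            if mode == "paper-conditionals":
                H3 = hypers(sx, sy)[2]
                if H3 > 0 and np.isfinite(H3):
                    a = max(rng.gamma(n + m + prior.eta[3], 1.0 / H3), 1e-12)
                    sx = _sample_sums(baseline_inst, theta, a, data.x)
                    sy = _sample_sums(baseline_inst, theta, a, data.y)
                else:
                    n_held_a += 1
            else:
                prop = a + _rw_scale(a) * rng.standard_normal()
                if prop > 0:
                    sxp = _sample_sums(baseline_inst, theta, prop, data.x)
                    syp = _sample_sums(baseline_inst, theta, prop, data.y)
                    d = (_joint_loglik_from_sums(sxp, syp, b1, b2, theta, prop, n, m)
                         + _gamma_logprior(prop, prior.eta[3], prior.xi[3])
                         - _joint_loglik_from_sums(sx, sy, b1, b2, theta, a, n, m)
                         - _gamma_logprior(a, prior.eta[3], prior.xi[3]))
                    if np.log(rng.uniform()) < d:
                        a, sx, sy = prop, sxp, syp
            # -- baseline parameter updates (random-walk MH)
            for k in range(0 if lambda_frozen else l):
                prop_lam = lam.copy()
                prop_lam[k] = lam[k] + scale[k] * rng.standard_normal()
                if prop_lam[k] <= 0:
                    continue
                try:
                    prop_inst = baseline_cls(prop_lam)
                    sxp = _sample_sums(prop_inst, theta, a, data.x)
                    syp = _sample_sums(prop_inst, theta, a, data.y)
                except (ValueError, FloatingPointError):
                    continue
                if mode == "paper-conditionals":
                    H4p = (sxp["logg"] - sxp["logsbar"] - sxp["logw"] - sxp["L1"]
                           + syp["logg"] - syp["logsbar"] - syp["logw"] - syp["L1"])
                    H4c = hypers(sx, sy)[3]
                    d = (_log_target_lambda_paper(prop_lam[k], prior.eta[4 + k],
                                                  prior.xi[4 + k], H4p)
                         - _log_target_lambda_paper(lam[k], prior.eta[4 + k],
                                                    prior.xi[4 + k], H4c))
                else:
                    d = (_joint_loglik_from_sums(sxp, syp, b1, b2, theta, a, n, m)
                         + _gamma_logprior(prop_lam[k], prior.eta[4 + k], prior.xi[4 + k])
                         - _joint_loglik_from_sums(sx, sy, b1, b2, theta, a, n, m)
                         - _gamma_logprior(lam[k], prior.eta[4 + k], prior.xi[4 + k]))
                if np.isfinite(d) and np.log(rng.uniform()) < d:
                    lam = prop_lam
                    baseline_inst = prop_inst
                    sx, sy = sxp, syp
                    acc[k] += 1
                    if t < adapt_until:
                        scale[k] *= 1.05
                elif t < adapt_until:
                    scale[k] *= 0.97

        rec[t] = np.r_[b1, b2, theta, a, lam, b1 / (b1 + b2)]

    cols = ["b1", "b2", "theta", "a", *baseline_cls.param_names, "R"]
    chain = pd.DataFrame(rec, columns=cols)
    return PosteriorDraws(chain=chain, T=T, seed=seed, mode=mode,
                          acceptance_rate_lambda=acc / T, n_held_a=n_held_a)


def _rw_scale(value):
    """Random-walk sd for scalar shared parameters in exact-MH mode."""
    return max(0.25 * abs(value), 1e-3)


def bayes_estimate_sel(draws: PosteriorDraws):
    """Squared-error-loss Bayes estimate: the mean of the R chain."""
    R = draws.R
    if R.size == 0:
        raise ValueError("empty chain")
    return float(R.mean())


def credible_interval_empirical(draws: PosteriorDraws, level=0.95):
    """Empirical (ε/2, 1−ε/2) quantiles of the sorted R chain.

    Quantiles follow numpy's default linear interpolation of the order
    statistics.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    eps = 1.0 - level
    if draws.T * eps / 2.0 < 1 - 1e-9:
        raise ValueError("chain too short for the requested level")
    lo, hi = np.quantile(draws.R, [eps / 2.0, 1.0 - eps / 2.0])
    return IntervalEstimate(float(lo), float(hi), level, "credible-empirical")


def _case2_hypers(data, prior, theta, a, baseline, baseline_params=None):
    if isinstance(baseline, str):
        baseline = get_baseline(baseline, baseline_params)
    if not isinstance(data, StressStrengthData):
        data = StressStrengthData(*data)
    hyp = posterior_hyper(data, theta, a, baseline, prior)
    alpha1 = data.n + prior.eta[0]
    alpha2 = data.m + prior.eta[1]
    return hyp.H1, hyp.H2, alpha1, alpha2


def credible_interval_F(data, prior, theta, a, baseline, baseline_params=None,
                        level=0.95):
    """Case II credible interval from the F-representation of R.

    With b1 ~ Gamma(n+η1, H1) and b2 ~ Gamma(m+η2, H2) exactly,
    R = [1 + ((m+η2)H1/((n+η1)H2))·F]⁻¹ with F ~ F(2(m+η2), 2(n+η1)).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    H1, H2, alpha1, alpha2 = _case2_hypers(data, prior, theta, a, baseline,
                                           baseline_params)
    if alpha1 <= 0 or alpha2 <= 0:
        raise ValueError("posterior shapes must be positive")
    eps = 1.0 - level
    ratio = alpha2 * H1 / (alpha1 * H2)
    fdist = stats.f(2 * alpha2, 2 * alpha1)
    ends = sorted(1.0 / (1.0 + ratio * fdist.ppf(q))
                  for q in (eps / 2.0, 1.0 - eps / 2.0))
    return IntervalEstimate(float(ends[0]), float(ends[1]), level, "credible-F")


def _posterior_mean_quadrature(alpha1, alpha2, psi):
    """Oracle-grade evaluation of E[w] with w-density ∝ w^{α1−1}(1−w)^{α2−1}(1−ψw)^{−c}."""
    c = alpha1 + alpha2

    def logq(w):
        return ((alpha1 - 1.0) * np.log(w) + (alpha2 - 1.0) * np.log1p(-w)
                - c * np.log1p(-psi * w))

    grid = np.linspace(1e-9, 1 - 1e-9, 2001)
    M = np.max(logq(grid))
    num = integrate.quad(lambda w: w * np.exp(logq(w) - M), 0, 1, limit=200)[0]
    den = integrate.quad(lambda w: np.exp(logq(w) - M), 0, 1, limit=200)[0]
    return num / den


def closed_form_bayes(data, prior, theta, a, baseline, baseline_params=None):
    """Case II posterior mean of R via the Gauss hypergeometric function.

    E[b1/(b1+b2)] = (1−ψ)^{α1} (α1/c) ₂F₁(c, α1+1; c+1; ψ) with
    α1 = n+η1, α2 = m+η2, c = α1+α2 and ψ = 1 − H1/H2.  For ψ < 0 the
    Pfaff transform gives the numerically safer
    (α1/c)(1−ψ)^{−α2} ₂F₁(c, α2; c+1; ψ/(ψ−1)) with argument in (0, 1).
    Falls back to adaptive quadrature if the hypergeometric evaluation
    fails.
    """
    H1, H2, alpha1, alpha2 = _case2_hypers(data, prior, theta, a, baseline,
                                           baseline_params)
    if H1 <= 0 or H2 <= 0:
        raise ValueError("posterior rates H1, H2 must be positive")
    c = alpha1 + alpha2
    psi = 1.0 - H1 / H2
    with np.errstate(over="ignore", invalid="ignore"):
        if psi < 0:
            val = (alpha1 / c) * np.exp(-alpha2 * np.log1p(-psi)) \
                * special.hyp2f1(c, alpha2, c + 1.0, psi / (psi - 1.0))
        else:
            val = (alpha1 / c) * np.exp(alpha1 * np.log1p(-psi)) \
                * special.hyp2f1(c, alpha1 + 1.0, c + 1.0, psi)
    if not np.isfinite(val) or not 0.0 <= val <= 1.0:
        val = _posterior_mean_quadrature(alpha1, alpha2, psi)
    return float(val)
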