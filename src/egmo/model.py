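"""Model/Results facade for stress-strength reliability inference.

:class:`StressStrength` is built from the two samples; ``fit()`` returns a
:class:`StressStrengthResults` carrying the joint MLE, standard errors,
R̂, log-likelihood, and interval constructors, and ``fit_bayes()`` returns
a :class:`BayesResults` wrapping the posterior chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bayes as _bayes
from . import frequentist as _freq
from .frequentist import StressStrengthData

__all__ = ["StressStrength", "StressStrengthResults", "BayesResults"]


class StressStrength:
    """Stress-strength model: X (stress) and Y (strength) are EGMO-G with
    shared (a, ϑ, λk) and sample-specific outer powers b1, b2, so that
    R = P(Y < X) = b1/(b1+b2)."""

    def __init__(self, x, y, baseline="weibull"):
        self.data = x if isinstance(x, StressStrengthData) \
            else StressStrengthData(x, y)
        self.baseline = baseline

    @classmethod
    def from_dataframe(cls, df, stress_col, strength_col, baseline="weibull"):
        """Build from a DataFrame with one column per sample (NaNs dropped)."""
        x = df[stress_col].dropna().to_numpy()
        y = df[strength_col].dropna().to_numpy()
        return cls(x, y, baseline=baseline)

    def loglike(self, b1, b2, theta, a, baseline_params):
        from .baselines import get_baseline
        return _freq.log_likelihood(self.data, b1, b2, theta, a,
                                    get_baseline(self.baseline, baseline_params))

    def fit(self, starts=20, seed=0, compute_info=True):
        raw = _freq.fit_mle(self.data, baseline=self.baseline, starts=starts,
                            seed=seed, compute_info=compute_info)
        return StressStrengthResults(self, raw)

    def fit_bayes(self, prior=None, T=10000, seed=0, mode="paper-conditionals",
                  init=None, fix_shared=False, mle_results=None, **kw):
        if init is None and mle_results is not None:
            init = mle_results._raw
        draws = _bayes.gibbs_mh_sampler(self.data, prior=prior, T=T, seed=seed,
                                        baseline=self.baseline, mode=mode,
                                        init=init, fix_shared=fix_shared, **kw)
        return BayesResults(self, draws)


class StressStrengthResults:
    """MLE results: estimates, uncertainties, R̂ and interval estimates."""

    def __init__(self, model, raw: _freq.StressStrengthFit):
        self.model = model
        self._raw = raw

    # statsmodels-style accessors
    @property
    def params(self):
        return pd.Series(self._raw.params_full, index=self._raw.param_names)

    @property
    def bse(self):
        se = self._raw.bse
        if se is None:
            se = np.full(len(self._raw.param_names), np.nan)
        return pd.Series(se, index=self._raw.param_names)

    @property
    def llf(self):
        return self._raw.loglik

    @property
    def R_hat(self):
        return self._raw.R_hat

    @property
    def converged(self):
        return self._raw.converged

    @property
    def info_matrix(self):
        return self._raw.info_matrix

    def conf_int_asymptotic(self, level=0.95):
        return _freq.asymptotic_ci(self._raw, level=level)

    def conf_int_bootstrap(self, B=1000, level=0.95, seed=0):
        return _freq.bootstrap_ci(self.model.data, baseline=self.model.baseline,
                                  B=B, level=level, seed=seed,
                                  full_fit=self._raw)

    def distribution(self, which="stress"):
        return self._raw.distribution(which)

    def to_dict(self):
        ci = self.conf_int_asymptotic()
        return {
            "baseline": self._raw.baseline_name,
            "n": self._raw.n, "m": self._raw.m,
            "params": self.params.to_dict(),
            "bse": {k: (None if not np.isfinite(v) else v)
                    for k, v in self.bse.items()},
            "loglik": self.llf,
            "R_hat": self.R_hat,
            "asymptotic_ci_95": [ci.lower, ci.upper],
            "converged": bool(self.converged),
        }

    def summary(self, level=0.95):
        raw = self._raw
        ci = self.conf_int_asymptotic(level=level)
        lines = [
            "Stress-Strength EGMO-G Maximum Likelihood Results",
            "=" * 57,
            f"Baseline: {raw.baseline_name:<14} n = {raw.n}, m = {raw.m}",
            f"Log-likelihood: {raw.loglik:.6f}   converged: {raw.converged}",
            "-" * 57,
            f"{'param':>8} {'estimate':>14} {'std err':>12}",
        ]
        for name, est, se in zip(raw.param_names, raw.params_full, self.bse):
            se_s = f"{se:12.4g}" if np.isfinite(se) else "         ---"
            lines.append(f"{name:>8} {est:14.6g} {se_s}")
        lines += [
            "-" * 57,
            f"R_hat = b1/(b1+b2) = {self.R_hat:.6f}",
            f"{int(level*100)}% asymptotic CI: [{ci.lower:.6f}, {ci.upper:.6f}]",
        ]
        return "\n".join(lines)


class BayesResults:
    """Posterior results: chain, squared-error-loss estimate, credible bands."""

    def __init__(self, model, draws: _bayes.PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def chain(self):
        return self.draws.chain

    @property
    def estimate(self):
        return _bayes.bayes_estimate_sel(self.draws)

    def credible_interval(self, level=0.95):
        return _bayes.credible_interval_empirical(self.draws, level=level)

    @property
    def acceptance_rate_lambda(self):
        return self.draws.acceptance_rate_lambda

    def to_csv(self, path):
        self.chain.to_csv(path, index=False)

    def summary(self, level=0.95):
        ci = self.credible_interval(level=level)
        post = self.chain.mean()
        lines = [
            "Stress-Strength EGMO-G Bayesian Results (MCMC)",
            "=" * 57,
            f"mode: {self.draws.mode}   T = {self.draws.T}   seed = {self.draws.seed}",
            "-" * 57,
            "posterior means:",
        ]
        for k, v in post.items():
            lines.append(f"{k:>8} {v:14.6g}")
        lines += [
            "-" * 57,
            f"R_B (squared-error loss) = {self.estimate:.6f}",
            f"{int(level*100)}% credible interval: [{ci.lower:.6f}, {ci.upper:.6f}]",
        ]
        return "\n".join(lines)
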