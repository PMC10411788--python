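"""Baseline (parent) distributions pluggable into the EGMO-G construction.

A baseline supplies the usual distribution surface (cdf/pdf/survival/quantile,
all delegated to :mod:`scipy.stats`) plus the two analytic gradients the
stress-strength score vector needs: the partial derivatives of the survival
function and of the log-density with respect to each baseline parameter.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["Baseline", "WeibullBaseline", "ExponentialBaseline", "get_baseline"]


class Baseline:
    """Abstract baseline distribution G with parameter vector ``params``.

    Subclasses must define ``name``, ``param_names`` and the frozen
    scipy distribution returned by :meth:`_make_dist`, and implement the
    analytic gradients :meth:`dsf_dparam` and :meth:`dlogpdf_dparam`.
    """

    name: str = ""
    param_names: tuple[str, ...] = ()

    def __init__(self, params):
        params = np.asarray(params, dtype=float)
        if params.shape != (len(self.param_names),):
            raise ValueError(
                f"{self.name} baseline expects {len(self.param_names)} "
                f"parameters {self.param_names}, got {params.shape}"
            )
        if np.any(params <= 0) or not np.all(np.isfinite(params)):
            raise ValueError(f"baseline parameters must be positive finite, got {params}")
        self.params = params
        self._frozen = None

    def _make_dist(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def _dist(self):
        # parameters are immutable, so the frozen distribution is built once
        if self._frozen is None:
            self._frozen = self._make_dist()
        return self._frozen

    # -- distribution surface ------------------------------------------------
    def cdf(self, x):
        return self._dist().cdf(x)

    def pdf(self, x):
        return self._dist().pdf(x)

    def logpdf(self, x):
        return self._dist().logpdf(x)

    def survival(self, x):
        return self._dist().sf(x)

    def logsf(self, x):
        return self._dist().logsf(x)

    def quantile(self, u):
        return self._dist().ppf(u)

    def isf(self, q):
        return self._dist().isf(q)

    # -- gradient contract ---------------------------------------------------
    def dsf_dparam(self, x, k):
        """∂Ḡ(x)/∂λk (so that ∂G/∂λk = −dsf_dparam)."""
        raise NotImplementedError

    def dlogpdf_dparam(self, x, k):
        """∂ log g(x)/∂λk."""
        raise NotImplementedError

    def with_params(self, params):
        return type(self)(params)

    def __repr__(self):
        pars = ", ".join(f"{n}={v:g}" for n, v in zip(self.param_names, self.params))
        return f"{type(self).__name__}({pars})"


class WeibullBaseline(Baseline):
    """Weibull baseline with shape γ and scale β: Ḡ(x) = exp(−(x/β)^γ)."""

    name = "weibull"
    param_names = ("gamma", "beta")

    def _make_dist(self):
        gamma, beta = self.params
        return stats.weibull_min(gamma, scale=beta)

    def dsf_dparam(self, x, k):
        x = np.asarray(x, dtype=float)
        gamma, beta = self.params
        z = (x / beta) ** gamma
        s = np.exp(-z)
        if k == 0:  # ∂/∂γ
            return -s * z * np.log(x / beta)
        if k == 1:  # ∂/∂β
            return s * z * gamma / beta
        raise IndexError(k)

    def dlogpdf_dparam(self, x, k):
        x = np.asarray(x, dtype=float)
        gamma, beta = self.params
        z = (x / beta) ** gamma
        if k == 0:
            return 1.0 / gamma + np.log(x / beta) * (1.0 - z)
        if k == 1:
            return gamma * (z - 1.0) / beta
        raise IndexError(k)


class ExponentialBaseline(Baseline):
    """Exponential baseline with rate λ: Ḡ(x) = exp(−λx)."""

    name = "exponential"
    param_names = ("lam",)

    def _make_dist(self):
        (lam,) = self.params
        return stats.expon(scale=1.0 / lam)

    def dsf_dparam(self, x, k):
        x = np.asarray(x, dtype=float)
        (lam,) = self.params
        if k == 0:
            return -x * np.exp(-lam * x)
        raise IndexError(k)

    def dlogpdf_dparam(self, x, k):
        x = np.asarray(x, dtype=float)
        (lam,) = self.params
        if k == 0:
            return 1.0 / lam - x
        raise IndexError(k)


_REGISTRY = {
    "weibull": WeibullBaseline,
    "exponential": ExponentialBaseline,
}


def get_baseline(name, params=None):
    """Return a baseline instance (or class when ``params`` is None) by name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown baseline {name!r}; known: {sorted(_REGISTRY)}") from None
    return cls if params is None else cls(params)
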