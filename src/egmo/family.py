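"""The exponentiated generalized Marshall-Olkin G (EGMO-G) family.

The construction tilts a baseline survival function Ḡ through the
Marshall-Olkin ratio ϑḠ/(1−ϑ̄Ḡ) with ϑ̄ = 1−ϑ, raises it to an inner power
``a`` ("generalization") and the complement to an outer power ``b``
("exponentiation"):

    F(x) = {1 − [ϑḠ(x) / (1 − ϑ̄Ḡ(x))]^a}^b ,   a, b, ϑ > 0.

For a = b = ϑ = 1 the family collapses to its baseline.  ϑ > 1 (hence
ϑ̄ < 0) is explicitly allowed; the denominator 1 − ϑ̄Ḡ is then > 1.

Numerics: with G = G(x) and Ḡ = 1−G the denominator is rewritten as
w = G + ϑḠ (exact, no cancellation), the Marshall-Olkin ratio as
r = 1 − G/w, and {1 − r^a} is kept in log space through log1p/expm1 so
that outer exponents b−1 < 0 never overflow.
"""

from __future__ import annotations

import numpy as np

from .baselines import Baseline, get_baseline

__all__ = ["EGMOParams", "EGMODistribution", "egmo_cdf", "egmo_pdf",
           "egmo_quantile", "egmo_sample"]


def mo_log_ratio(G, logsbar, theta):
    """log of the Marshall-Olkin ratio r = ϑḠ/(1−ϑ̄Ḡ), cancellation-safe.

    With w = G + ϑḠ ( = 1 − ϑ̄Ḡ):  for small G the complement 1 − r = G/w
    is exact, so log r = log1p(−G/w); for large G (where Ḡ underflows the
    complement) log r = log ϑ + log Ḡ − log w is the accurate branch.
    """
    sbar = np.exp(logsbar)
    w = G + theta * sbar
    with np.errstate(divide="ignore"):
        small_G = np.log1p(-G / np.where(w > 0, w, 1.0))
        large_G = np.log(theta) + logsbar - np.log(w)
    return np.where(G < 0.5, small_G, large_G)


class EGMOParams:
    """Parameter bundle (a, b, ϑ) plus a baseline for the EGMO-G family."""

    __slots__ = ("a", "b", "theta", "baseline")

    def __init__(self, a, b, theta, baseline):
        for nm, v in (("a", a), ("b", b), ("theta", theta)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {nm} must be positive finite, got {v}")
        if not isinstance(baseline, Baseline):
            raise TypeError("baseline must be a Baseline instance")
        self.a = float(a)
        self.b = float(b)
        self.theta = float(theta)
        self.baseline = baseline

    @property
    def theta_bar(self):
        return 1.0 - self.theta

    def __repr__(self):
        return (f"EGMOParams(a={self.a:g}, b={self.b:g}, theta={self.theta:g}, "
                f"baseline={self.baseline!r})")


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("x must be positive and finite")
    return x


class EGMODistribution:
    """EGMO-G distribution frozen at given parameters, scipy.stats-flavoured.

    Parameters
    ----------
    a, b, theta : float
        Positive shape parameters (inner power, outer power, Marshall-Olkin
        tilt).
    baseline : Baseline or str
        A baseline instance, or a registered name (then ``baseline_params``
        must be given).
    baseline_params : sequence of float, optional
        Parameters for a named baseline.
    """

    def __init__(self, a, b, theta, baseline, baseline_params=None):
        if isinstance(baseline, str):
            baseline = get_baseline(baseline, baseline_params)
        self.params = EGMOParams(a, b, theta, baseline)

    # convenience accessors
    a = property(lambda self: self.params.a)
    b = property(lambda self: self.params.b)
    theta = property(lambda self: self.params.theta)
    baseline = property(lambda self: self.params.baseline)

    # -- internal pieces -----------------------------------------------------
    def _log_one_minus_ra(self, x):
        """log{1 − r(x)^a} with r the Marshall-Olkin tilted survival."""
        base = self.baseline
        log_r = mo_log_ratio(base.cdf(x), base.logsf(x), self.theta)
        with np.errstate(divide="ignore"):
            return np.log1p(-np.exp(self.a * log_r))  # ≤ 0, −inf at x→0+

    # -- distribution surface ------------------------------------------------
    def logcdf(self, x):
        x = _check_x(x)
        return self.b * self._log_one_minus_ra(x)

    def cdf(self, x):
        return np.exp(self.logcdf(x))

    def sf(self, x):
        return -np.expm1(self.logcdf(x))

    def logpdf(self, x):
        # a·logϑ + (a−1)logḠ − (a+1)logw is rewritten as a·logr − logḠ − logw
        # (with logr the stable MO log-ratio) to preserve the analytic
        # cancellation between the huge-ϑ and huge-a regimes
        x = _check_x(x)
        a, b, theta = self.a, self.b, self.theta
        base = self.baseline
        G = base.cdf(x)
        logsbar = base.logsf(x)
        w = G + theta * np.exp(logsbar)
        logr = mo_log_ratio(G, logsbar, theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            L1 = np.log1p(-np.exp(a * logr))
            out = (np.log(a) + np.log(b) + base.logpdf(x)
                   + a * logr - logsbar - np.log(w)
                   + (b - 1.0) * L1)
        return out

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def ppf(self, u):
        """Quantile by the closed-form inversion through the baseline.

        Solving F(x) = u: t = (1 − u^{1/b})^{1/a}; the baseline survival
        target is Ḡ* = t/(ϑ + ϑ̄ t) and x = Ḡ⁻¹(Ḡ*).
        """
        u = np.asarray(u, dtype=float)
        if np.any(u <= 0) or np.any(u >= 1):
            raise ValueError("u must lie strictly inside (0, 1)")
        a, b, theta = self.a, self.b, self.theta
        t = (-np.expm1(np.log(u) / b)) ** (1.0 / a)   # (1 − u^{1/b})^{1/a}
        sbar = t / (theta + (1.0 - theta) * t)        # ϑ + ϑ̄t = t + ϑ(1−t)
        return self.baseline.isf(sbar)

    quantile = ppf

    def rvs(self, size, seed=None, rng=None):
        """Inverse-transform sampling; reproducible given ``seed``."""
        if rng is None:
            rng = np.random.default_rng(seed)
        u = rng.uniform(size=size)
        # keep u away from the open-interval endpoints at float resolution
        u = np.clip(u, 1e-15, 1.0 - 1e-15)
        return self.ppf(u)

    def __repr__(self):
        return f"EGMODistribution({self.params!r})"


# -- functional wrappers (operation-style surface) ---------------------------

def _dist(params: EGMOParams) -> EGMODistribution:
    return EGMODistribution(params.a, params.b, params.theta, params.baseline)


def egmo_cdf(params, x):
    """F(x) for the EGMO-G family at parameter bundle ``params``."""
    return _dist(params).cdf(x)


def egmo_pdf(params, x):
    """f(x) for the EGMO-G family."""
    return _dist(params).pdf(x)


def egmo_quantile(params, u):
    """Quantile function (inverse cdf) of the EGMO-G family."""
    return _dist(params).ppf(u)


def egmo_sample(params, n, seed=None, rng=None):
    """n i.i.d. draws by inverse-transform sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _dist(params).rvs(int(n), seed=seed, rng=rng)
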