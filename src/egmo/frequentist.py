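"""Joint maximum-likelihood inference for the stress-strength model.

Two independent samples — stress X (size n) and strength Y (size m) — are
modelled as EGMO-G with shared (a, ϑ, λk) and sample-specific outer powers
b1 and b2.  The stress-strength reliability is then R = P(Y < X) =
b1/(b1 + b2), estimated by R̂ = b̂1/(b̂1 + b̂2).

b1 and b2 admit closed-form profile maximizers given the shared parameters
(b̂1 = −n/Σ log{1−r(xi)^a}), so the numerical optimization runs over the
log-transformed shared parameters only, with multi-start to cope with the
multimodal surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .baselines import Baseline, get_baseline
from .family import EGMODistribution, mo_log_ratio

__all__ = [
    "StressStrengthData", "StressStrengthFit", "IntervalEstimate",
    "log_likelihood", "score_vector", "profile_b_hats", "fit_mle",
    "asymptotic_ci", "bootstrap_ci", "observed_information",
]

_BIG = 1e12


class StressStrengthData:
    """Container for the two positive samples (stress x, strength y)."""

    def __init__(self, x, y):
        x = np.sort(np.asarray(x, dtype=float).ravel())
        y = np.sort(np.asarray(y, dtype=float).ravel())
        for nm, v in (("x", x), ("y", y)):
            if v.size == 0 or np.any(v <= 0) or np.any(~np.isfinite(v)):
                raise ValueError(f"sample {nm} must be nonempty, positive and finite")
        self.x = x
        self.y = y

    @property
    def n(self):
        return self.x.size

    @property
    def m(self):
        return self.y.size

    def __repr__(self):
        return f"StressStrengthData(n={self.n}, m={self.m})"


@dataclass
class IntervalEstimate:
    """A two-sided interval for R with its nominal level and method label."""

    lower: float
    upper: float
    level: float
    method: str
    n_failed: int = 0

    def __iter__(self):
        yield self.lower
        yield self.upper

    @property
    def length(self):
        return self.upper - self.lower


@dataclass
class StressStrengthFit:
    """Joint MLE of (b1, b2, ϑ, a, λk) with R̂ and the observed information."""

    b1_hat: float
    b2_hat: float
    theta_hat: float
    a_hat: float
    lambda_hat: np.ndarray
    loglik: float
    baseline_name: str
    n: int
    m: int
    converged: bool
    n_restarts_used: int
    info_matrix: np.ndarray | None = None
    param_names: tuple = field(default_factory=tuple)

    @property
    def R_hat(self):
        return self.b1_hat / (self.b1_hat + self.b2_hat)

    @property
    def params_full(self):
        """Vector (b1, b2, ϑ, a, λk…) in the information-matrix order."""
        return np.concatenate([[self.b1_hat, self.b2_hat, self.theta_hat,
                                self.a_hat], self.lambda_hat])

    @property
    def bse(self):
        """Asymptotic standard errors from the inverse observed information."""
        if self.info_matrix is None:
            return None
        try:
            cov = np.linalg.inv(self.info_matrix)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            return np.sqrt(d)
        except np.linalg.LinAlgError:
            return np.full(self.params_full.size, np.nan)

    def baseline(self):
        return get_baseline(self.baseline_name, self.lambda_hat)

    def distribution(self, which):
        """Fitted EGMO distribution for the ``"stress"`` or ``"strength"`` arm."""
        b = {"stress": self.b1_hat, "strength": self.b2_hat}[which]
        return EGMODistribution(self.a_hat, b, self.theta_hat, self.baseline())


# -- likelihood machinery ----------------------------------------------------

def _pieces(baseline: Baseline, theta, a, x):
    """Per-observation terms shared by the log-likelihood and the score."""
    G = baseline.cdf(x)
    logsbar = baseline.logsf(x)
    sbar = np.exp(logsbar)
    w = G + theta * sbar                      # 1 − ϑ̄Ḡ
    with np.errstate(divide="ignore"):
        logr = mo_log_ratio(G, logsbar, theta)
        A = np.exp(a * logr)
        L1 = np.log1p(-A)                     # log{1 − r^a}
    return {"G": G, "sbar": sbar, "logsbar": logsbar, "w": w,
            "logr": logr, "A": A, "L1": L1, "logg": baseline.logpdf(x)}


def _sample_loglik(p, b, theta, a, n):
    """Sample contribution to log L given precomputed pieces ``p``.

    Written in the cancellation-safe form n·log(ab) + Σ log g + a·Σ log r
    − Σ log Ḡ − Σ log w + (b−1)·Σ L1, equivalent to the textbook display.
    """
    return (n * (np.log(a) + np.log(b))
            + p["logg"].sum() + a * p["logr"].sum()
            - p["logsbar"].sum() - np.log(p["w"]).sum()
            + (b - 1.0) * p["L1"].sum())


def log_likelihood(data: StressStrengthData, b1, b2, theta, a, baseline: Baseline):
    """Joint log-likelihood; −inf sentinel at infeasible parameter points."""
    if min(b1, b2, theta, a) <= 0:
        return -np.inf
    px = _pieces(baseline, theta, a, data.x)
    py = _pieces(baseline, theta, a, data.y)
    ll = (_sample_loglik(px, b1, theta, a, data.n)
          + _sample_loglik(py, b2, theta, a, data.m))
    return ll if np.isfinite(ll) else -np.inf


def profile_b_hats(data: StressStrengthData, theta, a, baseline: Baseline):
    """Closed-form profile maximizers b̂1 = −n/Σ L1(x), b̂2 = −m/Σ L1(y)."""
    S1 = _pieces(baseline, theta, a, data.x)["L1"].sum()
    S2 = _pieces(baseline, theta, a, data.y)["L1"].sum()
    if not (S1 < 0 and S2 < 0 and np.isfinite(S1) and np.isfinite(S2)):
        raise FloatingPointError("degenerate data: a profile log term vanishes")
    return -data.n / S1, -data.m / S2


def _sample_score(p, b, theta, a, baseline: Baseline, x, n):
    """Score contributions (db, dtheta, da, dλk…) for one sample."""
    sbar, w, logr, A, L1 = p["sbar"], p["w"], p["logr"], p["A"], p["L1"]
    Q = A / (1.0 - A)
    db = n / b + L1.sum()
    dtheta = (a * n / theta - (a + 1.0) * (sbar / w).sum()
              - (b - 1.0) * a * (Q * (1.0 - sbar) / w).sum() / theta)
    da = n / a + logr.sum() - (b - 1.0) * (Q * logr).sum()
    dlam = []
    tbar = 1.0 - theta
    for k in range(len(baseline.params)):
        sp = baseline.dsf_dparam(x, k)
        term = (baseline.dlogpdf_dparam(x, k).sum()
                + (a - 1.0) * (sp / sbar).sum()
                + (a + 1.0) * tbar * (sp / w).sum()
                - (b - 1.0) * a * (Q * sp / (sbar * w)).sum())
        dlam.append(term)
    return db, dtheta, da, np.asarray(dlam)


def score_vector(data: StressStrengthData, b1, b2, theta, a, baseline: Baseline):
    """Analytic gradient of log L in the order (b1, b2, ϑ, a, λk…)."""
    px = _pieces(baseline, theta, a, data.x)
    py = _pieces(baseline, theta, a, data.y)
    db1, dth_x, da_x, dl_x = _sample_score(px, b1, theta, a, baseline, data.x, data.n)
    db2, dth_y, da_y, dl_y = _sample_score(py, b2, theta, a, baseline, data.y, data.m)
    return np.concatenate([[db1, db2, dth_x + dth_y, da_x + da_y], dl_x + dl_y])


# -- optimization ------------------------------------------------------------

# compact optimization box for the log shared parameters: beyond e^±15 the
# Marshall-Olkin tilt is numerically indistinguishable from its limiting
# form and the likelihood surface degenerates into a flat ridge
_LOG_BOX = 15.0


def _neg_profile_loglik(psi, data, baseline_cls, want_grad=False):
    """Negative profiled log-likelihood over ψ = log(ϑ, a, λk…).

    Per-observation pieces are computed once per sample and shared by the
    profile maximizers, the likelihood value and the envelope gradient.
    """
    fail = (_BIG, np.zeros_like(psi)) if want_grad else _BIG
    if np.any(np.abs(psi) > _LOG_BOX):
        return fail
    theta, a, *lam = np.exp(psi)
    try:
        baseline = baseline_cls(lam)
        with np.errstate(over="ignore", invalid="ignore"):
            px = _pieces(baseline, theta, a, data.x)
            py = _pieces(baseline, theta, a, data.y)
    except (FloatingPointError, ValueError):
        return fail
    S1, S2 = px["L1"].sum(), py["L1"].sum()
    if not (S1 < 0 and S2 < 0 and np.isfinite(S1) and np.isfinite(S2)):
        return fail
    b1, b2 = -data.n / S1, -data.m / S2
    with np.errstate(over="ignore", invalid="ignore"):
        ll = (_sample_loglik(px, b1, theta, a, data.n)
              + _sample_loglik(py, b2, theta, a, data.m))
    if not np.isfinite(ll):
        return fail
    if not want_grad:
        return -ll
    # envelope theorem: d/dψ of the profiled log L is the partial score at
    # the profiled (b̂1, b̂2), times exp(ψ) for the log-parametrization
    with np.errstate(over="ignore", invalid="ignore"):
        _, dth_x, da_x, dl_x = _sample_score(px, b1, theta, a, baseline,
                                             data.x, data.n)
        _, dth_y, da_y, dl_y = _sample_score(py, b2, theta, a, baseline,
                                             data.y, data.m)
        score = np.concatenate([[dth_x + dth_y, da_x + da_y], dl_x + dl_y])
        grad = -score * np.exp(psi)
    if not np.all(np.isfinite(grad)):
        return fail
    return -ll, grad


def _start_points(data, baseline_cls, starts, rng):
    """Data-driven start (baseline MLE, a=ϑ=1) plus log-uniform random starts."""
    pts = []
    try:
        if baseline_cls.name == "weibull":
            c, _, scale = stats.weibull_min.fit(np.r_[data.x, data.y], floc=0)
            lam0 = [c, scale]
        else:
            lam0 = [1.0 / np.mean(np.r_[data.x, data.y])]
        pts.append(np.log(np.r_[1.0, 1.0, lam0]))
    except Exception:
        pass
    d = 2 + len(baseline_cls.param_names)
    lo, hi = np.log(1e-2), np.log(1e2)
    for _ in range(starts):
        pts.append(rng.uniform(lo, hi, size=d))
    return pts


def _is_stationary(res, tol_scale):
    """Interior stationary candidate: off the box bounds with a dead gradient.

    Boundary candidates are the non-identifiable limiting sub-families
    (a→0 with ϑ→∞, or ϑ→0 with b→∞) along which the likelihood climbs
    without attaining a maximum; they are rejected as estimates.
    """
    interior = np.all(np.abs(res.x) < _LOG_BOX - 1e-6)
    return interior and np.max(np.abs(res.jac)) < 1e-3 * tol_scale


def fit_mle(data, baseline="weibull", starts=20, seed=0, x0=None,
            compute_info=True, polish=True):
    """Joint MLE by multi-start quasi-Newton over the log shared parameters.

    The estimate is the best *interior stationary* local maximum found:
    candidates on the optimization box boundary or with a materially
    nonzero score (likelihood ridges of the over-parametrized family) are
    rejected; if no candidate passes, the best point found is returned
    with ``converged=False``.

    Parameters
    ----------
    data : StressStrengthData or (x, y) pair
    baseline : str
        Registered baseline name ("weibull" or "exponential").
    starts : int
        Number of random log-uniform starts in [1e-2, 1e2] per parameter,
        in addition to a data-driven start.
    seed : int
        Seed for the start-point generator.
    x0 : array, optional
        Warm start ψ0 = log(ϑ, a, λk…); if given it replaces the random
        multi-start (used by the bootstrap).
    polish : bool
        Tight optimizer tolerances (default).  ``False`` trades precision
        for speed — used by the Monte-Carlo drivers and bootstrap refits.
    """
    if not isinstance(data, StressStrengthData):
        data = StressStrengthData(*data)
    baseline_cls = get_baseline(baseline)
    rng = np.random.default_rng(seed)
    pts = [np.asarray(x0, float)] if x0 is not None else \
        _start_points(data, baseline_cls, starts, rng)

    best_ok = None
    best_any = None
    n_used = 0
    bounds = [(-_LOG_BOX, _LOG_BOX)] * len(pts[0])
    opts = {"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9} if polish \
        else {"maxiter": 300, "ftol": 1e-10, "gtol": 1e-7}
    for p0 in pts:
        res = optimize.minimize(
            _neg_profile_loglik, np.clip(p0, -_LOG_BOX, _LOG_BOX),
            args=(data, baseline_cls, True),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options=opts)
        n_used += 1
        if res.fun >= _BIG:
            continue
        if best_any is None or res.fun < best_any.fun:
            best_any = res
        if _is_stationary(res, max(1.0, abs(res.fun))) and \
                (best_ok is None or res.fun < best_ok.fun):
            best_ok = res
    if best_any is None:
        raise RuntimeError("no optimization start converged to a feasible point")
    best = best_ok if best_ok is not None else best_any

    theta, a, *lam = np.exp(best.x)
    baseline_inst = baseline_cls(lam)
    b1, b2 = profile_b_hats(data, theta, a, baseline_inst)
    ll = log_likelihood(data, b1, b2, theta, a, baseline_inst)

    fit = StressStrengthFit(
        b1_hat=b1, b2_hat=b2, theta_hat=theta, a_hat=a,
        lambda_hat=np.asarray(lam), loglik=ll, baseline_name=baseline,
        n=data.n, m=data.m, converged=best_ok is not None,
        n_restarts_used=n_used,
        param_names=("b1", "b2", "theta", "a") + baseline_cls.param_names)
    if compute_info and fit.converged:
        fit.info_matrix = observed_information(data, fit.params_full, baseline_cls)
    return fit


def observed_information(data, params, baseline_cls, rel_step=1e-4):
    """Negative Hessian of log L by central differences at ``params``.

    ``params`` is (b1, b2, ϑ, a, λk…); the differences are taken on the
    natural scale with a relative step.
    """
    params = np.asarray(params, dtype=float)
    p = params.size

    def ll(v):
        baseline = baseline_cls(v[4:])
        return log_likelihood(data, v[0], v[1], v[2], v[3], baseline)

    h = rel_step * np.maximum(np.abs(params), 1e-6)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                val = (ll(params + ei) - 2 * ll(params) + ll(params - ei)) / h[i] ** 2
            else:
                val = (ll(params + ei + ej) - ll(params + ei - ej)
                       - ll(params - ei + ej) + ll(params - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return -H


# -- interval estimates ------------------------------------------------------

def asymptotic_ci(fit: StressStrengthFit, level=0.95, n=None, m=None):
    """Delta-method interval R̂ ± z·b̂1b̂2/(b̂1+b̂2)²·√(1/n+1/m), clipped to [0,1]."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    n = fit.n if n is None else n
    m = fit.m if m is None else m
    z = stats.norm.ppf(0.5 + level / 2.0)
    b1, b2 = fit.b1_hat, fit.b2_hat
    half = z * b1 * b2 / (b1 + b2) ** 2 * np.sqrt(1.0 / n + 1.0 / m)
    lo = max(0.0, fit.R_hat - half)
    hi = min(1.0, fit.R_hat + half)
    return IntervalEstimate(lo, hi, level, "asymptotic")


def bootstrap_ci(data, baseline="weibull", B=1000, level=0.95, seed=0,
                 full_fit=None, return_draws=False):
    """Percentile bootstrap interval for R.

    Both samples are resampled with replacement independently; each
    resample is refitted warm-started at the full-data MLE and the
    empirical (δ/2, 1−δ/2) percentiles of the R̂* values are returned.
    Resamples whose refit fails are redrawn; more than 20% failures is an
    error.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if not isinstance(data, StressStrengthData):
        data = StressStrengthData(*data)
    if full_fit is None:
        full_fit = fit_mle(data, baseline=baseline, seed=seed)
    psi0 = np.log(np.r_[full_fit.theta_hat, full_fit.a_hat, full_fit.lambda_hat])
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    while len(draws) < B:
        xb = rng.choice(data.x, size=data.n, replace=True)
        yb = rng.choice(data.y, size=data.m, replace=True)
        try:
            f = fit_mle(StressStrengthData(xb, yb), baseline=baseline,
                        x0=psi0, compute_info=False, polish=False)
            draws.append(f.R_hat)
        except (RuntimeError, FloatingPointError):
            failures += 1
            if failures > 0.2 * B:
                raise RuntimeError("more than 20% of bootstrap refits failed")
    draws = np.sort(np.asarray(draws))
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    est = IntervalEstimate(lo, hi, level, "bootstrap", n_failed=failures)
    return (est, draws) if return_draws else est
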