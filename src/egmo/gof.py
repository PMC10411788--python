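"""Single-sample goodness-of-fit: EGMO-G against its nested sub-families.

Each sub-family is the EGMO-G density with some of (a, b, ϑ) pinned to 1:

====== =========================== ==========================
name    free shapes                 fixed
====== =========================== ==========================
EGMO    a, b, ϑ                     —
EG      a, b                        ϑ = 1
GMO     b, ϑ                        a = 1
EMO     a, ϑ                        b = 1
G       b                           a = ϑ = 1  (exponentiated baseline)
MO      ϑ                           a = b = 1
(base)  —                           a = b = ϑ = 1
====== =========================== ==========================

Fits are ranked by AIC; the KS statistic is the two-sided supremum
distance at the order statistics with the asymptotic Kolmogorov p-value
(estimated parameters plugged in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .baselines import get_baseline
from .family import EGMODistribution
from .frequentist import _pieces

__all__ = ["GofFit", "SUBMODELS", "fit_submodel", "ks_statistic",
           "compare_models", "compute_rates"]

_BIG = 1e12

# free-shape masks per sub-family tag: (a_free, b_free, theta_free)
_MASKS = {
    "EGMO": (True, True, True),
    "EG": (True, True, False),
    "GMO": (False, True, True),
    "EMO": (True, False, True),
    "G": (False, True, False),
    "MO": (False, False, True),
    "": (False, False, False),
}

SUBMODELS = {
    "weibull": ["EGMO-W", "EG-W", "GMO-W", "EMO-W", "G-W", "MO-W", "W"],
    "exponential": ["EGMO-E", "GMO-E", "EG-E", "MO-E", "E"],
}

_BASE_TAG = {"W": "weibull", "E": "exponential"}


def _parse_model(model):
    """Split e.g. "EGMO-W" → ("EGMO", "weibull"); "W" → ("", "weibull")."""
    if "-" in model:
        tag, suffix = model.rsplit("-", 1)
    else:
        tag, suffix = "", model
    if suffix not in _BASE_TAG or tag not in _MASKS:
        raise KeyError(f"unknown sub-model {model!r}")
    return tag, _BASE_TAG[suffix]


@dataclass
class GofFit:
    """Per-model fit record in the comparison-table layout."""

    model: str
    param_names: tuple
    estimates: np.ndarray
    bse: np.ndarray
    loglik: float
    aic: float
    bic: float
    ks_stat: float
    ks_pvalue: float
    n: int
    converged: bool = True
    a: float = 1.0
    b: float = 1.0
    theta: float = 1.0
    lam: np.ndarray = field(default_factory=lambda: np.array([]))
    baseline_name: str = ""

    @property
    def k(self):
        return len(self.param_names)

    def distribution(self):
        return EGMODistribution(self.a, self.b, self.theta,
                                self.baseline_name, self.lam)


def _single_loglik(x, a, b, theta, baseline):
    # cancellation-safe form: a·logϑ + (a−1)logḠ − (a+1)logw ≡ a·logr − logḠ − logw
    n = x.size
    p = _pieces(baseline, theta, a, x)
    ll = (n * (np.log(a) + np.log(b))
          + p["logg"].sum() + a * p["logr"].sum()
          - p["logsbar"].sum() - np.log(p["w"]).sum()
          + (b - 1.0) * p["L1"].sum())
    return ll, p["L1"].sum()


def _free_vector_loglik(v, x, mask, baseline_cls, profile_b=True):
    """Log-likelihood over the free natural-scale parameters ``v``.

    Order: [a (if free)], [theta (if free)], λk…; b is profiled out when
    free (b̂ = −n/Σ L1) and fixed at 1 otherwise.
    """
    a_free, b_free, th_free = mask
    i = 0
    a = v[i] if a_free else 1.0
    i += a_free
    theta = v[i] if th_free else 1.0
    i += th_free
    lam = v[i:]
    if min(a, theta, *lam) <= 0:
        return -np.inf, None
    try:
        baseline = baseline_cls(lam)
        ll, S = _single_loglik(x, a, 1.0, theta, baseline)
    except (ValueError, FloatingPointError):
        return -np.inf, None
    if not (S < 0 and np.isfinite(S)):
        return -np.inf, None
    if b_free and profile_b:
        b = -x.size / S
        ll = ll + x.size * np.log(b) + (b - 1.0) * S
    else:
        b = 1.0
    return (ll if np.isfinite(ll) else -np.inf), (a, b, theta, lam)


def fit_submodel(sample, model, starts=20, seed=0):
    """Fit one sub-family by multi-start MLE; returns a :class:`GofFit`."""
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    if np.any(x <= 0):
        raise ValueError("sample must be positive")
    tag, baseline_name = _parse_model(model)
    mask = _MASKS[tag]
    baseline_cls = get_baseline(baseline_name)
    l = len(baseline_cls.param_names)
    d = mask[0] + mask[2] + l

    # same compact log-box as the joint fit (tilt unidentifiable beyond it)
    BOX = 15.0

    def negll(psi):
        if np.any(np.abs(psi) > BOX):
            return _BIG
        ll, _ = _free_vector_loglik(np.exp(psi), x, mask, baseline_cls)
        return -ll if np.isfinite(ll) else _BIG

    rng = np.random.default_rng(seed)
    pts = []
    try:
        if baseline_name == "weibull":
            c, _, sc = stats.weibull_min.fit(x, floc=0)
            lam0 = [c, sc]
        else:
            lam0 = [1.0 / x.mean()]
        pts.append(np.log(np.r_[np.ones(mask[0] + mask[2]), lam0]))
    except Exception:
        pass
    pts += [rng.uniform(np.log(1e-2), np.log(1e2), size=d) for _ in range(starts)]

    # best interior stationary candidate wins; boundary/ridge points of the
    # over-parametrized family are rejected (flagged fallback otherwise)
    best_ok, best_any = None, None
    for p0 in pts:
        res = optimize.minimize(negll, np.clip(p0, -BOX, BOX),
                                method="L-BFGS-B",
                                bounds=[(-BOX, BOX)] * d,
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-9})
        if res.fun >= _BIG:
            continue
        if best_any is None or res.fun < best_any.fun:
            best_any = res
        stationary = (np.all(np.abs(res.x) < BOX - 1e-6)
                      and np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun)))
        if stationary and (best_ok is None or res.fun < best_ok.fun):
            best_ok = res
    if best_any is None:
        raise RuntimeError(f"no start converged for sub-model {model}")
    best = best_ok if best_ok is not None else best_any

    ll, (a, b, theta, lam) = _free_vector_loglik(np.exp(best.x), x, mask,
                                                 baseline_cls)
    # free parameters in the printed-table order: shapes then baseline
    names, estimates = [], []
    if mask[0]:
        names.append("a"); estimates.append(a)
    if mask[1]:
        names.append("b"); estimates.append(b)
    if mask[2]:
        names.append("theta"); estimates.append(theta)
    names += list(baseline_cls.param_names)
    estimates += list(lam)
    estimates = np.asarray(estimates)

    bse = _submodel_bse(x, mask, baseline_cls, a, b, theta, lam)
    k = len(names)
    dist = EGMODistribution(a, b, theta, baseline_name, lam)
    ks, pval = ks_statistic(x, dist.cdf)
    return GofFit(model=model, param_names=tuple(names), estimates=estimates,
                  bse=bse, loglik=ll, aic=2 * k - 2 * ll,
                  bic=k * np.log(x.size) - 2 * ll, ks_stat=ks, ks_pvalue=pval,
                  n=x.size, converged=best_ok is not None,
                  a=a, b=b, theta=theta, lam=np.asarray(lam),
                  baseline_name=baseline_name)


def _submodel_bse(x, mask, baseline_cls, a, b, theta, lam, rel_step=1e-4):
    """Standard errors from the FD observed information over the free params."""
    free = np.array([a] * mask[0] + [b] * mask[1] + [theta] * mask[2] + list(lam))
    a_free, b_free, th_free = mask

    def ll(v):
        i = 0
        av = v[i] if a_free else 1.0; i += a_free
        bv = v[i] if b_free else 1.0; i += b_free
        tv = v[i] if th_free else 1.0; i += th_free
        try:
            out, _ = _single_loglik(x, av, bv, tv, baseline_cls(v[i:]))
        except (ValueError, FloatingPointError):
            return -np.inf
        return out

    p = free.size
    h = rel_step * np.maximum(np.abs(free), 1e-6)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                val = (ll(free + ei) - 2 * ll(free) + ll(free - ei)) / h[i] ** 2
            else:
                val = (ll(free + ei + ej) - ll(free + ei - ej)
                       - ll(free - ei + ej) + ll(free - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    with np.errstate(invalid="ignore"):
        try:
            d = np.diag(np.linalg.inv(-H)).copy()
            d[d < 0] = np.nan
            return np.sqrt(d)
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)


def ks_statistic(sample, fitted_cdf):
    """Two-sided KS distance and asymptotic Kolmogorov p-value.

    D = max_i max(i/n − F̂(x_(i)), F̂(x_(i)) − (i−1)/n) at the order
    statistics; ties are handled by the cumulative empirical steps.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    F = np.asarray(fitted_cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    D = max(np.max(i / n - F), np.max(F - (i - 1) / n))
    pval = special.kolmogorov(np.sqrt(n) * D)
    return float(D), float(pval)


def compare_models(sample, baseline="weibull", models=None, starts=20, seed=0):
    """Fit the requested sub-families and return the comparison table.

    Returns a DataFrame sorted by AIC with a ``best`` flag on the minimum;
    per-model failures are reported inline (NaN rows) without aborting.
    """
    if models is None or models == "all":
        models = SUBMODELS[baseline]
    rows, fits = [], {}
    for mdl in models:
        try:
            f = fit_submodel(sample, mdl, starts=starts, seed=seed)
            fits[mdl] = f
            rows.append({
                "model": mdl,
                "params": ", ".join(f.param_names),
                "estimates": ", ".join(f"{v:.6g}" for v in f.estimates),
                "std_errors": ", ".join(f"{v:.3g}" for v in f.bse),
                "loglik": f.loglik, "aic": f.aic, "bic": f.bic,
                "ks": f.ks_stat, "p_value": f.ks_pvalue,
                "converged": f.converged,
            })
        except RuntimeError as exc:
            rows.append({"model": mdl, "params": "", "estimates": "",
                         "std_errors": "", "loglik": np.nan, "aic": np.nan,
                         "bic": np.nan, "ks": np.nan, "p_value": np.nan,
                         "converged": False, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["best"] = False
    if table["aic"].notna().any():
        table.loc[table["aic"].idxmin(), "best"] = True
    table.attrs["fits"] = fits
    return table


def compute_rates(confirmed, recovered, deaths):
    """Death rate = deaths/confirmed, recovery rate = recovered/confirmed."""
    confirmed = np.asarray(confirmed, dtype=float)
    recovered = np.asarray(recovered, dtype=float)
    deaths = np.asarray(deaths, dtype=float)
    if not (confirmed.shape == recovered.shape == deaths.shape):
        raise ValueError("count vectors must have equal lengths")
    if np.any(confirmed <= 0):
        raise ValueError("confirmed counts must be positive")
    return deaths / confirmed, recovered / confirmed
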