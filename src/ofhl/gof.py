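"""Goodness-of-fit battery for the OFHL model and its half-logistic baseline.

Reports the four information criteria (with ``nll`` the negative maximized
log-likelihood, ``k`` free parameters, ``n`` observations)

    AIC  = 2 k + 2 nll
    SIC  = k log n + 2 nll
    CAIC = AIC + 2 k (k+1) / (n - k - 1)
    HQIC = 2 k log(log n) + 2 nll

together with the Anderson-Darling (A*) and Cramér-von Mises (W*) distances —
the exact formulas used as estimation objectives, evaluated at whatever
parameters the caller supplies — and the two-sided Kolmogorov-Smirnov
statistic with its p-value.  The KS p-value uses the exact finite-sample null
distribution for n <= 100 and the asymptotic Kolmogorov series above that,
the convention of R's ``ks.test``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import optimize, special, stats

from . import estimation
from .distribution import Params, cdf as ofhl_cdf
from .estimation import FitResult, Sample, _values, neg_log_likelihood

__all__ = [
    "GofReport",
    "HLParam",
    "information_criteria",
    "ad_star",
    "w_star",
    "ks_test",
    "hl_pdf",
    "hl_cdf",
    "hl_neg_log_likelihood",
    "fit_hl_mle",
    "gof_report",
    "ttt_curve",
]


@dataclass(frozen=True)
class HLParam:
    """Half-logistic baseline parameter (one positive shape/rate)."""

    theta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta) and self.theta > 0.0):
            raise ValueError("theta must be a positive finite real")


@dataclass
class GofReport:
    n: int
    k_params: int
    neg_ll: float
    aic: float
    sic: float
    caic: float
    hqic: float
    a_star: float
    w_star: float
    ks: float
    ks_pvalue: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "k_params", "neg_ll", "aic", "sic", "caic", "hqic",
            "a_star", "w_star", "ks", "ks_pvalue",
        )}


def information_criteria(neg_ll: float, k_params: int, n: int) -> dict:
    """AIC/SIC/CAIC/HQIC from the negative maximized log-likelihood."""
    if n <= k_params + 1:
        raise ValueError("CAIC requires n > k_params + 1")
    aic = 2.0 * k_params + 2.0 * neg_ll
    return {
        "aic": aic,
        "sic": k_params * math.log(n) + 2.0 * neg_ll,
        "caic": aic + 2.0 * k_params * (k_params + 1.0) / (n - k_params - 1.0),
        "hqic": 2.0 * k_params * math.log(math.log(n)) + 2.0 * neg_ll,
    }


def ad_star(s, cdf_fn: Callable[[np.ndarray], np.ndarray]) -> float:
    """Anderson-Darling statistic of an arbitrary fitted CDF."""
    x = _values(s)
    n = x.size
    k = np.arange(1, n + 1)
    F = np.clip(np.asarray(cdf_fn(x), dtype=float), 1e-300, 1.0)
    S = np.clip(1.0 - F, 1e-300, 1.0)
    return float(-n - np.mean((2 * k - 1) * (np.log(F) + np.log(S[::-1]))))


def w_star(s, cdf_fn: Callable[[np.ndarray], np.ndarray]) -> float:
    """Cramér-von Mises statistic of an arbitrary fitted CDF."""
    x = _values(s)
    n = x.size
    k = np.arange(1, n + 1)
    F = np.asarray(cdf_fn(x), dtype=float)
    return float(1.0 / (12.0 * n) + np.sum((F - (2 * k - 1) / (2.0 * n)) ** 2))


def ks_test(
    s,
    cdf_fn: Callable[[np.ndarray], np.ndarray],
    mode: Literal["auto", "asymptotic", "exact"] = "auto",
) -> tuple[float, float]:
    """Two-sided KS statistic D and its p-value under the fitted CDF.

    D = max_k max(|k/n - F(x_(k))|, |(k-1)/n - F(x_(k))|).  ``mode="auto"``
    uses the exact finite-sample distribution for n <= 100 and the asymptotic
    Kolmogorov series otherwise.
    """
    x = _values(s)
    n = x.size
    k = np.arange(1, n + 1)
    F = np.asarray(cdf_fn(x), dtype=float)
    d = float(np.max(np.maximum(np.abs(k / n - F), np.abs((k - 1) / n - F))))
    if mode == "exact" or (mode == "auto" and n <= 100):
        p = float(stats.kstwo.sf(d, n))
    else:
        p = float(special.kolmogorov(math.sqrt(n) * d))
    return d, min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# half-logistic baseline
# ---------------------------------------------------------------------------

def hl_cdf(x, hp: HLParam):
    """Half-logistic CDF M(x) = (1 - e^{-theta x}) / (1 + e^{-theta x})."""
    x = np.asarray(x, dtype=float)
    e = np.exp(-hp.theta * np.maximum(x, 0.0))
    out = np.where(x > 0.0, (1.0 - e) / (1.0 + e), 0.0)
    return out if out.ndim else float(out)


def hl_pdf(x, hp: HLParam):
    x = np.asarray(x, dtype=float)
    e = np.exp(-hp.theta * np.maximum(x, 0.0))
    out = np.where(x > 0.0, 2.0 * hp.theta * e / (1.0 + e) ** 2, 0.0)
    return out if out.ndim else float(out)


def hl_neg_log_likelihood(s, hp: HLParam) -> float:
    x = _values(s)
    n = x.size
    ll = n * math.log(2.0 * hp.theta) - hp.theta * np.sum(x) - 2.0 * np.sum(
        np.log1p(np.exp(-hp.theta * x))
    )
    return -float(ll)


def fit_hl_mle(s) -> FitResult:
    """One-parameter half-logistic MLE by bounded scalar minimization."""
    x = _values(s)
    if x.size < 3:
        raise ValueError("fitting requires at least 3 observations")
    res = optimize.minimize_scalar(
        lambda lt: hl_neg_log_likelihood(x, HLParam(math.exp(lt))),
        bounds=(-15.0, 15.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    theta = float(math.exp(res.x))
    return FitResult(
        method="hl_mle",
        estimates=HLParam(theta),
        objective_value=float(res.fun),
        neg_log_likelihood=float(res.fun),
        converged=bool(res.success),
        n_starts=1,
        n_iter=int(res.nfev),
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def gof_report(s, params, model: Literal["ofhl", "hl"] = "ofhl") -> GofReport:
    """Full GoF battery for a fitted model at explicit parameter values.

    The A*/W* entries are evaluated at ``params`` — each estimation method's
    own estimates, not re-fitted — so the report and the estimation
    objectives agree by construction.
    """
    x = _values(s)
    n = x.size
    if model == "ofhl":
        p = params if isinstance(params, Params) else Params(*params)
        cdf_fn = lambda z: ofhl_cdf(z, p)
        nll = neg_log_likelihood(x, p)
        k_params = 2
        a = estimation.ad_objective(x, p)
        w = estimation.cvm_objective(x, p)
    elif model == "hl":
        hp = params if isinstance(params, HLParam) else HLParam(float(params))
        cdf_fn = lambda z: hl_cdf(z, hp)
        nll = hl_neg_log_likelihood(x, hp)
        k_params = 1
        a = ad_star(x, cdf_fn)
        w = w_star(x, cdf_fn)
    else:
        raise ValueError("model must be 'ofhl' or 'hl'")
    ic = information_criteria(nll, k_params, n)
    d, pv = ks_test(x, cdf_fn)
    return GofReport(
        n=n, k_params=k_params, neg_ll=nll,
        aic=ic["aic"], sic=ic["sic"], caic=ic["caic"], hqic=ic["hqic"],
        a_star=a, w_star=w, ks=d, ks_pvalue=pv,
    )


def ttt_curve(s) -> np.ndarray:
    """Scaled total-time-on-test transform of a sorted sample.

    Returns an (n+1, 2) array of points (r/n, T(r/n)) from (0, 0) to (1, 1)
    with T(r/n) = [sum_{i<=r} x_(i) + (n-r) x_(r)] / sum_i x_(i).  A concave
    curve indicates increasing hazard, convex decreasing, S-shapes bathtub
    forms.
    """
    x = _values(s)
    n = x.size
    if n < 2:
        raise ValueError("the TTT transform needs at least 2 observations")
    total = float(np.sum(x))
    csum = np.cumsum(x)
    r = np.arange(1, n + 1)
    t = (csum + (n - r) * x) / total
    u = np.concatenate(([0.0], r / n))
    tt = np.concatenate(([0.0], t))
    return np.column_stack([u, tt])
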