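"""Classical point estimation for the OFHL model.

Six estimators share one deterministic optimizer contract:

* MLE  — minimizes the negative log-likelihood derived from the density
  (the log-likelihood is ``sum log f(x_k)``; its alpha-gradient carries the
  ``-sum g_k^alpha log g_k`` term that the chain rule produces).
* ADE  — minimizes the Anderson-Darling distance
  ``A = -n - (1/n) sum (2k-1)[ln F(x_(k)) + ln S(x_(n+1-k))]``.
* CVME — minimizes the Cramér-von Mises distance
  ``C = 1/(12n) + sum [F(x_(k)) - (2k-1)/(2n)]^2``.
* MPSE — maximizes the mean log uniform spacing
  ``M = (1/(n+1)) sum log D_k`` with ``D_k = F(x_(k)) - F(x_(k-1))`` and the
  boundary conventions ``F(x_(0)) = 0``, ``F(x_(n+1)) = 1``.
* OLSE/WLSE — minimize ``sum w_k [F(x_(k)) - k/(n+1)]^2`` with ``w_k = 1``
  or the reciprocal-variance weight ``(n+1)^2 (n+2) / (k (n-k+1))`` of the
  k-th uniform order statistic.

All objectives are optimized over (log alpha, log theta) by Nelder-Mead from
a fixed 3x3 start grid, which makes every fit deterministic: alpha starts
{0.3, 1, 3} crossed with theta starts {m/2, m, 2m} where m = log(3)/median(x)
moment-matches the alpha=1 median formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .distribution import Params, _log_odds, logcdf, logpdf, logsf, cdf

__all__ = [
    "METHODS",
    "Sample",
    "FitResult",
    "neg_log_likelihood",
    "score",
    "ad_objective",
    "cvm_objective",
    "mps_objective",
    "lsq_objective",
    "spacings",
    "fit",
]

METHODS = ("mle", "ade", "cvme", "mpse", "olse", "wlse")


@dataclass(frozen=True)
class Sample:
    """Ordered univariate dataset of positive reals with a provenance label."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("a sample must be a non-empty 1-d array")
        if not np.all(np.isfinite(v)) or np.any(v <= 0.0):
            raise ValueError("all sample values must be finite and > 0")
        v = np.sort(v)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class FitResult:
    """Outcome of one estimation run."""

    method: str
    estimates: Params
    objective_value: float
    neg_log_likelihood: float
    converged: bool
    n_starts: int
    n_iter: int = 0
    messages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.estimates.alpha,
            "theta": self.estimates.theta,
            "objective": self.objective_value,
            "neg_log_likelihood": self.neg_log_likelihood,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "n_iter": self.n_iter,
            "messages": list(self.messages),
        }


def _values(s) -> np.ndarray:
    if isinstance(s, Sample):
        return s.values
    v = np.asarray(s, dtype=float)
    if not np.all(v[:-1] <= v[1:]):
        v = np.sort(v)
    if np.any(v <= 0.0) or not np.all(np.isfinite(v)):
        raise ValueError("all sample values must be finite and > 0")
    return v


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def neg_log_likelihood(s, p: Params) -> float:
    """-sum log f(x_k); +inf sentinel when any log term is undefined."""
    x = _values(s)
    val = -float(np.sum(logpdf(x, p)))
    return val if math.isfinite(val) else math.inf


def score(s, p: Params) -> np.ndarray:
    """Gradient (d/d alpha, d/d theta) of the log-likelihood.

    With lg = log g(x_k) and w_k = x_k / (1 - e^{-theta x_k}):

        dL/d alpha = n/alpha + sum lg_k - sum g_k^alpha lg_k
        dL/d theta = n/theta - alpha sum w_k
                     - sum x_k e^{-theta x_k} / (1 - e^{-theta x_k})
                     + alpha sum g_k^alpha w_k

    using d(lg)/d theta = -x/(1 - e^{-theta x}).
    """
    x = _values(s)
    n = x.size
    a, t = p.alpha, p.theta
    lg = _log_odds(x, t)
    ga = np.exp(a * lg)
    e = np.exp(-t * x)
    w = x / (1.0 - e)
    d_alpha = n / a + np.sum(lg) - np.sum(ga * lg)
    d_theta = n / t - a * np.sum(w) - np.sum(x * e / (1.0 - e)) + a * np.sum(ga * w)
    return np.array([d_alpha, d_theta])


def ad_objective(s, p: Params) -> float:
    """Anderson-Darling statistic of the fitted CDF (log-space evaluation)."""
    x = _values(s)
    n = x.size
    k = np.arange(1, n + 1)
    lF = np.asarray(logcdf(x, p))
    lS = np.asarray(logsf(x, p))
    if np.any(np.isneginf(lF)) or np.any(np.isneginf(lS)):
        return math.inf
    return float(-n - np.mean((2 * k - 1) * (lF + lS[::-1])))


def cvm_objective(s, p: Params) -> float:
    """Cramér-von Mises statistic; bounded below by 1/(12n)."""
    x = _values(s)
    n = x.size
    k = np.arange(1, n + 1)
    F = np.asarray(cdf(x, p))
    return float(1.0 / (12.0 * n) + np.sum((F - (2 * k - 1) / (2.0 * n)) ** 2))


def spacings(s, p: Params) -> np.ndarray:
    """Uniform spacings D_k = F(x_(k)) - F(x_(k-1)), k = 1..n+1.

    Non-negative and summing to 1 via the boundary conventions F(x_(0)) = 0,
    F(x_(n+1)) = 1.  Upper-tail spacings are computed as survival-function
    differences (S is exact near 1 via expm1) so that two CDF values both
    rounding to 1.0 do not collapse a genuinely positive spacing to zero.
    """
    x = _values(s)
    F = np.concatenate(([0.0], np.asarray(cdf(x, p)), [1.0]))
    S = np.concatenate(([1.0], np.exp(np.asarray(logsf(x, p))), [0.0]))
    lower = np.diff(F)
    upper = -np.diff(S)
    return np.where(F[:-1] < 0.5, lower, upper)


def mps_objective(s, p: Params) -> float:
    """Mean log-spacing (to MAXIMIZE); -inf sentinel for a zero spacing.

    Tied observations make their spacing identically zero; those spacings are
    replaced by the density at the tied value (the Cheng-Amin adjustment)
    before the zero-spacing sentinel applies.
    """
    x = _values(s)
    d = spacings(x, p)
    logd = np.empty_like(d)
    with np.errstate(divide="ignore"):
        np.log(d, out=logd, where=d > 0)
    logd[d <= 0] = -np.inf
    tied = np.concatenate(([False], np.diff(x) == 0.0))
    if np.any(tied):
        lp = np.asarray(logpdf(x, p))
        idx = np.flatnonzero(tied)
        logd[idx] = lp[idx]  # spacing k (0-based in d) ends at x_(k)
    if np.any(np.isneginf(logd)):
        return -math.inf
    return float(np.mean(logd))


def lsq_objective(s, p: Params, weighted: bool = False) -> float:
    """(Weighted) least-squares distance to the plotting positions k/(n+1)."""
    x = _values(s)
    n = x.size
    k = np.arange(1, n + 1)
    F = np.asarray(cdf(x, p))
    resid2 = (F - k / (n + 1.0)) ** 2
    if weighted:
        w = (n + 1.0) ** 2 * (n + 2.0) / (k * (n - k + 1.0))
        return float(np.sum(w * resid2))
    return float(np.sum(resid2))


_OBJECTIVES: dict[str, tuple[Callable, float]] = {
    # name -> (objective, sign applied so that the optimizer always minimizes)
    "mle": (neg_log_likelihood, 1.0),
    "ade": (ad_objective, 1.0),
    "cvme": (cvm_objective, 1.0),
    "mpse": (mps_objective, -1.0),
    "olse": (lambda s, p: lsq_objective(s, p, weighted=False), 1.0),
    "wlse": (lambda s, p: lsq_objective(s, p, weighted=True), 1.0),
}


# ---------------------------------------------------------------------------
# optimizer contract
# ---------------------------------------------------------------------------

def _start_grid(x: np.ndarray) -> list[np.ndarray]:
    m_hat = math.log(3.0) / float(np.median(x))
    return [
        np.log([a0, t0])
        for a0 in (0.3, 1.0, 3.0)
        for t0 in (0.5 * m_hat, m_hat, 2.0 * m_hat)
    ]


def fit(
    s,
    method: str = "mle",
    *,
    maxiter: int = 2000,
    xatol: float = 1e-8,
    fatol: float = 1e-10,
) -> FitResult:
    """Fit the OFHL model to a sample by the requested method.

    Deterministic multi-start Nelder-Mead over (log alpha, log theta); the
    returned :class:`FitResult` always carries the negative log-likelihood at
    the optimum, whichever objective was optimized.
    """
    method = method.lower()
    if method not in _OBJECTIVES:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    x = _values(s)
    if x.size < 3:
        raise ValueError("fitting requires at least 3 observations")
    x = np.ascontiguousarray(x)  # sorted once; objectives skip the re-sort
    objective, sign = _OBJECTIVES[method]

    def f(log_p: np.ndarray) -> float:
        a, t = np.exp(log_p)
        if not (np.isfinite(a) and np.isfinite(t) and a > 0 and t > 0):
            return math.inf
        val = sign * objective(x, Params(a, t))
        return val if math.isfinite(val) else math.inf

    starts = _start_grid(x)
    best = None
    messages: list[str] = []
    n_iter = 0
    # skip starts sitting on an infinite plateau (e.g. an underflowed spacing):
    # the simplex cannot rank vertices there and only burns its iteration budget
    finite_starts = [s0 for s0 in starts if math.isfinite(f(s0))]
    if finite_starts:
        starts = finite_starts
    for start in starts:
        with np.errstate(invalid="ignore"):  # NM compares inf sentinels
            res = optimize.minimize(
                f,
                start,
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
            )
        n_iter += int(res.nit)
        if not math.isfinite(res.fun):
            messages.append(f"start {np.exp(start)}: objective not finite at optimum")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} starts failed for method {method!r}: {messages}"
        )
    a, t = np.exp(best.x)
    p_hat = Params(float(a), float(t))
    return FitResult(
        method=method,
        estimates=p_hat,
        objective_value=sign * float(best.fun),
        neg_log_likelihood=neg_log_likelihood(x, p_hat),
        converged=bool(best.success),
        n_starts=len(starts),
        n_iter=n_iter,
        messages=messages,
    )


def fit_all(s, methods: Sequence[str] = METHODS) -> dict[str, FitResult]:
    """Convenience: fit every requested method on the same sample."""
    return {m: fit(s, m) for m in methods}
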