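"""Log-log confidence intervals and simultaneous confidence bands for CGRFS.

Both constructions use the log-log transformation ``h(x) = log{-log(1 - x)}``
so that retransformed limits stay inside the unit interval, together with the
weight

    g(t) = {CGRFS^(t) - 1} log{1 - CGRFS^(t)} / sqrt(n * var^{CGRFS^(t)}),

where ``var^`` is the bootstrap variance of the estimate.  Because
``dh(x) = -1 / {(1 - x) log(1 - x)}``, the studentization identity
``g(t) dh{CGRFS^(t)} = 1 / sqrt(n var^(t))`` holds wherever the estimate is
strictly inside (0, 1) and the variance is positive; time points where it is
not are flagged degenerate and carry collapsed bounds.

Empirical bootstrap quantiles use the ``ceil(B p)``-th order statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .resampling import BootstrapEnsemble
from .stepfun import StepFunction


@dataclass(frozen=True)
class ConfidenceSpec:
    """Confidence level and target (a time point or a band interval)."""

    alpha: float = 0.05
    time: float | None = None
    interval: tuple[float, float] | None = None
    transformation: str = "loglog"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.interval is not None and not self.interval[0] < self.interval[1]:
            raise ValueError("band interval must satisfy t1 < t2")
        if self.transformation != "loglog":
            raise ValueError("only the log-log transformation is supported")


@dataclass
class IntervalResult:
    """A pointwise confidence interval or a simultaneous confidence band."""

    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    quantile: float
    method: str
    kind: str  # "ci" or "band"
    degenerate: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def h_loglog(x):
    """``h(x) = log{-log(1 - x)}`` (defined for x in (0, 1))."""
    return np.log(-np.log1p(-np.asarray(x, dtype=np.float64)))


def h_loglog_inv(y):
    """``h^{-1}(y) = 1 - exp(-e^y)`` (saturating at the unit interval)."""
    with np.errstate(over="ignore"):
        return -np.expm1(-np.exp(np.asarray(y, dtype=np.float64)))


def dh_loglog(x):
    """``dh(x) = -1 / {(1 - x) log(1 - x)}``."""
    x = np.asarray(x, dtype=np.float64)
    return -1.0 / ((1.0 - x) * np.log1p(-x))


def order_statistic_quantile(x: np.ndarray, p: float) -> float:
    """The ``ceil(len(x) * p)``-th order statistic of ``x``."""
    x = np.sort(np.asarray(x, dtype=np.float64))
    b = len(x)
    if b == 0:
        raise ValueError("empty sample")
    k = min(max(ceil(b * p), 1), b)
    return float(x[k - 1])


# -- variance and weight ------------------------------------------------------


def bootstrap_variance(ensemble: BootstrapEnsemble) -> StepFunction:
    """Bootstrap variance of the CGRFS estimate on the ensemble grid.

    Realizations are stored on the sqrt(n) scale for both methods, so the
    estimate's variance is the replicate sample variance (denominator B - 1)
    divided by n.
    """
    if ensemble.B < 2:
        raise ValueError("need at least two bootstrap realizations")
    v = ensemble.realizations.var(axis=0, ddof=1) / ensemble.n
    return StepFunction(ensemble.grid, v, y0=0.0)


def weight_g(estimate: StepFunction, variance: StepFunction, n: int) -> StepFunction:
    """The band weight ``g(t)`` on the estimate's grid.

    The estimate is clipped to [0, 1] before transformation.  Degenerate
    times (clipped estimate 0 or 1, or zero variance) are flagged with NaN
    and excluded from band computations.
    """
    est = np.clip(np.asarray(estimate.values, dtype=np.float64), 0.0, 1.0)
    var = variance(estimate.x)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (est - 1.0) * np.log1p(-est) / np.sqrt(n * var)
    g = np.where((est > 0.0) & (est < 1.0) & (var > 0.0), g, np.nan)
    return StepFunction(estimate.x, g, y0=np.nan)


# -- pointwise confidence intervals ------------------------------------------


def _ci_bounds(est: float, q: float) -> tuple[float, float]:
    """Equal-theta log-log interval at one time point (est strictly in (0,1)).

    Evaluated in log space, ``1 - (1-est)^theta = -expm1{theta log(1-est)}``;
    the exponent of theta is clamped so an estimate within floating error of
    the boundary yields the limiting bounds instead of overflowing.
    """
    loge = np.log1p(-est)  # log(1 - est) < 0
    c = (est - 1.0) * loge  # positive on (0, 1)
    e = float(np.clip(q / c, -700.0, 700.0))
    lo = float(-np.expm1(np.exp(-e) * loge))
    hi = float(-np.expm1(np.exp(+e) * loge))
    return (min(lo, hi), max(lo, hi))


def loglog_ci(
    estimate_value: float,
    ensemble: BootstrapEnsemble,
    spec: ConfidenceSpec,
    t: float,
) -> IntervalResult:
    """Pointwise (1 - alpha) log-log confidence interval at time ``t``.

    ``q`` is the (1 - alpha/2) empirical quantile of the realizations at
    ``t`` divided by sqrt(n); the bounds are ``1 - {1 - CGRFS^(t)}^theta``
    with ``theta = exp[+-q / ({CGRFS^(t)-1} log{1-CGRFS^(t)})]``.  A clipped
    estimate of exactly 0 or 1 collapses the interval to the point.
    """
    est = float(np.clip(estimate_value, 0.0, 1.0))
    if ensemble.B * spec.alpha / 2.0 < 1.0:
        warnings.warn(
            "too few bootstrap realizations for the requested quantile; "
            "using the extreme order statistic",
            stacklevel=2,
        )
    q = order_statistic_quantile(
        ensemble.at(t) / np.sqrt(ensemble.n), 1.0 - spec.alpha / 2.0
    )
    degenerate = est <= 0.0 or est >= 1.0
    if degenerate:
        lo = hi = est
    else:
        lo, hi = _ci_bounds(est, q)
    return IntervalResult(
        times=np.asarray([t]),
        estimate=np.asarray([est]),
        lower=np.asarray([lo]),
        upper=np.asarray([hi]),
        quantile=q,
        method=ensemble.method,
        kind="ci",
        degenerate=np.asarray([degenerate]),
    )


# -- simultaneous confidence bands -------------------------------------------


def band_grid(estimate: StepFunction, spec: ConfidenceSpec) -> np.ndarray:
    """Evaluation grid of a band: estimate jump times within the interval,
    plus the interval endpoints (the sup of a step process is attained on
    jump points)."""
    t1, t2 = spec.interval
    inside = estimate.x[(estimate.x >= t1) & (estimate.x <= t2)]
    return np.unique(np.concatenate([[t1], inside, [t2]]))


def band_quantile(
    ensemble: BootstrapEnsemble,
    estimate: StepFunction,
    variance: StepFunction,
    spec: ConfidenceSpec,
) -> float:
    """(1 - alpha) quantile of the sup of the studentized bootstrap process.

    By the identity ``g dh = 1 / sqrt(n var^)``, the studentized process is
    ``|B^(t)| / sqrt(n var^(t))``; the sup runs over the nondegenerate grid
    points inside the band interval.
    """
    grid = band_grid(estimate, spec)
    est = np.clip(estimate(grid), 0.0, 1.0)
    var = variance(grid)
    ok = (est > 0.0) & (est < 1.0) & (var > 0.0)
    if not np.any(ok):
        raise ValueError("no nondegenerate grid point in the band interval")
    pts = grid[ok]
    idx = np.searchsorted(ensemble.grid, pts, side="right") - 1
    vals = np.where(
        idx[None, :] >= 0, ensemble.realizations[:, np.clip(idx, 0, None)], 0.0
    )
    stud = np.abs(vals) / np.sqrt(ensemble.n * var[ok])[None, :]
    sup = stud.max(axis=1)
    return order_statistic_quantile(sup, 1.0 - spec.alpha)


def loglog_band(
    estimate: StepFunction,
    variance: StepFunction,
    q: float,
    n: int,
    spec: ConfidenceSpec,
) -> IntervalResult:
    """Simultaneous (1 - alpha) log-log confidence band over the interval.

    On nondegenerate grid points the bounds are
    ``h^{-1}[h{CGRFS^(t)} +- q / {sqrt(n) g(t)}]``; degenerate points carry
    the collapsed (clipped) estimate.
    """
    if q < 0:
        raise ValueError("band quantile must be nonnegative")
    grid = band_grid(estimate, spec)
    est = np.clip(estimate(grid), 0.0, 1.0)
    var = variance(grid)
    ok = (est > 0.0) & (est < 1.0) & (var > 0.0)
    lower = est.copy()
    upper = est.copy()
    if np.any(ok):
        e = est[ok]
        g = (e - 1.0) * np.log1p(-e) / np.sqrt(n * var[ok])
        half = q / (np.sqrt(n) * g)
        hy = h_loglog(e)
        lower[ok] = h_loglog_inv(hy - half)
        upper[ok] = h_loglog_inv(hy + half)
    return IntervalResult(
        times=grid,
        estimate=est,
        lower=lower,
        upper=upper,
        quantile=q,
        method="band",
        kind="band",
        degenerate=~ok,
    )
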