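"""Growth-curve fits and minimum cohort-size inversion.

Two functional forms are fitted to saturation summaries:

* power-law growth ``N = a * X**b`` of the mean significant-gene count
  against cohort size or events number, fitted by default as ordinary
  least squares of ``ln N`` on ``ln X`` (the spreadsheet-trendline
  convention), with a nonlinear least-squares alternative on the linear
  scale;
* a logistic cumulative distribution function
  ``F(x) = 1 / (1 + exp(-(x - mu)/s))`` for the probability of obtaining
  at least one significant gene as a function of cohort size.

The logistic fit inverts in closed form to the minimum size achieving a
target probability below 1; a 100% target is resolved empirically as the
smallest grid size from which every replicate (at that size and all
larger ones) yields at least one hit, since the logistic only reaches 1
asymptotically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .saturation import ResampleRecord, summarize

__all__ = [
    "PowerLawFit",
    "LogisticFit",
    "fit_power_law",
    "eval_power_law",
    "logistic_cdf",
    "fit_logistic_cdf",
    "size_for_probability",
    "expected_events",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted power law N = a * X**b with goodness of fit.

    ``r_squared`` is reported on the scale the least squares ran on
    (``fit_scale``): the log-log scale for the default method, the linear
    scale for the nonlinear alternative.
    """

    a: float
    b: float
    r_squared: float
    fit_scale: str  # "log-log" or "linear"
    n_points: int

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("prefactor a must be positive")
        if not (0 <= self.r_squared <= 1):
            raise ValueError("r_squared must be in [0, 1]")
        if self.n_points < 3:
            raise ValueError("a power-law fit needs at least 3 points")


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic CDF: location mu (size at probability 0.5), scale s."""

    mu: float
    s: float
    rss: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("scale s must be positive")


def fit_power_law(
    x: np.ndarray, y: np.ndarray, fit_scale: str = "log-log"
) -> PowerLawFit:
    """Fit N = a * x**b.

    The default regresses ln y on ln x by ordinary least squares
    (a = exp(intercept), b = slope); points with y <= 0 carry no
    information on the log scale and are excluded with a log message.
    ``fit_scale="linear"`` instead runs nonlinear least squares of
    a*x**b against y directly (zeros allowed), initialised from the
    log-log solution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.any(x <= 0):
        raise ValueError("x values must be strictly positive")
    if fit_scale not in ("log-log", "linear"):
        raise ValueError("fit_scale must be 'log-log' or 'linear'")

    usable = y > 0
    if (~usable).any():
        logger.info(
            "excluding %d points with y <= 0 from the power-law fit",
            int((~usable).sum()),
        )
    xs, ys = x[usable], y[usable]
    if xs.size < 3:
        raise ValueError(
            f"power-law fit needs >= 3 points with y > 0, got {xs.size}"
        )

    lx, ly = np.log(xs), np.log(ys)
    res = stats.linregress(lx, ly)
    a0, b0 = math.exp(res.intercept), res.slope

    if fit_scale == "log-log":
        return PowerLawFit(
            a=a0,
            b=float(b0),
            r_squared=float(res.rvalue**2),
            fit_scale="log-log",
            n_points=int(xs.size),
        )

    popt, _ = optimize.curve_fit(
        lambda t, a, b: a * t**b, xs, ys, p0=[a0, b0], maxfev=10000
    )
    pred = popt[0] * xs ** popt[1]
    ss_res = float(np.sum((ys - pred) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        a=float(popt[0]),
        b=float(popt[1]),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        fit_scale="linear",
        n_points=int(xs.size),
    )


def eval_power_law(fit: PowerLawFit, x: float) -> float:
    """Predicted count a * x**b; requires x > 0."""
    if x <= 0:
        raise ValueError("power law is defined for x > 0 only")
    return fit.a * x**fit.b


def logistic_cdf(x: np.ndarray, mu: float, s: float) -> np.ndarray:
    """F(x) = 1 / (1 + exp(-(x - mu)/s))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - mu) / s))


def _crossing(x: np.ndarray, p: np.ndarray, level: float) -> float:
    """First linear-interpolated crossing of ``level``, for initialisation."""
    above = np.flatnonzero(p >= level)
    if above.size == 0:
        return float(x[-1])
    i = above[0]
    if i == 0 or p[i] == p[i - 1]:
        return float(x[i])
    w = (level - p[i - 1]) / (p[i] - p[i - 1])
    return float(x[i - 1] + w * (x[i] - x[i - 1]))


def fit_logistic_cdf(
    x: np.ndarray, p: np.ndarray, weights: np.ndarray | None = None
) -> LogisticFit:
    """Least-squares fit of the logistic CDF to probabilities per size.

    Initialisation takes the location from the empirical median crossing
    and the scale from the 25th-75th percentile crossing spread (the
    inter-quartile range of a logistic is ``2 s ln 3``).  Deterministic
    given its inputs.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape:
        raise ValueError("x and p must have the same length")
    if np.unique(x).size < 3:
        raise ValueError("logistic fit needs >= 3 distinct x values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.ptp(p) == 0:
        raise ValueError("all probabilities identical: location unidentifiable")

    order = np.argsort(x)
    xo, po = x[order], p[order]
    mu0 = _crossing(xo, po, 0.5)
    q25, q75 = _crossing(xo, po, 0.25), _crossing(xo, po, 0.75)
    s0 = max((q75 - q25) / (2.0 * math.log(3.0)), 1e-3 * max(np.ptp(xo), 1.0))

    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[order]
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        sigma = 1.0 / np.sqrt(w)

    popt, _ = optimize.curve_fit(
        logistic_cdf,
        xo,
        po,
        p0=[mu0, s0],
        sigma=sigma,
        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
        maxfev=20000,
    )
    mu, s = float(popt[0]), float(popt[1])
    resid = po - logistic_cdf(xo, mu, s)
    if sigma is not None:
        resid = resid / sigma
    return LogisticFit(mu=mu, s=s, rss=float(np.sum(resid**2)))


def size_for_probability(
    logfit: LogisticFit,
    records: list[ResampleRecord] | None,
    target_p: float,
) -> int | None:
    """Minimum cohort size reaching the target discovery probability.

    For ``target_p < 1`` this is the ceiling of the closed-form logistic
    inverse ``mu + s * ln(p / (1 - p))``.  For ``target_p == 1`` — which
    the logistic attains only asymptotically — the rule is empirical: the
    smallest grid size at which every replicate, there and at every
    larger size, produced at least one significant gene; ``None`` if no
    such size exists (not attained).
    """
    if not (0 < target_p <= 1):
        raise ValueError("target probability must be in (0, 1]")
    if target_p < 1:
        return math.ceil(
            logfit.mu + logfit.s * math.log(target_p / (1.0 - target_p))
        )
    if not records:
        raise ValueError("the 100% target needs the replicate records")
    summ = summarize(records).sort_values("size")
    sizes = summ["size"].to_numpy()
    saturated = summ["prob_ge1"].to_numpy() == 1.0
    # smallest size from which prob_ge1 stays pinned at 1
    ok_from = np.flatnonzero(saturated & (saturated[::-1].cumprod()[::-1] == 1))
    if ok_from.size == 0:
        return None
    return int(sizes[ok_from[0]])


def expected_events(n_sub: int, n_total: int, d_total: int) -> int:
    """Expected deaths in a uniform without-replacement subsample.

    The hypergeometric mean ``n_sub * d_total / n_total`` rounded half
    up, giving the integer events number a subsample of ``n_sub`` of
    ``n_total`` cases (``d_total`` deaths overall) carries on average.
    """
    if not (0 <= n_sub <= n_total):
        raise ValueError("need 0 <= n_sub <= n_total")
    if not (0 <= d_total <= n_total):
        raise ValueError("need 0 <= d_total <= n_total")
    if n_total == 0:
        return 0
    return int(math.floor(n_sub * d_total / n_total + 0.5))
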