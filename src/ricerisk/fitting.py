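"""Parametric input-distribution fitting and goodness-of-fit model selection.

The probabilistic exposure model feeds on two fitted inputs: a shifted
(three-parameter) lognormal for the contaminant concentration and a
triangular distribution for daily rice consumption.  Commercial risk
software parameterises the lognormal by its *arithmetic* mean ``m`` and
standard deviation ``s`` plus a location shift ``tau`` —
X = tau + Y with ln Y ~ N(mu_log, sigma_log^2), E[Y] = m, SD[Y] = s — so
this module carries both conventions and converts between them exactly:

    sigma_log^2 = ln(1 + (s/m)^2)
    mu_log      = ln(m) - sigma_log^2 / 2

Candidate families for AIC ranking default to {normal, lognormal,
shifted lognormal, gamma, triangular}; goodness of fit is summarised by the
Kolmogorov-Smirnov, Anderson-Darling and equal-probability-bin chi-square
statistics, with fitted parameters treated as known (statistics are
reported as-is, not re-calibrated into p-values).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateDataError,
    FitFailureError,
    InvalidInputError,
)

__all__ = [
    "FittedDistribution",
    "lognormal_arithmetic_to_logscale",
    "lognormal_logscale_to_arithmetic",
    "shifted_lognormal",
    "triangular",
    "fit_shifted_lognormal",
    "fit_lognormal",
    "fit_normal",
    "fit_gamma",
    "fit_triangular",
    "gof_suite",
    "rank_fits_by_aic",
    "DEFAULT_FAMILIES",
    "fit_candidates",
    "cdf_overlay",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameterisation conversions
# ---------------------------------------------------------------------------

def lognormal_arithmetic_to_logscale(m: float, s: float) -> tuple[float, float]:
    """Convert arithmetic mean/sd of a lognormal variate to (mu_log, sigma_log).

    Round-trips exactly: exp(mu + sigma^2/2) = m and the implied arithmetic
    sd equals s.
    """
    if m <= 0:
        raise InvalidInputError("arithmetic mean must be > 0")
    if s < 0:
        raise InvalidInputError("arithmetic sd must be >= 0")
    sigma2 = math.log1p((s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def lognormal_logscale_to_arithmetic(mu_log: float, sigma_log: float) -> tuple[float, float]:
    """Inverse of :func:`lognormal_arithmetic_to_logscale`."""
    if sigma_log < 0:
        raise InvalidInputError("sigma_log must be >= 0")
    m = math.exp(mu_log + sigma_log**2 / 2.0)
    s = m * math.sqrt(math.expm1(sigma_log**2))
    return m, s


# ---------------------------------------------------------------------------
# FittedDistribution container
# ---------------------------------------------------------------------------

@dataclass
class FittedDistribution:
    """A parametric family with parameters and (optionally) fit diagnostics.

    ``params`` is family-specific:

    * ``shifted_lognormal``: m, s, tau (arithmetic convention) plus the
      derived mu_log, sigma_log;
    * ``lognormal``: mu_log, sigma_log (tau fixed at 0);
    * ``triangular``: a (min), c (mode), b (max);
    * ``normal``: mean, sd;  ``gamma``: shape, scale.

    ``aic = 2k - 2 log L`` with k the number of free parameters.
    """

    family: str
    params: dict[str, float]
    n: int | None = None
    log_likelihood: float | None = None
    aic: float | None = None
    gof: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.params
        if self.family == "shifted_lognormal":
            if "mu_log" not in p:
                mu, sig = lognormal_arithmetic_to_logscale(p["m"], p["s"])
                p["mu_log"], p["sigma_log"] = mu, sig
            elif "m" not in p:
                p["m"], p["s"] = lognormal_logscale_to_arithmetic(p["mu_log"], p["sigma_log"])
            p.setdefault("tau", 0.0)
            if p["s"] <= 0 or p["sigma_log"] <= 0:
                raise InvalidInputError("shifted lognormal requires s > 0")
        elif self.family == "lognormal":
            if p["sigma_log"] <= 0:
                raise InvalidInputError("lognormal requires sigma_log > 0")
        elif self.family == "triangular":
            if not (p["a"] <= p["c"] <= p["b"] and p["a"] < p["b"]):
                raise InvalidInputError("triangular requires a <= c <= b and a < b")
        elif self.family == "normal":
            if p["sd"] <= 0:
                raise InvalidInputError("normal requires sd > 0")
        elif self.family == "gamma":
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise InvalidInputError("gamma requires shape, scale > 0")
        else:
            raise InvalidInputError(f"unknown family {self.family!r}")

    # -- scipy bridge -------------------------------------------------------
    def frozen(self):
        """The scipy.stats frozen distribution for this family/params."""
        p = self.params
        if self.family == "shifted_lognormal":
            return stats.lognorm(p["sigma_log"], loc=p["tau"], scale=math.exp(p["mu_log"]))
        if self.family == "lognormal":
            return stats.lognorm(p["sigma_log"], scale=math.exp(p["mu_log"]))
        if self.family == "triangular":
            a, c, b = p["a"], p["c"], p["b"]
            return stats.triang((c - a) / (b - a), loc=a, scale=b - a)
        if self.family == "normal":
            return stats.norm(p["mean"], p["sd"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        raise InvalidInputError(self.family)

    def cdf(self, x):
        return self.frozen().cdf(x)

    def pdf(self, x):
        return self.frozen().pdf(x)

    def ppf(self, u):
        return self.frozen().ppf(u)

    def mean(self) -> float:
        return float(self.frozen().mean())

    def sd(self) -> float:
        return float(self.frozen().std())

    @property
    def k_params(self) -> int:
        return {"shifted_lognormal": 3, "lognormal": 2, "triangular": 3,
                "normal": 2, "gamma": 2}[self.family]

    def describe(self) -> dict:
        out = {"family": self.family, "params": dict(self.params), "n": self.n,
               "log_likelihood": self.log_likelihood, "aic": self.aic}
        if self.gof:
            out["gof"] = dict(self.gof)
        return out


def shifted_lognormal(m: float, s: float, tau: float = 0.0) -> FittedDistribution:
    """Construct a shifted lognormal from arithmetic mean/sd and shift."""
    return FittedDistribution("shifted_lognormal", {"m": m, "s": s, "tau": tau})


def triangular(a: float, c: float, b: float) -> FittedDistribution:
    """Construct a triangular distribution from min/mode/max."""
    return FittedDistribution("triangular", {"a": a, "c": c, "b": b})


# ---------------------------------------------------------------------------
# Maximum-likelihood fits
# ---------------------------------------------------------------------------

def _check_fit_data(values: Sequence[float], n_min: int) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < n_min:
        raise InvalidInputError(f"need at least {n_min} one-dimensional values")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("values must be finite")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical; nothing to fit")
    return x


def _finish(dist: FittedDistribution, x: np.ndarray) -> FittedDistribution:
    ll = float(np.sum(np.log(np.clip(dist.pdf(x), 1e-300, None))))
    dist.n = len(x)
    dist.log_likelihood = ll
    dist.aic = 2 * dist.k_params - 2 * ll
    return dist


def _shift_profile_loglik(x: np.ndarray, tau: float) -> float:
    """Profile log-likelihood of the 3-parameter lognormal at fixed shift."""
    z = np.log(x - tau)
    mu = z.mean()
    sigma = z.std()  # MLE (ddof=0)
    if sigma <= 0:
        return -np.inf
    return float(-len(x) * (math.log(sigma) + 0.5 * math.log(2 * math.pi) + 0.5) - z.sum())


def fit_shifted_lognormal(values: Sequence[float]) -> FittedDistribution:
    """Maximum-likelihood fit of the three-parameter (shifted) lognormal.

    The shift is ill-conditioned in joint MLE, so it is profiled: given tau,
    the conditional MLEs are mu = mean(ln(x - tau)), sigma = sd(ln(x - tau));
    the profile likelihood is scanned on a grid over
    (-s_sample, min(x) - eps), eps = 1e-6 x data range, then refined by
    bounded one-dimensional optimisation.  If the profile is flat a
    moment-matching fallback is used (with a logged warning).
    """
    x = _check_fit_data(values, 10)
    s_sample = float(np.std(x, ddof=1))
    eps = 1e-6 * float(np.ptp(x))
    lo, hi = -s_sample, float(np.min(x)) - eps
    if not lo < hi:
        raise FitFailureError("empty shift search interval", {"lo": lo, "hi": hi})
    grid = np.linspace(lo, hi, 101)
    ll_grid = np.array([_shift_profile_loglik(x, t) for t in grid])
    if not np.any(np.isfinite(ll_grid)):
        raise FitFailureError("profile likelihood undefined on the whole grid")
    i = int(np.nanargmax(ll_grid))
    span = np.nanmax(ll_grid) - np.nanmin(ll_grid[np.isfinite(ll_grid)])
    if span < 1e-8:
        logger.warning("flat shift profile; falling back to moment matching")
        tau = 0.0
        m, s = float(np.mean(x)), s_sample
        mu, sig = lognormal_arithmetic_to_logscale(m, s)
    else:
        bl = grid[max(i - 1, 0)]
        bh = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -_shift_profile_loglik(x, t), bounds=(bl, bh), method="bounded"
        )
        tau = float(res.x) if res.success else float(grid[i])
        z = np.log(x - tau)
        mu, sig = float(z.mean()), float(z.std())
        m, s = lognormal_logscale_to_arithmetic(mu, sig)
    dist = FittedDistribution(
        "shifted_lognormal",
        {"m": m, "s": s, "tau": tau, "mu_log": mu, "sigma_log": sig},
    )
    return _finish(dist, x)


def fit_lognormal(values: Sequence[float]) -> FittedDistribution:
    """Two-parameter lognormal MLE (shift fixed at zero)."""
    x = _check_fit_data(values, 2)
    if np.any(x <= 0):
        raise InvalidInputError("lognormal fit requires strictly positive values")
    z = np.log(x)
    dist = FittedDistribution("lognormal", {"mu_log": float(z.mean()), "sigma_log": float(z.std())})
    return _finish(dist, x)


def fit_normal(values: Sequence[float]) -> FittedDistribution:
    x = _check_fit_data(values, 2)
    dist = FittedDistribution("normal", {"mean": float(x.mean()), "sd": float(x.std())})
    return _finish(dist, x)


def fit_gamma(values: Sequence[float]) -> FittedDistribution:
    x = _check_fit_data(values, 2)
    if np.any(x <= 0):
        raise InvalidInputError("gamma fit requires strictly positive values")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    dist = FittedDistribution("gamma", {"shape": float(shape), "scale": float(scale)})
    return _finish(dist, x)


def fit_triangular(values: Sequence[float], exact_extremes: bool = False) -> FittedDistribution:
    """Fit a triangular distribution: endpoints from the extremes, mode by MLE.

    Raw sample extremes bias a and b inward, so by default they are expanded
    by range/(n-1) on each side; ``exact_extremes=True`` pins them to the
    observed min/max.  The mode c is then the bounded one-dimensional MLE.
    """
    x = _check_fit_data(values, 3)
    n = len(x)
    r = float(np.ptp(x))
    if exact_extremes:
        a, b = float(np.min(x)), float(np.max(x))
    else:
        a = float(np.min(x)) - r / (n - 1)
        b = float(np.max(x)) + r / (n - 1)

    def nll(c: float) -> float:
        fr = stats.triang((c - a) / (b - a), loc=a, scale=b - a)
        return -float(np.sum(np.log(np.clip(fr.pdf(x), 1e-300, None))))

    res = optimize.minimize_scalar(nll, bounds=(a, b), method="bounded")
    c = float(res.x)
    dist = FittedDistribution("triangular", {"a": a, "c": c, "b": b})
    return _finish(dist, x)


# ---------------------------------------------------------------------------
# Goodness of fit and ranking
# ---------------------------------------------------------------------------

def gof_suite(values: Sequence[float], dist: FittedDistribution) -> dict[str, float]:
    """KS, Anderson-Darling and chi-square statistics of ``values`` vs ``dist``.

    AD uses the standard A^2 form on probability-integral-transformed
    values; chi-square uses k = max(5, ceil(n/50)) equal-probability bins
    under the fitted CDF.  All statistics are order-invariant and >= 0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 10:
        raise InvalidInputError("need n >= 10 for the goodness-of-fit suite")
    u = np.clip(dist.cdf(x), 1e-12, 1 - 1e-12)
    # Kolmogorov-Smirnov
    i = np.arange(1, n + 1)
    ks = float(max(np.max(i / n - u), np.max(u - (i - 1) / n)))
    # Anderson-Darling
    ad = float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))))
    # chi-square over equal-probability bins
    k = max(5, math.ceil(n / 50))
    edges = dist.ppf(np.linspace(0, 1, k + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(x, bins=edges)
    expected = np.full(k, n / k)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    result = {"ks_statistic": ks, "ad_statistic": ad,
              "chi2_statistic": chi2, "chi2_bins": k}
    dist.gof.update(result)
    return result


def rank_fits_by_aic(fits: Sequence[FittedDistribution]) -> list[FittedDistribution]:
    """Order candidate fits by ascending AIC, ties broken by family name."""
    if not fits:
        raise InvalidInputError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise InvalidInputError(f"fits computed on differing sample sizes: {sorted(ns)}")
    if any(f.aic is None for f in fits):
        raise InvalidInputError("every fit must carry an AIC")
    return sorted(fits, key=lambda f: (f.aic, f.family))


_FITTERS: dict[str, Callable] = {
    "normal": fit_normal,
    "lognormal": fit_lognormal,
    "shifted_lognormal": fit_shifted_lognormal,
    "gamma": fit_gamma,
    "triangular": fit_triangular,
}

DEFAULT_FAMILIES = ("normal", "lognormal", "shifted_lognormal", "gamma", "triangular")


def fit_candidates(
    values: Sequence[float], families: Sequence[str] = DEFAULT_FAMILIES
) -> list[FittedDistribution]:
    """Fit every candidate family, attach GOF statistics, rank by AIC.

    Families whose support cannot accommodate the data (e.g. lognormal with
    non-positive values) are skipped with a logged note.
    """
    fits = []
    for fam in families:
        if fam not in _FITTERS:
            raise InvalidInputError(f"unknown family {fam!r}")
        try:
            fit = _FITTERS[fam](values)
        except (InvalidInputError, DegenerateDataError, FitFailureError) as exc:
            logger.info("skipping family %s: %s", fam, exc)
            continue
        gof_suite(values, fit)
        fits.append(fit)
    if not fits:
        raise FitFailureError("no candidate family could be fitted")
    return rank_fits_by_aic(fits)


def cdf_overlay(values: Sequence[float], dist: FittedDistribution) -> "np.ndarray":
    """(x, F_emp, F_fit) columns for an empirical-vs-fitted CDF overlay plot."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    f_emp = np.arange(1, n + 1) / n
    return np.column_stack([x, f_emp, dist.cdf(x)])
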