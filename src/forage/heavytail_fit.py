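"""Likelihood fitting and comparison of movement-length models.

Four candidate models for the distribution of movement lengths l >= a:

* ``PL``   unbounded power law,   f(l) = (mu-1) a^(mu-1) l^-mu
* ``PLB``  bounded power law,     f(l) = C(mu, a, b) l^-mu on [a, b]
* ``Exp``  shifted exponential,   f(l) = lam exp(-lam (l-a))
* ``ExpB`` truncated exponential, f(l) = lam exp(-lam l) / (e^-lam a - e^-lam b)

PL has the closed-form MLE mu = 1 + n / sum(ln(l_i/a)); Exp has
lam = 1 / (mean(l) - a).  The bounded models are maximized numerically; the
bounded power law is defined for any real exponent (mu = 1 handled by its
logarithmic limit), which matters because empirical fits can land at mu <= 1.
Models are compared with AIC, Akaike weights, and evidence ratios; absolute
fit is assessed with a G-test on equal-probability bins of the fitted model;
a log-binned least-squares slope is provided as the traditional reference
method for power-law exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distributions import (
    ParetoTail,
    ShiftedExponential,
    TruncatedExponential,
    TruncatedPareto,
)
from .errors import FitError, InsufficientDataError
from .trajectory import MovementSample

SampleLike = Union[MovementSample, Sequence[float], np.ndarray]

MODELS = ("PL", "PLB", "Exp", "ExpB")


def _lengths(sample: SampleLike) -> np.ndarray:
    if isinstance(sample, MovementSample):
        x = sample.lengths
    else:
        x = np.asarray(sample, dtype=float).ravel()
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 lengths to fit")
    return x


@dataclass
class FitResult:
    """A fitted movement-length model."""

    model: str
    params: dict
    a: float
    b: Optional[float]
    logL: float
    k: int
    n: int
    dist: object = field(repr=False, default=None)

    @property
    def AIC(self) -> float:
        return -2.0 * self.logL + 2.0 * self.k


@dataclass
class ModelComparison:
    """Akaike comparison of several fits on the same sample."""

    fits: dict
    delta_aic: dict
    weights: dict
    evidence_ratios: dict
    best_model: str
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            rows.append(
                {
                    "model": name,
                    **{f"param_{k}": v for k, v in fit.params.items()},
                    "logL": fit.logL,
                    "AIC": fit.AIC,
                    "delta_AIC": self.delta_aic[name],
                    "akaike_weight": self.weights[name],
                    "evidence_ratio": self.evidence_ratios[name],
                    "best": name == self.best_model,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class GofResult:
    """G-test (likelihood-ratio) goodness of fit on binned data."""

    G: float
    df: int
    p_value: float
    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray


@dataclass
class LogBinFit:
    """Width-normalized geometric histogram with a log-log OLS slope."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    slope: float
    stderr: float
    intercept: float


# ------------------------------------------------------------ model fitting


def fit_powerlaw(sample: SampleLike, a: Optional[float] = None,
                 count_bounds_as_params: bool = False) -> FitResult:
    """Closed-form MLE of the unbounded power law: mu = 1 + n/sum(ln(x/a))."""
    x = _lengths(sample)
    a = float(np.min(x)) if a is None else float(a)
    if a <= 0:
        raise ValueError("lower cutoff a must be positive")
    if (x < a - 1e-12).any():
        raise ValueError("sample contains lengths below the lower cutoff a")
    n = len(x)
    slog = float(np.sum(np.log(np.maximum(x, a) / a)))
    if slog == 0.0:
        raise FitError("all lengths equal the cutoff: power-law MLE diverges")
    mu = 1.0 + n / slog
    logL = n * np.log(mu - 1.0) + n * (mu - 1.0) * np.log(a) - mu * float(
        np.sum(np.log(x))
    )
    k = 2 if count_bounds_as_params else 1
    return FitResult("PL", {"mu": mu}, a, None, float(logL), k, n,
                     dist=ParetoTail(mu, a))


def _plb_loglik(mu: float, n: int, sum_log: float, a: float, b: float) -> float:
    if abs(mu - 1.0) < 1e-9:
        log_norm = -np.log(np.log(b / a))
    else:
        log_norm = np.log(abs(mu - 1.0)) - np.log(
            abs(a ** (1.0 - mu) - b ** (1.0 - mu))
        )
    return n * log_norm - mu * sum_log


def fit_powerlaw_bounded(sample: SampleLike, a: Optional[float] = None,
                         b: Optional[float] = None,
                         count_bounds_as_params: bool = False,
                         mu_range: tuple[float, float] = (-10.0, 10.0)) -> FitResult:
    """Numerical MLE of the power law truncated to [a, b].

    The exponent is free over ``mu_range`` (the truncated density is
    normalizable for any mu, with the mu = 1 logarithmic limit handled
    explicitly); by default the bounds are the sample extremes and are not
    counted as free parameters (``count_bounds_as_params`` flips that).
    """
    x = _lengths(sample)
    a = float(np.min(x)) if a is None else float(a)
    b = float(np.max(x)) if b is None else float(b)
    if b <= a:
        raise ValueError(f"require a < b, got a={a}, b={b}")
    if (x < a - 1e-12).any() or (x > b + 1e-12).any():
        raise ValueError("sample outside [a, b]")
    n = len(x)
    sum_log = float(np.sum(np.log(x)))
    res = optimize.minimize_scalar(
        lambda mu: -_plb_loglik(mu, n, sum_log, a, b),
        bounds=mu_range,
        method="bounded",
        options={"xatol": 1e-12},
    )
    mu = float(res.x)
    k = 3 if count_bounds_as_params else 1
    return FitResult("PLB", {"mu": mu}, a, b, float(-res.fun), k, n,
                     dist=TruncatedPareto(mu, a, b))


def fit_exponential(sample: SampleLike, a: Optional[float] = None,
                    count_bounds_as_params: bool = False) -> FitResult:
    """Closed-form MLE of the shifted exponential: lam = 1/(mean(x) - a)."""
    x = _lengths(sample)
    a = float(np.min(x)) if a is None else float(a)
    if (x < a - 1e-12).any():
        raise ValueError("sample contains lengths below the lower cutoff a")
    n = len(x)
    excess = float(np.mean(x) - a)
    if excess <= 0.0:
        raise FitError("mean equals the cutoff: exponential MLE diverges")
    lam = 1.0 / excess
    logL = n * np.log(lam) - lam * float(np.sum(x - a))
    k = 2 if count_bounds_as_params else 1
    return FitResult("Exp", {"lam": lam}, a, None, float(logL), k, n,
                     dist=ShiftedExponential(lam, a))


def fit_exponential_bounded(sample: SampleLike, a: Optional[float] = None,
                            b: Optional[float] = None,
                            count_bounds_as_params: bool = False) -> FitResult:
    """Numerical MLE of the exponential truncated to [a, b]."""
    x = _lengths(sample)
    a = float(np.min(x)) if a is None else float(a)
    b = float(np.max(x)) if b is None else float(b)
    if b <= a:
        raise ValueError(f"require a < b, got a={a}, b={b}")
    if (x < a - 1e-12).any() or (x > b + 1e-12).any():
        raise ValueError("sample outside [a, b]")
    n = len(x)
    mean_excess = float(np.mean(x) - a)

    def nll(lam: float) -> float:
        d = TruncatedExponential(lam, a, b)
        return -(float(np.sum(d.logpdf(x))))

    span = b - a
    # bracket scales: positive rates up to far beyond the unbounded MLE
    # 1/mean_excess, negative (increasing-density) rates on the span scale
    hi = 1e3 / mean_excess if mean_excess > 0 else 1.0 / span
    lo = -1e2 / span
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * min(mean_excess, span)}
    )
    lam = float(res.x)
    k = 3 if count_bounds_as_params else 1
    return FitResult("ExpB", {"lam": lam}, a, b, float(-res.fun), k, n,
                     dist=TruncatedExponential(lam, a, b))


def fit_all(sample: SampleLike, a: Optional[float] = None,
            b: Optional[float] = None,
            count_bounds_as_params: bool = False) -> dict:
    """Fit all four candidate models with shared cutoffs."""
    return {
        "PL": fit_powerlaw(sample, a, count_bounds_as_params),
        "PLB": fit_powerlaw_bounded(sample, a, b, count_bounds_as_params),
        "Exp": fit_exponential(sample, a, count_bounds_as_params),
        "ExpB": fit_exponential_bounded(sample, a, b, count_bounds_as_params),
    }


# ------------------------------------------------------------ model choice


def compare_models(fits: Union[dict, Sequence[FitResult]]) -> ModelComparison:
    """AIC differences, Akaike weights, and evidence ratios.

    The best model's evidence ratio is 1.0; every other model's ratio is the
    best weight divided by its weight (>= 1, exp(delta_AIC/2) in closed form).
    """
    fit_list = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if len(fit_list) < 2:
        raise ValueError("need at least 2 fits to compare")
    ns = {f.n for f in fit_list}
    if len(ns) != 1:
        raise ValueError(f"fits on different sample sizes: {sorted(ns)}")
    aic = np.array([f.AIC for f in fit_list])
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    best_i = int(np.argmin(aic))
    with np.errstate(divide="ignore"):
        ratios = np.where(w > 0, w[best_i] / np.maximum(w, 1e-300), np.inf)
    names = [f.model for f in fit_list]
    return ModelComparison(
        fits=dict(zip(names, fit_list)),
        delta_aic=dict(zip(names, delta)),
        weights=dict(zip(names, w)),
        evidence_ratios=dict(zip(names, ratios)),
        best_model=names[best_i],
        n=fit_list[0].n,
    )


# --------------------------------------------------------- goodness of fit


def g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """G = 2 sum O_i ln(O_i/E_i); empty observed cells contribute zero."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    mask = o > 0
    return float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))


def g_test(sample: SampleLike, fit: FitResult, n_bins: int = 20) -> GofResult:
    """Likelihood-ratio goodness of fit of a fitted model.

    Bins are equal-probability quantile bins of the fitted distribution,
    merged greedily until every expected count is at least 5.  Degrees of
    freedom are ``bins - 1 - k`` with ``k`` the fitted parameter count.
    """
    x = _lengths(sample)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    n = len(x)
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.asarray(fit.dist.ppf(qs), dtype=float)
    edges[0] = min(edges[0], float(x.min())) - 1e-9
    edges[-1] = max(edges[-1], float(x.max())) + 1e-9
    probs = np.full(n_bins, 1.0 / n_bins)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    observed = np.bincount(idx, minlength=n_bins).astype(float)
    expected = n * probs
    edges = list(edges)
    observed = list(observed)
    expected = list(expected)
    while len(expected) > 1 and min(expected) < 5.0:
        i = int(np.argmin(expected))
        j = i + 1 if i == 0 else i - 1
        if 0 < i < len(expected) - 1 and expected[i + 1] < expected[i - 1]:
            j = i + 1
        lo, hi = sorted((i, j))
        observed[lo] += observed.pop(hi)
        expected[lo] += expected.pop(hi)
        edges.pop(hi)
    observed = np.asarray(observed)
    expected = np.asarray(expected)
    df = len(expected) - 1 - fit.k
    if df <= 0:
        raise FitError("goodness-of-fit test undefined: non-positive df after merging")
    G = g_statistic(observed, expected)
    p = float(stats.chi2.sf(G, df))
    return GofResult(G, df, p, np.asarray(edges), observed, expected)


# ------------------------------------------------------- logarithmic binning


def log_bin_slope(sample: SampleLike, base: float = 2.0) -> LogBinFit:
    """Power-law slope from a geometrically binned, width-normalized histogram.

    Counts in bins [a base^k, a base^(k+1)) are divided by bin width; the
    slope is the OLS regression of log10(normalized frequency) on
    log10(geometric bin center) over non-empty bins.  A pure power law l^-mu
    yields slope -mu.
    """
    x = _lengths(sample)
    if base <= 1.0:
        raise ValueError("bin ratio base must exceed 1")
    a = float(np.min(x))
    xmax = float(np.max(x))
    n_edges = int(np.ceil(np.log(xmax / a) / np.log(base))) + 1
    edges = a * base ** np.arange(max(n_edges, 1) + 1)
    edges[-1] = max(edges[-1], xmax * (1.0 + 1e-12))
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    nonempty = counts > 0
    if nonempty.sum() < 3:
        raise InsufficientDataError(
            f"log-binned sample spans only {int(nonempty.sum())} non-empty bins; need 3"
        )
    freq = counts[nonempty] / (widths[nonempty] * len(x))
    centers = np.sqrt(edges[:-1] * edges[1:])[nonempty]
    reg = stats.linregress(np.log10(centers), np.log10(freq))
    return LogBinFit(edges, freq, float(reg.slope), float(reg.stderr),
                     float(reg.intercept))
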