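"""Movement-length distributions with stable log-densities and inverse CDFs.

Four families are used throughout: the unbounded Pareto tail (power law on
[a, inf)), the truncated Pareto (power law on [a, b], normalizable for any
exponent mu including mu <= 1), the shifted exponential on [a, inf), and the
truncated exponential on [a, b].  All expose ``logpdf``, ``pdf``, ``cdf``,
``ppf`` and ``rvs`` so they can serve both as samplers and as fitted models in
goodness-of-fit binning.
"""

from __future__ import annotations

import numpy as np

_MU_ONE_TOL = 1e-9
_LAM_ZERO_TOL = 1e-12


def _log1mexp(s):
    """log|1 - exp(-s)| evaluated stably for any real s != 0."""
    s = np.asarray(s, dtype=float)
    out = np.where(s < -500.0, -s, np.log(np.abs(-np.expm1(-np.clip(s, -500.0, None)))))
    return out


class ParetoTail:
    """Power law l^-mu on [a, inf); requires mu > 1 for normalizability."""

    def __init__(self, mu: float, a: float):
        if a <= 0:
            raise ValueError("lower bound a must be positive")
        if mu <= 1:
            raise ValueError("unbounded power law requires mu > 1")
        self.mu, self.a = float(mu), float(a)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, -np.inf)
        ok = x >= self.a
        out[ok] = (
            np.log(self.mu - 1.0)
            + (self.mu - 1.0) * np.log(self.a)
            - self.mu * np.log(x[ok])
        )
        return out

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x < self.a, 0.0, 1.0 - (np.maximum(x, self.a) / self.a) ** (1.0 - self.mu))

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        return self.a * (1.0 - q) ** (1.0 / (1.0 - self.mu))

    def rvs(self, size, rng: np.random.Generator):
        return self.ppf(rng.uniform(size=size))


class TruncatedPareto:
    """Power law l^-mu restricted to [a, b]; defined for any real mu."""

    def __init__(self, mu: float, a: float, b: float):
        if a <= 0 or b <= a:
            raise ValueError("require 0 < a < b")
        self.mu, self.a, self.b = float(mu), float(a), float(b)

    @property
    def _log_norm(self) -> float:
        """log of the normalizing constant C with pdf = C * x^-mu."""
        mu, a, b = self.mu, self.a, self.b
        if abs(mu - 1.0) < _MU_ONE_TOL:
            return -np.log(np.log(b / a))
        return np.log(abs(mu - 1.0)) - np.log(abs(a ** (1.0 - mu) - b ** (1.0 - mu)))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, -np.inf)
        ok = (x >= self.a) & (x <= self.b)
        out[ok] = self._log_norm - self.mu * np.log(x[ok])
        return out

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.a, self.b)
        mu, a, b = self.mu, self.a, self.b
        if abs(mu - 1.0) < _MU_ONE_TOL:
            return np.log(x / a) / np.log(b / a)
        e = 1.0 - mu
        return (a**e - x**e) / (a**e - b**e)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        mu, a, b = self.mu, self.a, self.b
        if abs(mu - 1.0) < _MU_ONE_TOL:
            return a * (b / a) ** q
        e = 1.0 - mu
        return (a**e - q * (a**e - b**e)) ** (1.0 / e)

    def rvs(self, size, rng: np.random.Generator):
        return self.ppf(rng.uniform(size=size))


class ShiftedExponential:
    """Exponential with rate lam on [a, inf)."""

    def __init__(self, lam: float, a: float):
        if lam <= 0:
            raise ValueError("rate must be positive")
        self.lam, self.a = float(lam), float(a)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, -np.inf)
        ok = x >= self.a
        out[ok] = np.log(self.lam) - self.lam * (x[ok] - self.a)
        return out

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x < self.a, 0.0, -np.expm1(-self.lam * (np.maximum(x, self.a) - self.a)))

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        with np.errstate(divide="ignore"):  # ppf(1) = inf
            return self.a - np.log1p(-q) / self.lam

    def rvs(self, size, rng: np.random.Generator):
        return self.a + rng.exponential(1.0 / self.lam, size=size)


class TruncatedExponential:
    """Exponential with rate lam restricted to [a, b]; lam may be any real.

    lam -> 0 degenerates smoothly to the uniform distribution on [a, b];
    negative lam gives an increasing density (useful as a numerical limit).
    """

    def __init__(self, lam: float, a: float, b: float):
        if b <= a:
            raise ValueError("require a < b")
        self.lam, self.a, self.b = float(lam), float(a), float(b)

    @property
    def _span(self) -> float:
        return self.b - self.a

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, -np.inf)
        ok = (x >= self.a) & (x <= self.b)
        lam = self.lam
        if abs(lam) < _LAM_ZERO_TOL:
            out[ok] = -np.log(self._span)
            return out
        s = lam * self._span
        # log lam - lam (x-a) - log(1 - e^{-s}); signs of lam and (1-e^{-s}) match
        log_norm = -np.log(self._span) - _log_s_ratio(s)
        out[ok] = log_norm - lam * (x[ok] - self.a)
        return out

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.a, self.b)
        lam = self.lam
        if abs(lam) < _LAM_ZERO_TOL:
            return (x - self.a) / self._span
        return np.expm1(-lam * (x - self.a)) / np.expm1(-lam * self._span)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        lam = self.lam
        if abs(lam) < _LAM_ZERO_TOL:
            return self.a + q * self._span
        return self.a - np.log1p(q * np.expm1(-lam * self._span)) / lam

    def rvs(self, size, rng: np.random.Generator):
        return self.ppf(rng.uniform(size=size))


def _log_s_ratio(s: float) -> float:
    """log[(1 - e^-s)/s], the smooth truncation factor; -> 0 as s -> 0."""
    if abs(s) < 1e-8:
        return -s / 2.0 + s * s / 24.0
    if s < -500.0:
        return -s - np.log(-s)
    return float(np.log(-np.expm1(-s)) - np.log(s)) if s > 0 else float(
        np.log(np.expm1(-s) ) - np.log(-s)
    )
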