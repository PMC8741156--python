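"""Scalar distribution helpers used by the hierarchical model.

Fast, vectorized log-densities for the handful of families appearing in the
model (normal, truncated normal, gamma, uniform), plus draws. Written
directly (rather than through scipy.stats frozen objects) because they sit
in the sampler's inner loop; scipy.stats serves as the oracle in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ndtr

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def norm_logpdf(x, loc, scale):
    x = np.asarray(x, dtype=float)
    z = (x - loc) / scale
    return -0.5 * z * z - math.log(scale) - _LOG_SQRT_2PI


def truncnorm_logpdf(x, loc, scale, lo=-np.inf, hi=np.inf):
    """Normal(loc, scale) truncated to [lo, hi], normalization included.
    Broadcasts over x and loc."""
    x = np.asarray(x, dtype=float)
    loc = np.asarray(loc, dtype=float)
    za = ndtr((lo - loc) / scale) if np.isfinite(lo) else np.zeros_like(loc)
    zb = ndtr((hi - loc) / scale) if np.isfinite(hi) else np.ones_like(loc)
    mass = zb - za
    with np.errstate(divide="ignore"):
        out = norm_logpdf(x, loc, scale) - np.log(mass)
    return np.where((x >= lo) & (x <= hi) & (mass > 0), out, -np.inf)


def gamma_logpdf(x, shape, rate):
    """Gamma in shape/rate parameterization (Gamma(1,1) = Exponential(1))."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = shape * math.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x
    return np.where(x > 0, out, -np.inf)


def uniform_logpdf(x, lo, hi):
    x = np.asarray(x, dtype=float)
    return np.where((x >= lo) & (x <= hi), -math.log(hi - lo), -np.inf)


@dataclass(frozen=True)
class Dist:
    """A scalar prior distribution: family in {'normal','truncnorm','gamma',
    'uniform'} with its parameters (gamma is shape/rate; second argument of
    the normal families is a standard deviation)."""

    family: str
    args: tuple

    def logpdf(self, x):
        if self.family == "normal":
            return norm_logpdf(x, *self.args)
        if self.family == "truncnorm":
            return truncnorm_logpdf(x, *self.args)
        if self.family == "gamma":
            return gamma_logpdf(x, *self.args)
        if self.family == "uniform":
            return uniform_logpdf(x, *self.args)
        raise ValueError(f"unknown family {self.family!r}")

    def rvs(self, rng: np.random.Generator, size=None):
        if self.family == "normal":
            loc, sc = self.args
            return rng.normal(loc, sc, size)
        if self.family == "truncnorm":
            from scipy import stats

            loc, sc, lo, hi = self.args
            return stats.truncnorm.rvs(
                (lo - loc) / sc, (hi - loc) / sc, loc=loc, scale=sc, size=size, random_state=rng
            )
        if self.family == "gamma":
            shape, rate = self.args
            return rng.gamma(shape, 1.0 / rate, size)
        if self.family == "uniform":
            lo, hi = self.args
            return rng.uniform(lo, hi, size)
        raise ValueError(f"unknown family {self.family!r}")

    def at_zero(self) -> float:
        """Density (not log) at 0; used by Savage-Dickey ratios."""
        return float(np.exp(self.logpdf(0.0)))
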