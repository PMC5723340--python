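"""Moment-standardized Fernandez–Steel skew-normal distribution.

The family takes a standard-normal base density :math:`f` and allocates mass
to either side of the mode :math:`M` through a shape parameter
:math:`\\gamma > 0`:

.. math::

    p(\\epsilon \\mid \\gamma) = \\frac{2}{\\gamma + 1/\\gamma}
        \\left\\{ f(\\epsilon/\\gamma)\\, I_{[M,\\infty)}(\\epsilon)
        + f(\\gamma\\epsilon)\\, I_{(-\\infty,M)}(\\epsilon) \\right\\},

with :math:`M = 0` for the raw form.  :math:`\\gamma = 1` recovers the
normal; :math:`\\gamma > 1` shifts mass above the mode (right skew) and the
density for :math:`1/\\gamma` is the mirror image of the one for
:math:`\\gamma`.

The public parameterization here is *moment-standardized*: ``SkewNormal(mean,
sd, shape)`` has true expectation ``mean`` and true standard deviation ``sd``
for every shape.  This is the parameterization implied by a fitting procedure
that pins the first two moments to the data and optimizes only the shape.
Internally the raw form above is shifted and scaled by its own moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "SkewNormal",
    "raw_moments",
    "density",
    "cdf",
    "quantile",
    "sample",
    "mode_of",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
_LOG_NORM_CONST = -0.5 * math.log(2.0 * math.pi)


def _validate_shape(shape: float) -> float:
    shape = float(shape)
    if not math.isfinite(shape) or shape <= 0.0:
        raise ValueError(f"shape must be finite and > 0, got {shape!r}")
    return shape


def raw_moments(shape: float) -> tuple[float, float]:
    """Mean and sd of the raw (mode-0, unit-base) skew density.

    For a standard-normal base the absolute moments of the half-normal give

    ``E[eps]   = sqrt(2/pi) * (gamma - 1/gamma)``
    ``E[eps^2] = (gamma^3 + gamma^-3) / (gamma + 1/gamma)``

    These are the constants used to affinely standardize the family so that
    the declared mean/sd are the true moments.
    """
    g = _validate_shape(shape)
    raw_mean = _SQRT_2_OVER_PI * (g - 1.0 / g)
    second = (g**3 + g**-3) / (g + 1.0 / g)
    raw_var = second - raw_mean**2
    return raw_mean, math.sqrt(raw_var)


@dataclass(frozen=True)
class SkewNormal:
    """Skew-normal distribution with true-moment parameterization.

    Parameters
    ----------
    mean : float
        True expectation, in units of the elicited quantity.
    sd : float
        True standard deviation, > 0.
    shape : float
        Skewness parameter gamma > 0; 1 is symmetric (exactly normal),
        > 1 right-skewed, < 1 left-skewed.
    """

    mean: float
    sd: float
    shape: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mean", "sd", "shape"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd!r}")
        _validate_shape(self.shape)

    # raw_mean + raw_sd * (x - mean)/sd maps x to the raw epsilon scale
    @property
    def _std(self) -> tuple[float, float]:
        return raw_moments(self.shape)

    def _to_raw(self, x):
        r_mean, r_sd = self._std
        return r_mean + r_sd * (np.asarray(x, dtype=float) - self.mean) / self.sd

    def pdf(self, x):
        return density(x, self)

    def logpdf(self, x):
        return log_density(x, self)

    def cdf(self, x):
        return cdf(x, self)

    def quantile(self, p):
        return quantile(p, self)

    def sample(self, n: int, seed) -> np.ndarray:
        return sample(self, n, seed)

    @property
    def mode(self) -> float:
        return mode_of(self)

    @property
    def variance(self) -> float:
        return self.sd**2


def _raw_logpdf(eps: np.ndarray, g: float) -> np.ndarray:
    """Log of the raw mass-allocation density at mode 0 with unit-normal base."""
    eps = np.asarray(eps, dtype=float)
    log_c = math.log(2.0) - math.log(g + 1.0 / g)
    # branch argument: eps/gamma above the mode, gamma*eps below; the two
    # branches agree at eps = 0 so either assignment of the tie is continuous
    z = np.where(eps >= 0.0, eps / g, eps * g)
    with np.errstate(over="ignore"):  # z*z -> inf maps to logpdf -inf
        return log_c + _LOG_NORM_CONST - 0.5 * z * z


def log_density(x, dist: SkewNormal):
    """Log-density of ``dist`` at ``x`` (vectorized)."""
    r_mean, r_sd = dist._std
    eps = dist._to_raw(x)
    out = _raw_logpdf(eps, dist.shape) + math.log(r_sd) - math.log(dist.sd)
    return out if np.ndim(x) else float(out)


def density(x, dist: SkewNormal):
    """Density of ``dist`` at ``x``; proper in x (Jacobian included)."""
    out = np.exp(log_density(np.asarray(x, dtype=float), dist))
    return out if np.ndim(x) else float(out)


def _raw_cdf(eps: np.ndarray, g: float) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    g2 = g * g
    below = 2.0 * ndtr(g * eps) / (1.0 + g2)
    above = 1.0 / (1.0 + g2) + (2.0 * g2 / (1.0 + g2)) * (ndtr(eps / g) - 0.5)
    return np.where(eps < 0.0, below, above)


def cdf(x, dist: SkewNormal):
    """Cumulative probability P(X <= x)."""
    out = _raw_cdf(dist._to_raw(x), dist.shape)
    return out if np.ndim(x) else float(out)


def _raw_quantile(p: np.ndarray, g: float) -> np.ndarray:
    """Closed-form inverse of the piecewise raw CDF."""
    p = np.asarray(p, dtype=float)
    g2 = g * g
    split = 1.0 / (1.0 + g2)  # mass below the mode
    with np.errstate(invalid="ignore"):
        below = ndtri(np.clip(p * (1.0 + g2) / 2.0, 0.0, 1.0)) / g
        above = g * ndtri(np.clip(0.5 + (p - split) * (1.0 + g2) / (2.0 * g2), 0.0, 1.0))
    return np.where(p < split, below, above)


def quantile(p, dist: SkewNormal):
    """Quantile function (inverse CDF); strictly increasing on (0, 1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr >= 1.0):
        raise ValueError("quantile requires 0 < p < 1")
    r_mean, r_sd = dist._std
    eps = _raw_quantile(p_arr, dist.shape)
    out = dist.mean + dist.sd * (eps - r_mean) / r_sd
    return out if np.ndim(p) else float(out)


def sample(dist: SkewNormal, n: int, seed) -> np.ndarray:
    """Draw ``n`` reproducible values by inverse-CDF on seeded uniforms."""
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    r_mean, r_sd = raw_moments(dist.shape)
    eps = _raw_quantile(u, dist.shape)
    return dist.mean + dist.sd * (eps - r_mean) / r_sd


def mode_of(dist: SkewNormal) -> float:
    """Location of the density maximum (the mode M of the raw form, mapped back).

    Equals the mean at shape 1; lies below the mean for shape > 1 because the
    standardization shift ``-sd * raw_mean / raw_sd`` is then negative.
    """
    r_mean, r_sd = dist._std
    return dist.mean - dist.sd * r_mean / r_sd
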