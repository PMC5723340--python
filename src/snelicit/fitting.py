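"""Maximum-likelihood fitting of elicited skew-normal distributions.

Two estimation problems arise in the elicitation pipeline:

* **Shape-only fit** (step 2): the mean and standard deviation are pinned to
  the sample moments of the chip value vector and only the shape gamma is
  optimized by maximum likelihood.
* **Bounds fit** (steps 3-4): the expert supplies a location estimate mu0 and
  reasonable lower/upper bounds; a weighted sample (mu0 repeated 100 times,
  each bound 10 times) is built, the mean is constrained to mu0 exactly, and
  scale and shape are jointly optimized.

Both are exposed as scikit-learn estimators (``ShapeMLE``,
``BoundsPriorMLE``) so they compose with pipelines and model selection; the
module-level functions ``fit_shape`` and ``fit_from_bounds`` are thin
wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator

from .skewnorm import SkewNormal, log_density

__all__ = [
    "BoundsElicitation",
    "ShapeMLE",
    "BoundsPriorMLE",
    "log_likelihood",
    "fit_shape",
    "build_bounds_sample",
    "fit_from_bounds",
    "LOG_SHAPE_BOUNDS",
]

# search space for gamma: log gamma in [log 0.01, log 100]
LOG_SHAPE_BOUNDS = (math.log(0.01), math.log(100.0))
_NEG_INF = float("-inf")


def log_likelihood(values, dist: SkewNormal) -> float:
    """Sum of log densities of ``values`` under ``dist``.

    Returns ``-inf`` if any point has zero density (underflow), as an
    explicit flag rather than an exception.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    ll = log_density(values, dist)
    total = float(np.sum(ll))
    return total if np.isfinite(total) else _NEG_INF


@dataclass(frozen=True)
class BoundsElicitation:
    """A location estimate with its reasonable lower and upper bounds.

    The weighted-sample construction repeats mu0 ``n_center`` times and each
    bound ``n_bound`` times (defaults 100 and 10, giving the 120-value
    sample).
    """

    mu0: float
    lower: float
    upper: float
    n_center: int = 100
    n_bound: int = 10

    def __post_init__(self) -> None:
        for name in ("mu0", "lower", "upper"):
            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if not (self.lower < self.mu0 < self.upper):
            raise ValueError(
                "bounds must bracket the estimate: require "
                f"lower < mu0 < upper, got {self.lower} < {self.mu0} "
                f"< {self.upper}"
            )
        if self.n_center < 1 or self.n_bound < 1:
            raise ValueError("n_center and n_bound must be >= 1")


def build_bounds_sample(e: BoundsElicitation) -> np.ndarray:
    """Deterministic weighted sample: centers, then lowers, then uppers."""
    return np.concatenate(
        [
            np.full(e.n_center, float(e.mu0)),
            np.full(e.n_bound, float(e.lower)),
            np.full(e.n_bound, float(e.upper)),
        ]
    )


class ShapeMLE(BaseEstimator):
    """Skew-normal fit with moments pinned to the sample (shape-only MLE).

    The fitted mean and sd equal the sample mean and sd (ddof=1) exactly;
    the shape maximizes the log-likelihood over
    ``log gamma in [log 0.01, log 100]`` with a bounded scalar minimizer.

    Attributes
    ----------
    mean_ : float
        Sample mean of the training values.
    sd_ : float
        Sample standard deviation (n-1 denominator).
    shape_ : float
        Maximum-likelihood shape at the pinned moments.
    dist_ : SkewNormal
        The fitted distribution.
    log_likelihood_ : float
        Log-likelihood of the training values at the fit.
    """

    def __init__(self, xtol: float = 1e-8):
        self.xtol = xtol

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        if values.size < 2:
            raise ValueError("need at least 2 values to fit")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1))
        if sd == 0.0:
            raise ValueError(
                "zero sample variance (all values identical, e.g. every "
                "chip in one column); cannot fit a distribution"
            )

        def nll(log_g: float) -> float:
            d = SkewNormal(mean, sd, math.exp(log_g))
            return -log_likelihood(values, d)

        res = minimize_scalar(
            nll,
            bounds=LOG_SHAPE_BOUNDS,
            method="bounded",
            options={"xatol": self.xtol},
        )
        self.mean_ = mean
        self.sd_ = sd
        self.shape_ = float(math.exp(res.x))
        self.dist_ = SkewNormal(mean, sd, self.shape_)
        self.log_likelihood_ = -float(res.fun)
        return self

    def score(self, X, y=None) -> float:
        """Log-likelihood of ``X`` under the fitted distribution."""
        return log_likelihood(np.asarray(X, dtype=float).ravel(), self.dist_)


class BoundsPriorMLE(BaseEstimator):
    """Mean-constrained skew-normal fit to a bounds-weighted sample.

    ``fit`` takes a :class:`BoundsElicitation` (or an (mu0, lower, upper)
    triple), builds the weighted sample, and maximizes the log-likelihood
    over ``(log sigma, log gamma)`` with the distribution mean held exactly
    at mu0.  Symmetric bounds therefore recover shape ~ 1; a longer upper
    tail pushes the fitted shape above 1.

    Attributes
    ----------
    mean_ : float
        Equal to mu0 by construction.
    sd_, shape_ : float
        Jointly optimized scale and shape.
    dist_ : SkewNormal
    log_likelihood_ : float
    """

    def __init__(self, tol: float = 1e-8):
        self.tol = tol

    def fit(self, X, y=None):
        e = X if isinstance(X, BoundsElicitation) else BoundsElicitation(*X)
        values = build_bounds_sample(e)
        mu0 = float(e.mu0)
        half_range = max(e.upper - mu0, mu0 - e.lower)
        sd0 = float(np.std(values, ddof=1))

        def nll(params) -> float:
            log_sd, log_g = params
            d = SkewNormal(mu0, math.exp(log_sd), math.exp(log_g))
            ll = log_likelihood(values, d)
            return -ll if np.isfinite(ll) else 1e300

        # scale search bracket: well below the tightest plausible spread,
        # well above the full bound range
        lo = math.log(sd0) - 8.0
        hi = math.log(half_range) + 4.0
        best = None
        for g0 in (0.0, math.log(2.0), -math.log(2.0)):
            res = minimize(
                nll,
                x0=np.array([math.log(sd0), g0]),
                method="L-BFGS-B",
                bounds=[(lo, hi), LOG_SHAPE_BOUNDS],
                options={"ftol": self.tol, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        log_sd, log_g = best.x
        self.elicitation_ = e
        self.mean_ = mu0
        self.sd_ = float(math.exp(log_sd))
        self.shape_ = float(math.exp(log_g))
        self.dist_ = SkewNormal(mu0, self.sd_, self.shape_)
        self.log_likelihood_ = -float(best.fun)
        return self


def fit_shape(values) -> SkewNormal:
    """Step-2 fit: moments from the value vector, shape by MLE."""
    return ShapeMLE().fit(values).dist_


def fit_from_bounds(e: BoundsElicitation) -> SkewNormal:
    """Steps 3-4 fit: mean constrained to mu0, (sd, shape) by joint MLE."""
    return BoundsPriorMLE().fit(e).dist_
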