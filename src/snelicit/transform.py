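"""Linear scale transformation for harmonizing expert panels.

Experts may reason on different scales — per product, per product type, per
region, or in totals.  A location estimate theta on one scale maps to
``theta* = a * theta + b`` on another; for a distribution the mean maps the
same way, the sd scales by ``|a|``, and (for the skew-normal family) the
shape is unchanged under a > 0 and reciprocated under a < 0 (mirror
identity).  Harmonizing a panel expresses every expert's estimate or
distribution on one common target scale so they become comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .skewnorm import SkewNormal

__all__ = [
    "ScaleSpec",
    "transform_estimate",
    "transform_distribution",
    "compose",
    "invert",
    "rescale",
    "harmonize_panel",
]


@dataclass(frozen=True)
class ScaleSpec:
    """An affine scale ``theta* = a * theta + b`` with a display label."""

    a: float
    b: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("a and b must be finite")
        if self.a == 0.0:
            raise ValueError("multiplier a must be nonzero")


IDENTITY = ScaleSpec(1.0, 0.0, "identity")


def transform_estimate(theta: float, spec: ScaleSpec) -> float:
    """Map a point estimate: a * theta + b."""
    return spec.a * float(theta) + spec.b


def transform_distribution(dist: SkewNormal, spec: ScaleSpec) -> SkewNormal:
    """Map a distribution through the affine scale.

    If X ~ SN(mean, sd^2, shape) then aX + b ~ SN(a*mean + b, (a*sd)^2,
    shape) for a > 0; a < 0 additionally mirrors the density, which in this
    family is the reciprocal shape.
    """
    shape = dist.shape if spec.a > 0 else 1.0 / dist.shape
    return SkewNormal(
        mean=spec.a * dist.mean + spec.b,
        sd=abs(spec.a) * dist.sd,
        shape=shape,
    )


def compose(first: ScaleSpec, second: ScaleSpec, label: str = "") -> ScaleSpec:
    """The single spec equal to applying ``first`` then ``second``."""
    return ScaleSpec(second.a * first.a, second.a * first.b + second.b, label)


def invert(spec: ScaleSpec, label: str = "") -> ScaleSpec:
    """The spec undoing ``spec``: (1/a, -b/a)."""
    return ScaleSpec(1.0 / spec.a, -spec.b / spec.a, label)


def rescale(spec_from: ScaleSpec, spec_to: ScaleSpec, label: str = "") -> ScaleSpec:
    """Spec converting values on ``spec_from``'s scale to ``spec_to``'s.

    Both specs are read as maps from a common base scale; the conversion is
    ``spec_to  o  spec_from^{-1}``.
    """
    return compose(invert(spec_from), spec_to, label)


def harmonize_panel(records, target: ScaleSpec) -> list[dict]:
    """Express each (value-or-distribution, scale) record on the target scale.

    Parameters
    ----------
    records : iterable of (estimate or SkewNormal, ScaleSpec)
        Each expert's elicited quantity with the scale it was stated on.
        Scales are affine maps from a common base scale (e.g. per-product),
        so a per-type estimate with ``ScaleSpec(9, 0)`` and a total with
        ``ScaleSpec(104, 0)`` are mutually convertible.
    target : ScaleSpec
        The common scale to express everything on.

    Returns
    -------
    list of dict
        Order-preserving; each entry keeps the original value and scale
        label for audit alongside the harmonized value.
    """
    out = []
    for value, spec in records:
        conv = rescale(spec, target)
        if isinstance(value, SkewNormal):
            harmonized = transform_distribution(value, conv)
        else:
            harmonized = transform_estimate(value, conv)
        out.append(
            {
                "original": value,
                "original_scale": spec.label,
                "value": harmonized,
                "scale": target.label,
            }
        )
    return out
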