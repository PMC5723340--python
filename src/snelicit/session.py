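"""Orchestration of the five elicitation steps, panels, and persistence.

An :class:`ElicitationRecord` is one expert's audit-trailed pass through the
pipeline: the chip grid (if used), the shape-only fit on the chip values,
the location estimate carried to the bounds stage, the bounds, and the
resulting prior on the common scale.  Adjust/re-fit feedback cycles are
recorded as appended iterations rather than hidden state: adjusting means
calling again with edited inputs.

The synthetic-expert generator draws chip placements from a known
skew-normal so every stage can be tested round-trip without human input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fitting import BoundsElicitation, fit_from_bounds, fit_shape
from .roulette import RouletteGrid, chips_to_values
from .skewnorm import SkewNormal, cdf, sample
from .transform import ScaleSpec, rescale, transform_estimate

__all__ = [
    "ElicitationRecord",
    "ExpertPanel",
    "run_five_steps",
    "simulate_expert",
    "save_session",
    "load_session",
    "SESSION_VERSION",
]

SESSION_VERSION = 1


@dataclass
class ElicitationRecord:
    """One expert's pass through the elicitation steps."""

    expert_id: str
    scale: ScaleSpec
    step1_grid: Optional[RouletteGrid] = None
    step2_fit: Optional[SkewNormal] = None
    step2_accepted: bool = False
    step3_bounds: Optional[BoundsElicitation] = None
    step4_prior: Optional[SkewNormal] = None
    iterations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.step4_prior is not None and self.step3_bounds is None:
            raise ValueError(
                "step4_prior requires step3_bounds (no bounds were recorded)"
            )


@dataclass
class ExpertPanel:
    """Records for experts d = 1..D on a common scale, plus an optional
    posterior summary in the same hyperparameter form."""

    records: list
    common_scale: ScaleSpec
    posterior: Optional[SkewNormal] = None

    def __post_init__(self) -> None:
        ids = [r.expert_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"expert ids must be unique, got {ids}")


def run_five_steps(
    *,
    expert_id: str = "expert",
    scale: ScaleSpec,
    target_scale: ScaleSpec,
    bounds: tuple[float, float],
    grid: Optional[RouletteGrid] = None,
    mu0: Optional[float] = None,
) -> ElicitationRecord:
    """Run the elicitation pipeline for one expert, deterministically.

    Two entry paths mirror how experts reason:

    * **grid path** — ``grid`` holds the chip placements (steps 1-2): the
      chip values are fitted with pinned moments and the fitted mean is the
      location estimate, stated on ``scale``.
    * **direct path** — ``mu0`` is the location estimate stated directly on
      ``scale`` (an expert may reason in totals without placing chips).

    The location is transformed onto ``target_scale``; ``bounds`` are the
    expert's reasonable lower/upper bounds for the estimate *on the target
    scale*, from which the prior's scale and shape are fitted with the mean
    constrained.

    Raises
    ------
    ValueError
        Propagated from the stage modules with a stage label prefixed.
    """
    if (grid is None) == (mu0 is None):
        raise ValueError("provide exactly one of grid (steps 1-2) or mu0")

    record = ElicitationRecord(expert_id=expert_id, scale=scale)
    if grid is not None:
        record.step1_grid = grid
        try:
            values = chips_to_values(grid)
            step2 = fit_shape(values)
        except ValueError as err:
            raise ValueError(f"steps 1-2 (chip fit): {err}") from err
        record.step2_fit = step2
        record.step2_accepted = True
        record.iterations.append(
            {
                "step": 2,
                "inputs": {"n_chips": grid.n_chips,
                           "lower": grid.lower, "upper": grid.upper},
                "fit": step2,
            }
        )
        location = step2.mean  # the mean is extracted from the fitted curve
    else:
        location = float(mu0)

    conv = rescale(scale, target_scale)
    mu0_target = transform_estimate(location, conv)

    try:
        elic = BoundsElicitation(mu0=mu0_target, lower=bounds[0], upper=bounds[1])
        prior = fit_from_bounds(elic)
    except ValueError as err:
        raise ValueError(f"steps 3-4 (bounds fit): {err}") from err
    record.step3_bounds = elic
    record.step4_prior = prior
    record.iterations.append(
        {
            "step": 4,
            "inputs": {"mu0": elic.mu0, "lower": elic.lower, "upper": elic.upper},
            "fit": prior,
        }
    )
    return record


def simulate_expert(
    true_dist: SkewNormal,
    n_chips: int,
    lower: float,
    upper: float,
    seed,
    n_columns: int = 600,
    n_rows: int = 300,
) -> RouletteGrid:
    """Synthetic chip placements drawn from a known distribution.

    ``n_chips`` seeded draws from ``true_dist`` are binned to the value axis
    on [lower, upper]; the first two chips are forced into the end columns
    (the range-defining chips an expert places first).  The stated range
    must cover at least 99% of the generating distribution's mass, as a
    coherent expert's bounds would.
    """
    n_chips = int(n_chips)
    if n_chips < 7:
        raise ValueError("n_chips must be >= 7 for a fit-ready grid")
    coverage = cdf(upper, true_dist) - cdf(lower, true_dist)
    if coverage < 0.99:
        raise ValueError(
            f"[lower, upper] covers only {coverage:.4f} of the generating "
            "distribution's mass; at least 0.99 is required"
        )
    draws = sample(true_dist, n_chips, seed)
    frac = (np.clip(draws, lower, upper) - lower) / (upper - lower)
    cols = np.rint(frac * (n_columns - 1)).astype(int)
    cols[0] = 0
    cols[1] = n_columns - 1
    # stack chips within a column on successive rows
    row_counter: dict[int, int] = {}
    chips = []
    for c in cols:
        r = row_counter.get(int(c), 0)
        if r >= n_rows:
            raise ValueError(f"column {c} overflows the {n_rows}-row grid")
        chips.append((int(c), r))
        row_counter[int(c)] = r + 1
    return RouletteGrid(
        lower=float(lower),
        upper=float(upper),
        chips=tuple(chips),
        n_columns=n_columns,
        n_rows=n_rows,
    )


# ---------------------------------------------------------------------------
# persistence


def _dist_to_dict(d: Optional[SkewNormal]):
    if d is None:
        return None
    return {"mean": d.mean, "sd": d.sd, "shape": d.shape}


def _dist_from_dict(d, where: str) -> Optional[SkewNormal]:
    if d is None:
        return None
    try:
        return SkewNormal(float(d["mean"]), float(d["sd"]), float(d["shape"]))
    except (KeyError, TypeError, ValueError) as err:
        raise ValueError(f"invalid distribution at {where}: {err}") from err


def _record_to_dict(r: ElicitationRecord) -> dict:
    return {
        "expert_id": r.expert_id,
        "scale": {"a": r.scale.a, "b": r.scale.b, "label": r.scale.label},
        "step1_grid": r.step1_grid.to_dict() if r.step1_grid else None,
        "step2_fit": _dist_to_dict(r.step2_fit),
        "step2_accepted": r.step2_accepted,
        "step3_bounds": (
            None
            if r.step3_bounds is None
            else {
                "mu0": r.step3_bounds.mu0,
                "lower": r.step3_bounds.lower,
                "upper": r.step3_bounds.upper,
                "n_center": r.step3_bounds.n_center,
                "n_bound": r.step3_bounds.n_bound,
            }
        ),
        "step4_prior": _dist_to_dict(r.step4_prior),
        "iterations": [
            {"step": it["step"], "inputs": it["inputs"],
             "fit": _dist_to_dict(it["fit"])}
            for it in r.iterations
        ],
    }


def _record_from_dict(d: dict) -> ElicitationRecord:
    where = f"record {d.get('expert_id', '?')!r}"
    try:
        scale = ScaleSpec(
            float(d["scale"]["a"]), float(d["scale"]["b"]),
            str(d["scale"].get("label", "")),
        )
    except (KeyError, TypeError, ValueError) as err:
        raise ValueError(f"invalid scale at {where}: {err}") from err
    grid = d.get("step1_grid")
    bounds = d.get("step3_bounds")
    try:
        grid_obj = RouletteGrid.from_dict(grid) if grid else None
    except (KeyError, TypeError, ValueError) as err:
        raise ValueError(f"invalid step1_grid at {where}: {err}") from err
    try:
        bounds_obj = (
            BoundsElicitation(
                float(bounds["mu0"]), float(bounds["lower"]),
                float(bounds["upper"]),
                int(bounds.get("n_center", 100)), int(bounds.get("n_bound", 10)),
            )
            if bounds
            else None
        )
    except (KeyError, TypeError, ValueError) as err:
        raise ValueError(f"invalid step3_bounds at {where}: {err}") from err
    return ElicitationRecord(
        expert_id=str(d["expert_id"]),
        scale=scale,
        step1_grid=grid_obj,
        step2_fit=_dist_from_dict(d.get("step2_fit"), f"{where}.step2_fit"),
        step2_accepted=bool(d.get("step2_accepted", False)),
        step3_bounds=bounds_obj,
        step4_prior=_dist_from_dict(d.get("step4_prior"), f"{where}.step4_prior"),
        iterations=[
            {"step": it["step"], "inputs": it["inputs"],
             "fit": _dist_from_dict(it.get("fit"), f"{where}.iterations")}
            for it in d.get("iterations", [])
        ],
    )


def save_session(panel: ExpertPanel, path) -> None:
    """Serialize a panel to versioned JSON (full float precision)."""
    doc = {
        "version": SESSION_VERSION,
        "common_scale": {
            "a": panel.common_scale.a,
            "b": panel.common_scale.b,
            "label": panel.common_scale.label,
        },
        "posterior": _dist_to_dict(panel.posterior),
        "records": [_record_to_dict(r) for r in panel.records],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_session(path) -> ExpertPanel:
    """Load a panel saved by :func:`save_session`; validates as it reads."""
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("version")
    if version != SESSION_VERSION:
        raise ValueError(
            f"unsupported session version {version!r}; "
            f"this build reads version {SESSION_VERSION}"
        )
    try:
        cs = doc["common_scale"]
        common = ScaleSpec(float(cs["a"]), float(cs["b"]),
                           str(cs.get("label", "")))
    except (KeyError, TypeError, ValueError) as err:
        raise ValueError(f"invalid common_scale: {err}") from err
    return ExpertPanel(
        records=[_record_from_dict(r) for r in doc.get("records", [])],
        common_scale=common,
        posterior=_dist_from_dict(doc.get("posterior"), "posterior"),
    )
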