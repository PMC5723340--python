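"""Digitized trial-roulette grid (chips-and-bins elicitation).

An expert places chips on a bounded grid whose columns form an equally
spaced value axis from a reasonable lower bound to a reasonable upper bound;
the leftmost and rightmost chips define the range.  Each chip activates one
cell; the activated columns' axis values, one per chip, form the value
vector handed to the fitting stage.  With ``n`` chips each chip carries
``1/n`` of the elicited probability mass (5% at the conventional 20 chips).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RouletteGrid",
    "build_axis",
    "chips_to_values",
    "grid_from_positions",
    "read_chip_csv",
    "MIN_CHIPS",
]

# procedural rule: a grid is fit-ready only with at least seven chips
MIN_CHIPS = 7


def build_axis(lower: float, upper: float, n_columns: int = 600) -> np.ndarray:
    """Equally spaced value axis of length ``n_columns`` from lower to upper.

    The endpoints are hit exactly, so the range-defining chips in the first
    and last column map to the stated bounds.
    """
    if not np.isfinite(lower) or not np.isfinite(upper):
        raise ValueError("bounds must be finite")
    if upper <= lower:
        raise ValueError(f"upper must exceed lower, got [{lower}, {upper}]")
    n_columns = int(n_columns)
    if n_columns < 2:
        raise ValueError("axis needs at least 2 columns")
    return np.linspace(float(lower), float(upper), n_columns)


@dataclass(frozen=True)
class RouletteGrid:
    """Chip placements on a bounded grid.

    Parameters
    ----------
    lower, upper : float
        Reasonable bounds spanned by the value axis (upper > lower).
    chips : tuple of (column, row) int pairs
        0-based cell coordinates.  Rows carry no numeric meaning (vertical
        stacking only); columns index the value axis.  Duplicate cells are
        rejected; several chips may stack in one column on distinct rows.
    n_columns, n_rows : int
        Grid dimensions, default 600 x 300.
    """

    lower: float
    upper: float
    chips: tuple[tuple[int, int], ...]
    n_columns: int = 600
    n_rows: int = 300

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if self.upper <= self.lower:
            raise ValueError(
                f"upper must exceed lower, got [{self.lower}, {self.upper}]"
            )
        if self.n_columns < 2 or self.n_rows < 1:
            raise ValueError("grid must have >= 2 columns and >= 1 row")
        chips = tuple((int(c), int(r)) for c, r in self.chips)
        object.__setattr__(self, "chips", chips)
        if len(chips) == 0:
            raise ValueError("grid has no chips")
        seen = set()
        for c, r in chips:
            if not (0 <= c < self.n_columns):
                raise ValueError(
                    f"chip column {c} outside [0, {self.n_columns})"
                )
            if not (0 <= r < self.n_rows):
                raise ValueError(f"chip row {r} outside [0, {self.n_rows})")
            if (c, r) in seen:
                raise ValueError(f"duplicate chip at cell ({c}, {r})")
            seen.add((c, r))

    @property
    def n_chips(self) -> int:
        return len(self.chips)

    @property
    def axis(self) -> np.ndarray:
        return build_axis(self.lower, self.upper, self.n_columns)

    @property
    def columns(self) -> np.ndarray:
        return np.array([c for c, _ in self.chips], dtype=int)

    def is_fit_ready(self) -> bool:
        cols = self.columns
        return (
            self.n_chips >= MIN_CHIPS
            and 0 in cols
            and (self.n_columns - 1) in cols
        )

    def to_dict(self) -> dict:
        return {
            "n_columns": self.n_columns,
            "n_rows": self.n_rows,
            "lower": self.lower,
            "upper": self.upper,
            "chips": [list(c) for c in self.chips],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RouletteGrid":
        return cls(
            lower=float(d["lower"]),
            upper=float(d["upper"]),
            chips=tuple((int(c), int(r)) for c, r in d["chips"]),
            n_columns=int(d.get("n_columns", 600)),
            n_rows=int(d.get("n_rows", 300)),
        )


def grid_from_positions(
    positions,
    lower: float,
    upper: float,
    n_columns: int = 600,
    n_rows: int = 300,
) -> RouletteGrid:
    """Validated grid constructor from (column, row) pairs."""
    positions = tuple((int(c), int(r)) for c, r in positions)
    if not positions:
        raise ValueError("positions must be nonempty")
    return RouletteGrid(
        lower=float(lower),
        upper=float(upper),
        chips=positions,
        n_columns=n_columns,
        n_rows=n_rows,
    )


def chips_to_values(grid: RouletteGrid) -> np.ndarray:
    """Value vector consumed by the shape fit: one axis value per chip.

    Stacked chips in one column repeat the column's value, so chip counts act
    as integral weights.  Requires a fit-ready grid (at least ``MIN_CHIPS``
    chips).
    """
    if grid.n_chips < MIN_CHIPS:
        raise ValueError(
            f"grid has {grid.n_chips} chips; at least {MIN_CHIPS} are "
            "required for a fit-ready elicitation"
        )
    return grid.axis[grid.columns]


def read_chip_csv(path, lower: float, upper: float, **grid_kw) -> RouletteGrid:
    """Read a chip file (CSV with header ``column,row``) into a grid."""
    df = pd.read_csv(path)
    missing = {"column", "row"} - set(df.columns)
    if missing:
        raise ValueError(f"chip CSV missing columns: {sorted(missing)}")
    positions = list(zip(df["column"].astype(int), df["row"].astype(int)))
    return grid_from_positions(positions, lower, upper, **grid_kw)
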