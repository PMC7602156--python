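"""Trend direction detection and parameter bound sets.

Bounding the parameters is what lets a global swarm search run without a
user-supplied initial guess: symmetry values live in [-1, 1], so the final
value c is bounded by [-1, 1], total change by [-2, 2], and rates by
[-ln2, 0] (a 50% change in a single stride already being an impractical
extreme).  The amplitude bounds are then narrowed by the direction from
which the series approaches its final value and, for the double model, by
whether an overshoot (opposite-sign amplitudes) is allowed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .series_io import SymmetrySeries

__all__ = [
    "Direction",
    "OvershootVariant",
    "BoundSet",
    "detect_direction",
    "direction_mean_difference",
    "make_bounds",
]

LN2 = math.log(2.0)


class Direction(str, enum.Enum):
    """Direction from which the series approaches its final value.

    POSITIVE: from above (total change is positive, the series decreases).
    NEGATIVE: from below.
    """

    POSITIVE = "+ve"
    NEGATIVE = "-ve"


class OvershootVariant(str, enum.Enum):
    """Whether the double-model amplitude bounds permit an overshoot."""

    NO = "no"
    YES = "yes"
    NA = "n/a"  # single model


@dataclass(frozen=True)
class BoundSet:
    lower: np.ndarray
    upper: np.ndarray
    direction: Direction
    overshoot_variant: OvershootVariant
    model_kind: str  # "single" | "double"

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))

    def contains(self, x, atol: float = 1e-12) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )


def direction_mean_difference(series: SymmetrySeries, window: int = 50) -> float:
    """mean(first w strides) - mean(last w strides), w = min(window, N//2)."""
    n = series.n_strides
    if n < 2:
        raise ValueError("direction detection needs at least 2 strides")
    w = min(int(window), n // 2)
    return float(series.values[:w].mean() - series.values[-w:].mean())


def detect_direction(series: SymmetrySeries, window: int = 50) -> Direction:
    """Infer the trend direction from first-vs-last stride-window means.

    A positive mean difference means the series starts above where it ends,
    i.e. it approaches its final value from above.  The 50-stride window
    shrinks to floor(N/2) for short series.  The rule is a heuristic; a zero
    difference (or distrust of the rule) is handled upstream by racing both
    directions and keeping the lower-cost fit.
    """
    return (
        Direction.POSITIVE
        if direction_mean_difference(series, window) > 0
        else Direction.NEGATIVE
    )


# Amplitude bounds per (direction, overshoot variant); rates are always
# [-ln2, 0] and c always [-1, 1].
_SINGLE_A = {Direction.POSITIVE: (0.0, 2.0), Direction.NEGATIVE: (-2.0, 0.0)}
_DOUBLE_AMPS = {
    (Direction.POSITIVE, OvershootVariant.NO): ((0.0, 1.0), (0.0, 1.0)),
    (Direction.POSITIVE, OvershootVariant.YES): ((-1.0, 0.0), (0.0, 1.0)),
    (Direction.NEGATIVE, OvershootVariant.NO): ((-1.0, 0.0), (-1.0, 0.0)),
    (Direction.NEGATIVE, OvershootVariant.YES): ((0.0, 1.0), (-1.0, 0.0)),
}


def make_bounds(
    model_kind: str,
    direction: Direction,
    overshoot_variant: OvershootVariant | None = None,
) -> BoundSet:
    """Construct the bound set for a model kind, direction and overshoot variant.

    Parameter order is (a, b, c) for the single model and
    (as, bs, af, bf, c) for the double model.
    """
    direction = Direction(direction)
    if model_kind == "single":
        if overshoot_variant not in (None, OvershootVariant.NA):
            raise ValueError("overshoot variant does not apply to the single model")
        a_lo, a_hi = _SINGLE_A[direction]
        return BoundSet(
            lower=[a_lo, -LN2, -1.0],
            upper=[a_hi, 0.0, 1.0],
            direction=direction,
            overshoot_variant=OvershootVariant.NA,
            model_kind="single",
        )
    if model_kind == "double":
        variant = OvershootVariant(overshoot_variant or OvershootVariant.NO)
        if variant is OvershootVariant.NA:
            raise ValueError("double model requires overshoot variant yes/no")
        (as_lo, as_hi), (af_lo, af_hi) = _DOUBLE_AMPS[(direction, variant)]
        return BoundSet(
            lower=[as_lo, -LN2, af_lo, -LN2, -1.0],
            upper=[as_hi, 0.0, af_hi, 0.0, 1.0],
            direction=direction,
            overshoot_variant=variant,
            model_kind="double",
        )
    raise ValueError(f"unknown model kind: {model_kind!r}")
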