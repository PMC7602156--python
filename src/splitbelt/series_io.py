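"""Stride-indexed series containers and CSV I/O.

The regression response is the per-stride step length symmetry

    y(n) = (lf(n) - ls(n)) / (lf(n) + ls(n)),

a unitless number in (-1, 1) where ``lf``/``ls`` are the fast- and slow-leg
step lengths of stride ``n``.  Zero means perfectly symmetric steps; positive
values mean the fast leg steps longer.  Stride indices start at 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StepLengthSeries",
    "SymmetrySeries",
    "compute_symmetry",
    "group_average",
    "read_series",
    "write_series",
]


class SeriesInputError(ValueError):
    """Raised for malformed or out-of-range series input."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise SeriesInputError(f"{name} must be one-dimensional")
    if arr.size < 1:
        raise SeriesInputError(f"{name} must contain at least one stride")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise SeriesInputError(f"{name} has non-finite value at stride {bad[0] + 1}")
    return arr


@dataclass(frozen=True)
class StepLengthSeries:
    """Per-stride fast- and slow-leg step lengths (any consistent length unit)."""

    fast: np.ndarray
    slow: np.ndarray

    def __post_init__(self):
        fast = _as_float_array(self.fast, "fast step lengths")
        slow = _as_float_array(self.slow, "slow step lengths")
        if fast.size != slow.size:
            raise SeriesInputError(
                f"length mismatch: {fast.size} fast vs {slow.size} slow strides"
            )
        for name, arr in (("fast", fast), ("slow", slow)):
            bad = np.flatnonzero(arr <= 0)
            if bad.size:
                raise SeriesInputError(
                    f"nonpositive {name} step length at stride {bad[0] + 1}"
                )
        object.__setattr__(self, "fast", fast)
        object.__setattr__(self, "slow", slow)

    @property
    def n_strides(self) -> int:
        return self.fast.size


@dataclass(frozen=True)
class SymmetrySeries:
    """Step length symmetry values y(n), n = 1..N, each within [-1, 1]."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        values = _as_float_array(self.values, "symmetry values")
        bad = np.flatnonzero(np.abs(values) > 1)
        if bad.size:
            raise SeriesInputError(
                f"symmetry value {values[bad[0]]:g} outside [-1, 1] "
                f"at stride {bad[0] + 1}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_strides(self) -> int:
        return self.values.size

    @property
    def stride_index(self) -> np.ndarray:
        """Integer stride numbers 1..N the trend models are evaluated at."""
        return np.arange(1, self.values.size + 1)


def compute_symmetry(steps: StepLengthSeries, label: str = "") -> SymmetrySeries:
    """Step length symmetry (fast - slow) / (fast + slow), stride by stride.

    Positive step lengths guarantee the result lies strictly inside (-1, 1).
    """
    values = (steps.fast - steps.slow) / (steps.fast + steps.slow)
    return SymmetrySeries(values=values, label=label)


def group_average(series: list[SymmetrySeries], label: str = "group mean") -> SymmetrySeries:
    """Per-stride mean across participants.

    Participants may contribute different stride counts; all series are
    truncated to the shortest one before averaging so that the mean at stride
    n is always over the same participants.
    """
    if not series:
        raise SeriesInputError("group_average requires at least one series")
    n_min = min(s.n_strides for s in series)
    stacked = np.vstack([s.values[:n_min] for s in series])
    return SymmetrySeries(values=stacked.mean(axis=0), label=label)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_series(path, label: str = "") -> SymmetrySeries | StepLengthSeries:
    """Read a stride series from CSV.

    One numeric column is parsed as a symmetry series; two columns as
    fast,slow step lengths.  A single header row is detected and skipped.
    Validation errors name the offending file row.
    """
    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SeriesInputError(f"{path}: empty file")
    first = [tok.strip() for tok in lines[0].split(",")]
    has_header = not all(_looks_numeric(tok) for tok in first if tok)
    frame = pd.read_csv(
        io.StringIO(text), header=0 if has_header else None, comment="#"
    )
    if frame.shape[1] not in (1, 2):
        raise SeriesInputError(
            f"{path}: expected 1 (symmetry) or 2 (fast,slow) columns, "
            f"found {frame.shape[1]}"
        )
    offset = 2 if has_header else 1  # file row number of the first data row
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(numeric.isna().to_numpy())
        if bad.size:
            raise SeriesInputError(
                f"{path}: malformed value in row {bad[0] + offset}"
            )
        frame[col] = numeric
    try:
        if frame.shape[1] == 1:
            return SymmetrySeries(values=frame.iloc[:, 0].to_numpy(), label=label)
        return StepLengthSeries(
            fast=frame.iloc[:, 0].to_numpy(), slow=frame.iloc[:, 1].to_numpy()
        )
    except SeriesInputError as err:  # re-anchor stride index to file rows
        raise SeriesInputError(f"{path}: {err} (data starts at row {offset})") from err


def write_series(series: SymmetrySeries, path) -> None:
    """Write a symmetry series as a one-column CSV with a ``symmetry`` header."""
    pd.DataFrame({"symmetry": series.values}).to_csv(path, index=False)
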