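"""Single and double exponential trend models and their interpretation.

Single exponential:  f1(n; theta) = a * exp(b*n) + c
Double exponential:  f2(n; theta) = as * exp(bs*n) + af * exp(bf*n) + c

with stride number n = 1..N, negative rate constants (decaying trends only)
and, for the double model, bf < bs so the "fast" term vanishes first.  The
parameters map onto quantities practitioners reason about directly: initial
asymmetry, total change, strides to 50% change, final asymmetry, overshoot,
and residual SD; that transform lives in :func:`to_common_language`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThetaSingle",
    "ThetaDouble",
    "OvershootResult",
    "CommonLanguage",
    "eval_single",
    "eval_double",
    "overshoot",
    "half_change_strides",
    "to_common_language",
    "overshoot_map",
    "OvershootGrid",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ThetaSingle:
    """Parameters of the single exponential trend.

    a : change in symmetry from the beginning to the end of the phase
    b : rate constant per stride (negative for a decaying trend)
    c : symmetry value at the end of the phase
    """

    a: float
    b: float
    c: float

    def to_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ThetaSingle":
        a, b, c = (float(v) for v in x)
        return cls(a=a, b=b, c=c)

    @property
    def names(self) -> tuple[str, ...]:
        return ("a", "b", "c")

    @property
    def n_params(self) -> int:
        return 3


@dataclass(frozen=True)
class ThetaDouble:
    """Parameters of the double exponential trend.

    as_, af : amplitudes of the slow and fast exponential terms
    bs, bf  : their rate constants per stride; bf < bs <= 0 when fitted
    c       : symmetry value at the end of the phase
    """

    as_: float
    bs: float
    af: float
    bf: float
    c: float

    def to_array(self) -> np.ndarray:
        return np.array([self.as_, self.bs, self.af, self.bf, self.c], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ThetaDouble":
        as_, bs, af, bf, c = (float(v) for v in x)
        return cls(as_=as_, bs=bs, af=af, bf=bf, c=c)

    @property
    def names(self) -> tuple[str, ...]:
        return ("as", "bs", "af", "bf", "c")

    @property
    def n_params(self) -> int:
        return 5


def _strides(n_max: int) -> np.ndarray:
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    return np.arange(1, int(n_max) + 1, dtype=float)


def eval_single(theta: ThetaSingle, n: int | np.ndarray) -> np.ndarray:
    """Evaluate f1(n) = a*exp(b*n) + c at strides 1..n (or an explicit grid)."""
    grid = _strides(n) if np.isscalar(n) else np.asarray(n, dtype=float)
    return theta.a * np.exp(theta.b * grid) + theta.c


def eval_double(theta: ThetaDouble, n: int | np.ndarray) -> np.ndarray:
    """Evaluate f2(n) = as*exp(bs*n) + af*exp(bf*n) + c."""
    grid = _strides(n) if np.isscalar(n) else np.asarray(n, dtype=float)
    return (
        theta.as_ * np.exp(theta.bs * grid)
        + theta.af * np.exp(theta.bf * grid)
        + theta.c
    )


@dataclass(frozen=True)
class OvershootResult:
    """Overshoot of the double-exponential trend past its asymptote.

    The trend's first derivative vanishes at

        ncrit = ln(-as*bs / (af*bf)) / (bf - bs)

    which is real only when the amplitudes have opposite signs; the trend
    value there is the overshoot ycrit = f2(ncrit).  ``defined`` is False
    ("UD") otherwise.  ``in_range`` flags whether ncrit falls inside the
    observed stride range when one is known.
    """

    defined: bool
    ncrit: float | None = None
    ycrit: float | None = None
    in_range: bool | None = None
    note: str = ""

    def to_json(self) -> dict:
        return {
            "defined": self.defined,
            "ncrit": self.ncrit if self.defined else "UD",
            "ycrit": self.ycrit if self.defined else "UD",
            "in_range": self.in_range,
            "note": self.note,
        }


def overshoot(theta: ThetaDouble, n_strides: int | None = None) -> OvershootResult:
    """Locate and evaluate the overshoot of a double-exponential trend.

    Returns an undefined result when the amplitudes share a sign (no critical
    point exists) or when bs == bf (the critical-stride expression has a zero
    denominator).
    """
    if theta.bs == theta.bf:
        return OvershootResult(
            defined=False, note="bs equals bf: critical-stride denominator is zero"
        )
    if theta.as_ * theta.af >= 0:
        return OvershootResult(
            defined=False, note="amplitudes do not have opposite signs"
        )
    ratio = -(theta.as_ * theta.bs) / (theta.af * theta.bf)
    if ratio <= 0:  # cannot occur with negative rates, guards rate sign misuse
        return OvershootResult(defined=False, note="log argument not positive")
    ncrit = math.log(ratio) / (theta.bf - theta.bs)
    ycrit = float(eval_double(theta, np.array([ncrit]))[0])
    in_range = None
    if n_strides is not None:
        in_range = bool(1.0 <= ncrit <= float(n_strides))
    return OvershootResult(defined=True, ncrit=ncrit, ycrit=ycrit, in_range=in_range)


def half_change_strides(rate: float) -> int:
    """Strides to complete ~50% of an exponential change: floor(ln2 / |rate|).

    Only decaying trends (rate < 0) have a half-change stride count.
    """
    if not rate < 0:
        raise ValueError(f"rate must be negative for a decaying trend, got {rate}")
    return int(math.floor(LN2 / abs(rate)))


@dataclass(frozen=True)
class CommonLanguage:
    """Model parameters transformed into practitioner-facing quantities."""

    initial_asymmetry: float
    total_change: float
    half_change: tuple[int, ...]
    final_asymmetry: float
    overshoot: OvershootResult
    residual_sd: float
    degenerate: bool = False

    def to_json(self) -> dict:
        return {
            "initial_asymmetry": self.initial_asymmetry,
            "total_change": self.total_change,
            "half_change_strides": list(self.half_change),
            "final_asymmetry": self.final_asymmetry,
            "overshoot": self.overshoot.to_json(),
            "residual_sd": self.residual_sd,
            "degenerate": self.degenerate,
        }


def to_common_language(
    theta: ThetaSingle | ThetaDouble,
    residual_sd: float,
    n_strides: int | None = None,
) -> CommonLanguage:
    """Transform fitted parameters to their common-language interpretation.

    Single model: initial asymmetry a+c, total change a, floor(ln2/|b|)
    strides to half change, final asymmetry c; the overshoot is always
    undefined.  Double model: initial asymmetry as+af+c, total change as+af,
    one half-change count per trend, plus the overshoot analysis.  An
    amplitude fitted at exactly 0 marks the degenerate boundary case — a
    double exponential no better than a single one.
    """
    if isinstance(theta, ThetaSingle):
        return CommonLanguage(
            initial_asymmetry=theta.a + theta.c,
            total_change=theta.a,
            half_change=(half_change_strides(theta.b),) if theta.b < 0 else (),
            final_asymmetry=theta.c,
            overshoot=OvershootResult(defined=False, note="single exponential model"),
            residual_sd=residual_sd,
            degenerate=theta.a == 0.0,
        )
    halves = tuple(
        half_change_strides(rate) for rate in (theta.bs, theta.bf) if rate < 0
    )
    return CommonLanguage(
        initial_asymmetry=theta.as_ + theta.af + theta.c,
        total_change=theta.as_ + theta.af,
        half_change=halves,
        final_asymmetry=theta.c,
        overshoot=overshoot(theta, n_strides=n_strides),
        residual_sd=residual_sd,
        degenerate=theta.as_ == 0.0 or theta.af == 0.0,
    )


@dataclass(frozen=True)
class OvershootGrid:
    """Parameter grid for the numerical overshoot analysis.

    Defaults: amplitudes over [-1, 1] in steps of 0.1, rates over ten points
    spanning [-ln2, -1e-3], c = 0, with the admissibility constraints
    bf < bs and |as + af| <= 2.
    """

    as_values: np.ndarray | None = None
    af_values: np.ndarray | None = None
    bs_values: np.ndarray | None = None
    bf_values: np.ndarray | None = None

    def resolved(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        amps = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)
        rates = np.linspace(-LN2, -1e-3, 10)
        return (
            amps if self.as_values is None else np.asarray(self.as_values, float),
            amps if self.af_values is None else np.asarray(self.af_values, float),
            rates if self.bs_values is None else np.asarray(self.bs_values, float),
            rates if self.bf_values is None else np.asarray(self.bf_values, float),
        )


def overshoot_map(grid: OvershootGrid | None = None) -> pd.DataFrame:
    """Tabulate the overshoot over an (as, af, bs, bf) grid with c = 0.

    Reproduces the numerical analysis relating amplitude pairs to achievable
    overshoot values: every admissible combination (bf < bs, |as+af| <= 2)
    is enumerated and its ycrit computed, with combinations whose amplitudes
    share a sign flagged as undefined.
    """
    grid = grid or OvershootGrid()
    as_v, af_v, bs_v, bf_v = grid.resolved()
    rows = []
    for as_ in as_v:
        for af in af_v:
            if abs(as_ + af) > 2:
                continue
            for bs in bs_v:
                for bf in bf_v:
                    if not bf < bs:
                        continue
                    res = overshoot(
                        ThetaDouble(as_=as_, bs=bs, af=af, bf=bf, c=0.0)
                    )
                    rows.append(
                        {
                            "as": as_,
                            "af": af,
                            "bs": bs,
                            "bf": bf,
                            "defined": res.defined,
                            "ncrit": res.ncrit if res.defined else np.nan,
                            "ycrit": res.ycrit if res.defined else np.nan,
                        }
                    )
    if not rows:
        raise ValueError("overshoot_map grid admits no (as, af, bs, bf) combination")
    return pd.DataFrame(rows)
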