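"""Seeded synthetic symmetry series with the structure the models assume.

The trial data behind the method (15 healthy adults, two sessions of 2:1
split-belt walking) is not publicly deposited, so this generator stands in
for it: an exponential trend (single or double) plus iid zero-mean Gaussian
noise, optionally plus a small sinusoid mimicking the cyclic residual trends
seen in participant-level series.  The four named default specs emulate the
magnitudes of the published group-averaged fits (residual SD around
5-7e-3, slow/fast half-lives from a few to a few hundred strides, ~750
adaptation / ~500 de-adaptation strides); they are an emulation of those
study conditions, not a replication of the original series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import ThetaDouble, ThetaSingle, eval_double, eval_single
from .series_io import SymmetrySeries

__all__ = ["CyclicComponent", "SimulationSpec", "simulate_series", "default_specs"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class CyclicComponent:
    """Sinusoid A*sin(2*pi*n/T) added to the trend (amplitude unitless,
    period in strides)."""

    amplitude: float
    period: float

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("cyclic period must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic series: trend, noise SD, length, seed.

    A spec whose trend +/- 4 sigma (plus any cyclic amplitude) exits [-1, 1]
    is rejected outright — clipping generated values would silently break
    the Gaussian-noise assumption.
    """

    theta: ThetaSingle | ThetaDouble
    sigma: float
    n_strides: int
    seed: int = 0
    cyclic: CyclicComponent | None = None
    label: str = ""

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n_strides < 1:
            raise ValueError("need at least one stride")
        trend = self.trend()
        margin = 4.0 * self.sigma + (abs(self.cyclic.amplitude) if self.cyclic else 0.0)
        if np.any(np.abs(trend) + margin > 1.0):
            raise ValueError(
                "trend +/- 4 sigma leaves the [-1, 1] symmetry range; "
                "choose smaller amplitudes or noise"
            )

    def trend(self) -> np.ndarray:
        if isinstance(self.theta, ThetaSingle):
            return eval_single(self.theta, self.n_strides)
        return eval_double(self.theta, self.n_strides)

    def to_json(self) -> dict:
        data = {
            "model": "single" if isinstance(self.theta, ThetaSingle) else "double",
            "theta": dict(zip(self.theta.names, self.theta.to_array())),
            "sigma": self.sigma,
            "n_strides": self.n_strides,
            "seed": self.seed,
            "label": self.label,
        }
        if self.cyclic is not None:
            data["cyclic"] = {
                "amplitude": self.cyclic.amplitude,
                "period": self.cyclic.period,
            }
        return data

    @classmethod
    def from_json(cls, data: dict) -> "SimulationSpec":
        theta_map = dict(data["theta"])
        if data["model"] == "single":
            theta = ThetaSingle(a=theta_map["a"], b=theta_map["b"], c=theta_map["c"])
        else:
            theta = ThetaDouble(
                as_=theta_map["as"], bs=theta_map["bs"],
                af=theta_map["af"], bf=theta_map["bf"], c=theta_map["c"],
            )
        cyclic = None
        if data.get("cyclic"):
            cyclic = CyclicComponent(
                amplitude=data["cyclic"]["amplitude"],
                period=data["cyclic"]["period"],
            )
        return cls(
            theta=theta,
            sigma=data["sigma"],
            n_strides=data["n_strides"],
            seed=data.get("seed", 0),
            cyclic=cyclic,
            label=data.get("label", ""),
        )


def simulate_series(spec: SimulationSpec, seed: int | None = None) -> SymmetrySeries:
    """Draw one series y(n) = trend(n) [+ sinusoid] + N(0, sigma^2) noise.

    ``seed`` overrides the spec's stored seed; identical seeds give
    identical series.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    y = spec.trend().copy()
    if spec.cyclic is not None:
        n = np.arange(1, spec.n_strides + 1, dtype=float)
        y += spec.cyclic.amplitude * np.sin(2.0 * np.pi * n / spec.cyclic.period)
    y += rng.normal(0.0, spec.sigma, size=spec.n_strides)
    # no clipping: the spec validation keeps trend +/- 4 sigma inside [-1, 1],
    # and silently clipping would distort the Gaussian residual model
    return SymmetrySeries(values=y, label=spec.label)


def default_specs() -> dict[str, SimulationSpec]:
    """Four example regimes: adaptation/de-adaptation in two session-like states.

    adaptation1    two-timescale negative adaptation, half-lives ~235/~21
                   strides, no overshoot (session-I-like).
    adaptation2    adaptation ending with a positive overshoot (opposite-sign
                   amplitudes, half-lives ~30/~15 strides, session-II-like).
    deadaptation1  positive de-adaptation, half-lives ~100/~15 strides.
    deadaptation2  faster de-adaptation, half-lives ~58/~4 strides.
    """
    return {
        "adaptation1": SimulationSpec(
            theta=ThetaDouble(
                as_=-0.100, bs=-LN2 / 235.0, af=-0.037, bf=-LN2 / 21.0, c=0.024
            ),
            sigma=0.0064,
            n_strides=750,
            label="adaptation1",
        ),
        "adaptation2": SimulationSpec(
            theta=ThetaDouble(
                as_=0.080, bs=-LN2 / 30.0, af=-0.143, bf=-LN2 / 15.0, c=0.030
            ),
            sigma=0.0056,
            n_strides=750,
            label="adaptation2",
        ),
        "deadaptation1": SimulationSpec(
            theta=ThetaDouble(
                as_=0.065, bs=-LN2 / 100.0, af=0.052, bf=-LN2 / 15.0, c=0.024
            ),
            sigma=0.0070,
            n_strides=500,
            label="deadaptation1",
        ),
        "deadaptation2": SimulationSpec(
            theta=ThetaDouble(
                as_=0.060, bs=-LN2 / 58.0, af=0.038, bf=-LN2 / 4.0, c=0.027
            ),
            sigma=0.0062,
            n_strides=500,
            label="deadaptation2",
        ),
    }
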