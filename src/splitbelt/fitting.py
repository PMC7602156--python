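"""Bounded nonlinear least-squares fitting of the exponential trend models.

The single model minimises the residual sum of squares

    S(theta) = sum_{n=1..N} (y(n) - f1(n; theta))^2,    theta_l <= theta <= theta_u.

The double model adds two penalty terms enforcing its soft constraints,

    lambda1 * max(0, bf - bs + delta)^2  +  lambda2 * max(0, |as + af| - 2)^2,

with weights lambda1 = lambda2 = 1e3 and rate-separation slack delta = 1e-3:
bf must decay faster than bs and the total change |as + af| cannot exceed 2.

Each fit runs a global particle-swarm stage (random initialisation within the
bound box, coarse cost tolerance 1e-3) followed by a bounded derivative-based
least-squares refinement (cost tolerance 1e-6), repeats the whole procedure
from fresh random swarms (two restarts by default), and — for the double
model — races the overshoot and no-overshoot bound variants, keeping the
lowest-cost solution.  Everything is deterministic given the master seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .bounds import (
    BoundSet,
    Direction,
    OvershootVariant,
    direction_mean_difference,
    make_bounds,
)
from .models import ThetaDouble, ThetaSingle, eval_double, eval_single
from .pso import pso_minimize
from .series_io import SymmetrySeries

__all__ = [
    "FitConfig",
    "FitResult",
    "cost_single",
    "cost_double",
    "penalty_terms",
    "fit",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the two-stage optimisation.

    The penalty weights, rate-separation slack, stage cost tolerances and
    restart count carry the method's stated defaults; the swarm
    hyperparameters are implementation defaults comparable to common swarm
    optimisers and are all exposed here.
    """

    lambda1: float = 1e3
    lambda2: float = 1e3
    delta: float = 1e-3
    global_tol: float = 1e-3
    local_tol: float = 1e-6
    restarts: int = 2
    seed: int = 0
    swarm_size: int = 100
    max_iters: int = 1000
    stall_iters: int = 20
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618

    def __post_init__(self):
        if self.global_tol <= 0 or self.local_tol <= 0 or self.delta <= 0:
            raise ValueError("tolerances and delta must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be at least 1")

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, data: dict) -> "FitConfig":
        return cls(**data)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit.

    ``sse`` is the pure residual sum of squares (penalties excluded, so AIC
    and the residual-variance formulas consume exactly sum(eps^2));
    ``penalty_at_optimum`` reports the penalty contribution separately.
    ``s`` is the residual scale sqrt(SSE / (N - p)) with p regression
    parameters.  ``restart_costs`` records the penalized cost of every
    (direction, variant, restart) run of the race.
    """

    model_kind: str
    theta_hat: ThetaSingle | ThetaDouble
    sse: float
    residuals: np.ndarray
    s: float
    penalty_at_optimum: float
    bound_set: BoundSet
    restart_costs: tuple[dict, ...]
    seed_used: int
    converged: bool
    n_strides: int

    @property
    def n_params(self) -> int:
        return self.theta_hat.n_params

    @property
    def fitted_values(self) -> np.ndarray:
        n = np.arange(1, self.n_strides + 1, dtype=float)
        if self.model_kind == "single":
            return eval_single(self.theta_hat, n)
        return eval_double(self.theta_hat, n)

    def summary(self) -> dict:
        return {
            "model": self.model_kind,
            "theta": dict(zip(self.theta_hat.names, self.theta_hat.to_array())),
            "sse": self.sse,
            "residual_scale": self.s,
            "penalty_at_optimum": self.penalty_at_optimum,
            "direction": self.bound_set.direction.value,
            "overshoot_variant": self.bound_set.overshoot_variant.value,
            "restart_costs": list(self.restart_costs),
            "seed": self.seed_used,
            "converged": self.converged,
            "n_strides": self.n_strides,
        }


# ---------------------------------------------------------------------------
# Cost functions


def cost_single(theta: ThetaSingle, series: SymmetrySeries) -> float:
    """Residual sum of squares of the single exponential model."""
    resid = series.values - eval_single(theta, series.n_strides)
    return float(resid @ resid)


def penalty_terms(theta: ThetaDouble, config: FitConfig | None = None) -> tuple[float, float]:
    """The two penalty terms of the double-model objective.

    Term 1 punishes a rate ordering violation (bf not at least delta below
    bs); term 2 punishes total change beyond 2.  With the default weights,
    bf == bs contributes exactly 1e3 * (1e-3)^2 = 1e-3.
    """
    config = config or FitConfig()
    p1 = config.lambda1 * max(0.0, theta.bf - theta.bs + config.delta) ** 2
    p2 = config.lambda2 * max(0.0, abs(theta.as_ + theta.af) - 2.0) ** 2
    return p1, p2


def cost_double(
    theta: ThetaDouble, series: SymmetrySeries, config: FitConfig | None = None
) -> float:
    """Penalized objective of the double exponential model (SSE + penalties)."""
    config = config or FitConfig()
    resid = series.values - eval_double(theta, series.n_strides)
    return float(resid @ resid) + sum(penalty_terms(theta, config))


# ---------------------------------------------------------------------------
# Vectorised swarm objectives (particles-by-parameters matrices)


def _swarm_cost_single(X: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    pred = X[:, 0:1] * np.exp(X[:, 1:2] * n[None, :]) + X[:, 2:3]
    diff = y[None, :] - pred
    return np.einsum("ij,ij->i", diff, diff)


def _swarm_cost_double(
    X: np.ndarray, y: np.ndarray, n: np.ndarray, config: FitConfig
) -> np.ndarray:
    pred = (
        X[:, 0:1] * np.exp(X[:, 1:2] * n[None, :])
        + X[:, 2:3] * np.exp(X[:, 3:4] * n[None, :])
        + X[:, 4:5]
    )
    diff = y[None, :] - pred
    sse = np.einsum("ij,ij->i", diff, diff)
    p1 = config.lambda1 * np.maximum(0.0, X[:, 3] - X[:, 1] + config.delta) ** 2
    p2 = config.lambda2 * np.maximum(0.0, np.abs(X[:, 0] + X[:, 2]) - 2.0) ** 2
    return sse + p1 + p2


# ---------------------------------------------------------------------------
# Residual vectors and Jacobians for the local least-squares stage.  Penalty
# terms enter as extra residual rows sqrt(lambda) * max(0, g) so the penalized
# objective is exactly a sum of squares.


def _residuals_single(x: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    a, b, c = x
    return y - (a * np.exp(b * n) + c)


def _jac_single(x: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    a, b, _ = x
    e = np.exp(b * n)
    return -np.column_stack([e, a * n * e, np.ones_like(n)])


def _residuals_double(
    x: np.ndarray, y: np.ndarray, n: np.ndarray, config: FitConfig
) -> np.ndarray:
    as_, bs, af, bf, c = x
    data = y - (as_ * np.exp(bs * n) + af * np.exp(bf * n) + c)
    pen1 = math.sqrt(config.lambda1) * max(0.0, bf - bs + config.delta)
    pen2 = math.sqrt(config.lambda2) * max(0.0, abs(as_ + af) - 2.0)
    return np.concatenate([data, [pen1, pen2]])


def _jac_double(
    x: np.ndarray, y: np.ndarray, n: np.ndarray, config: FitConfig
) -> np.ndarray:
    as_, bs, af, bf, c = x
    es = np.exp(bs * n)
    ef = np.exp(bf * n)
    data = -np.column_stack([es, as_ * n * es, ef, af * n * ef, np.ones_like(n)])
    pen1 = np.zeros(5)
    if bf - bs + config.delta > 0:
        root = math.sqrt(config.lambda1)
        pen1[1] = -root
        pen1[3] = root
    pen2 = np.zeros(5)
    if abs(as_ + af) - 2.0 > 0:
        g = math.sqrt(config.lambda2) * math.copysign(1.0, as_ + af)
        pen2[0] = g
        pen2[2] = g
    return np.vstack([data, pen1, pen2])


def _refine(
    x0: np.ndarray,
    bound_set: BoundSet,
    y: np.ndarray,
    n: np.ndarray,
    config: FitConfig,
):
    """Bounded derivative-based polish from x0; returns (x, penalized_cost, ok)."""
    x0 = np.clip(x0, bound_set.lower, bound_set.upper)
    if bound_set.model_kind == "single":
        fun, jac = _residuals_single, _jac_single
        args = (y, n)
    else:
        fun, jac = _residuals_double, _jac_double
        args = (y, n, config)
    result = least_squares(
        fun,
        x0,
        jac=jac,
        args=args,
        bounds=(bound_set.lower, bound_set.upper),
        method="trf",
        ftol=config.local_tol,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    r = fun(result.x, *args)
    return result.x, float(r @ r), result.status > 0


def refine_with_fixed(
    series: SymmetrySeries,
    model_kind: str,
    theta0: np.ndarray,
    bound_set: BoundSet,
    fixed_index: int,
    fixed_value: float,
    config: FitConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Minimise the objective with one parameter held fixed (profile step).

    The fixed parameter may sit outside its bound-set box (profile brackets
    are allowed to extend past the fitting bounds); the free parameters keep
    their bounds.  Returns the full parameter vector and the pure SSE there.
    """
    config = config or FitConfig()
    y = series.values
    n = series.stride_index.astype(float)
    free = [i for i in range(theta0.size) if i != fixed_index]

    def embed(xf: np.ndarray) -> np.ndarray:
        full = np.empty(theta0.size)
        full[free] = xf
        full[fixed_index] = fixed_value
        return full

    if model_kind == "single":
        fun_full, jac_full = _residuals_single, _jac_single
        args = (y, n)
    else:
        fun_full, jac_full = _residuals_double, _jac_double
        args = (y, n, config)

    x0 = np.clip(theta0, bound_set.lower, bound_set.upper)[free]
    result = least_squares(
        lambda xf: fun_full(embed(xf), *args),
        x0,
        jac=lambda xf: jac_full(embed(xf), *args)[:, free],
        bounds=(bound_set.lower[free], bound_set.upper[free]),
        method="trf",
        ftol=config.local_tol,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    full = embed(result.x)
    if model_kind == "single":
        resid = y - eval_single(ThetaSingle.from_array(full), n)
    else:
        resid = y - eval_double(ThetaDouble.from_array(full), n)
    return full, float(resid @ resid)


# ---------------------------------------------------------------------------
# The fitting driver


def _run_seed(master: int, dir_idx: int, var_idx: int, restart: int) -> np.random.Generator:
    # restart seeds follow master, master+1, ...; direction/variant runs get
    # independent deterministic sub-streams via the spawn key
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master + restart, spawn_key=(dir_idx, var_idx))
    )


def _directions_in_play(
    series: SymmetrySeries, direction: str | Direction
) -> list[Direction]:
    if isinstance(direction, Direction):
        return [direction]
    if direction == "race":
        return [Direction.POSITIVE, Direction.NEGATIVE]
    if direction in ("+ve", "pos", "positive"):
        return [Direction.POSITIVE]
    if direction in ("-ve", "neg", "negative"):
        return [Direction.NEGATIVE]
    if direction == "auto":
        diff = direction_mean_difference(series)
        if diff == 0.0:  # undecidable: race both and keep the lower cost
            return [Direction.POSITIVE, Direction.NEGATIVE]
        return [Direction.POSITIVE if diff > 0 else Direction.NEGATIVE]
    raise ValueError(f"unknown direction setting {direction!r}")


def _single_embedding(x_single: np.ndarray, config: FitConfig) -> np.ndarray:
    """Embed a single-model solution into the double-model parameter space."""
    a, b, c = x_single
    bf = max(b - config.delta, -LN2)
    bs = min(b, bf + config.delta)
    bs = min(bs, 0.0)
    return np.array([a / 2.0, bs, a / 2.0, bf, c])


def fit(
    series: SymmetrySeries,
    model_kind: str,
    config: FitConfig | None = None,
    direction: str | Direction = "auto",
) -> FitResult:
    """Fit the single or double exponential model to a symmetry series.

    Runs the swarm-then-refine procedure for every bound set in play
    (direction x overshoot-variant) and for each restart, then returns the
    lowest-penalized-cost solution.  For the double model an additional
    deterministic candidate — the best single-model solution embedded as
    as = af = a/2 with rates b and b - delta — is polished under the
    no-overshoot bounds, which guarantees the double fit never ends up worse
    than the single fit it nests.
    """
    config = config or FitConfig()
    if model_kind not in ("single", "double"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    p = 3 if model_kind == "single" else 5
    if series.n_strides <= p:
        raise ValueError(
            f"need more strides than parameters: N={series.n_strides}, p={p}"
        )
    y = series.values
    n = series.stride_index.astype(float)
    directions = _directions_in_play(series, direction)
    variants = (
        [OvershootVariant.NA]
        if model_kind == "single"
        else [OvershootVariant.NO, OvershootVariant.YES]
    )

    runs = []  # (cost, x, bound_set, converged, record)
    for d_idx, direc in enumerate(directions):
        for v_idx, variant in enumerate(variants):
            bset = make_bounds(
                model_kind, direc, None if model_kind == "single" else variant
            )
            if model_kind == "single":
                swarm_fun = lambda X: _swarm_cost_single(X, y, n)
            else:
                swarm_fun = lambda X: _swarm_cost_double(X, y, n, config)
            for restart in range(config.restarts):
                rng = _run_seed(config.seed, d_idx, v_idx, restart)
                swarm = pso_minimize(
                    swarm_fun,
                    bset.lower,
                    bset.upper,
                    rng,
                    swarm_size=config.swarm_size,
                    max_iters=config.max_iters,
                    tol=config.global_tol,
                    stall_iters=config.stall_iters,
                    inertia=config.inertia,
                    cognitive=config.cognitive,
                    social=config.social,
                )
                x, cost, ok = _refine(swarm.x, bset, y, n, config)
                runs.append(
                    (
                        cost,
                        x,
                        bset,
                        ok and swarm.converged,
                        {
                            "direction": direc.value,
                            "variant": bset.overshoot_variant.value,
                            "restart": restart,
                            "cost": cost,
                        },
                    )
                )

    if model_kind == "double":
        # deterministic nested-model candidate per direction in play
        for d_idx, direc in enumerate(directions):
            single_fit = fit(
                series,
                "single",
                replace(config, restarts=1),
                direction=direc,
            )
            x0 = _single_embedding(single_fit.theta_hat.to_array(), config)
            bset = make_bounds("double", direc, OvershootVariant.NO)
            x, cost, ok = _refine(x0, bset, y, n, config)
            runs.append(
                (
                    cost,
                    x,
                    bset,
                    ok,
                    {
                        "direction": direc.value,
                        "variant": bset.overshoot_variant.value,
                        "restart": "single-embedding",
                        "cost": cost,
                    },
                )
            )

    # lowest cost wins; a tie (within 1e-12) between overshoot variants goes
    # to the no-overshoot variant for the simpler interpretation
    def rank(run):
        cost, _, bset, _, _ = run
        prefer_no = 0 if bset.overshoot_variant is not OvershootVariant.YES else 1
        return (cost, prefer_no)

    best_cost = min(r[0] for r in runs)
    contenders = [r for r in runs if r[0] <= best_cost + 1e-12]
    cost, x, bset, converged, _ = min(contenders, key=rank)

    if model_kind == "single":
        theta = ThetaSingle.from_array(x)
        resid = y - eval_single(theta, n)
        penalty = 0.0
    else:
        theta = ThetaDouble.from_array(x)
        resid = y - eval_double(theta, n)
        penalty = sum(penalty_terms(theta, config))
    sse = float(resid @ resid)
    s = math.sqrt(sse / (series.n_strides - p))
    return FitResult(
        model_kind=model_kind,
        theta_hat=theta,
        sse=sse,
        residuals=resid,
        s=s,
        penalty_at_optimum=penalty,
        bound_set=bset,
        restart_costs=tuple(r[4] for r in runs),
        seed_used=config.seed,
        converged=converged,
        n_strides=series.n_strides,
    )
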