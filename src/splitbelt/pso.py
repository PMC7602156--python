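"""Seeded global-best particle swarm optimiser over box bounds.

Minimal, vectorised implementation: positions initialised uniformly within
the bounds (no user initial guess), constriction-style coefficients, particles
clipped to the box with their offending velocity component zeroed, and a
stall-based stop rule — the search ends once the relative improvement of the
best cost stays below ``tol`` for ``stall_iters`` consecutive iterations.
The swarm provides the coarse global stage of fitting; a derivative-based
bounded local stage polishes its best point afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["SwarmResult", "pso_minimize"]


@dataclass(frozen=True)
class SwarmResult:
    x: np.ndarray
    cost: float
    n_iters: int
    converged: bool  # stalled out (tolerance met) rather than hitting max_iters
    history: np.ndarray  # best cost per iteration


def pso_minimize(
    func: Callable[[np.ndarray], np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
    swarm_size: int = 100,
    max_iters: int = 1000,
    tol: float = 1e-3,
    stall_iters: int = 20,
    inertia: float = 0.7298,
    cognitive: float = 1.49618,
    social: float = 1.49618,
) -> SwarmResult:
    """Minimise ``func`` over the box [lower, upper].

    ``func`` must accept a (particles, dims) matrix and return a cost per
    particle.  Fully deterministic given ``rng``.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    dims = lower.size
    span = upper - lower

    x = lower + rng.uniform(size=(swarm_size, dims)) * span
    v = np.zeros_like(x)
    pbest_x = x.copy()
    pbest_cost = func(x)
    g = int(np.argmin(pbest_cost))
    gbest_x = pbest_x[g].copy()
    gbest_cost = float(pbest_cost[g])

    history = [gbest_cost]
    stall = 0
    n_iters = 0
    for n_iters in range(1, max_iters + 1):
        r1 = rng.uniform(size=(swarm_size, dims))
        r2 = rng.uniform(size=(swarm_size, dims))
        v = (
            inertia * v
            + cognitive * r1 * (pbest_x - x)
            + social * r2 * (gbest_x[None, :] - x)
        )
        x = x + v
        out_low = x < lower
        out_high = x > upper
        np.clip(x, lower, upper, out=x)
        v[out_low | out_high] = 0.0

        cost = func(x)
        improved = cost < pbest_cost
        pbest_x[improved] = x[improved]
        pbest_cost[improved] = cost[improved]
        g = int(np.argmin(pbest_cost))
        prev_best = gbest_cost
        if pbest_cost[g] < gbest_cost:
            gbest_cost = float(pbest_cost[g])
            gbest_x = pbest_x[g].copy()
        history.append(gbest_cost)

        rel_improve = (prev_best - gbest_cost) / max(abs(prev_best), 1e-12)
        stall = stall + 1 if rel_improve < tol else 0
        if stall >= stall_iters:
            return SwarmResult(
                x=gbest_x, cost=gbest_cost, n_iters=n_iters,
                converged=True, history=np.array(history),
            )
    return SwarmResult(
        x=gbest_x, cost=gbest_cost, n_iters=n_iters,
        converged=False, history=np.array(history),
    )
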