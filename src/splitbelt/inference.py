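"""Model selection (AIC) and confidence intervals for fitted trends.

AIC for the exponential models is 2k + N ln(SSE) with k counting the
regression parameters plus the residual variance (k = 4 single, k = 6
double); the double model is preferred only when its AIC undercuts the
single model's by more than 2.

Two interval flavours per parameter:

* linearized — theta_j +/- sqrt(V_jj) * t_{N-p, 1-alpha/2} with
  V = s^2 (J^T J)^{-1}, the standard first-order approximation;
* profile — the "exact" F-based interval: the two roots of

      (N - p) * (S~(theta_j*) - S(theta^)) / S(theta^) = F_{1-alpha}(1, N-p)

  where S~ re-minimises the SSE over the remaining parameters with the j-th
  one held fixed.  Roots are bracketed between the estimate and the fitting
  bound, the bracket end is pushed out to +/-100 when no sign change is
  found, and an endpoint with no root in the extended range is reported as
  undefined ("UD").

Interval comparison follows the no-overlap rule: disjoint intervals are read
as a statistically significant difference; any overlap — including overlap
that cannot be ruled out because an endpoint is undefined — is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .fitting import FitConfig, FitResult, refine_with_fixed
from .models import LN2, ThetaDouble, ThetaSingle, half_change_strides
from .series_io import SymmetrySeries

__all__ = [
    "AICResult",
    "IntervalEstimate",
    "LinearizationArtifacts",
    "aic",
    "select_model",
    "jacobian",
    "linearization",
    "ci_linearized",
    "profile_interval",
    "ci_profile",
    "compare_intervals",
    "common_language_intervals",
]

PROFILE_EXTENSION = 100.0  # far bracket ends are pushed to +/-10^2


def aic(fit: FitResult, k: int | None = None) -> float:
    """Akaike's information criterion 2k + N ln(SSE).

    k counts estimated parameters including the residual variance: 4 for the
    single and 6 for the double exponential model.  A perfect fit (SSE = 0)
    has no finite AIC under this formula.
    """
    if k is None:
        k = 4 if fit.model_kind == "single" else 6
    if fit.sse <= 0:
        raise ValueError("AIC undefined for SSE <= 0 (perfect fit)")
    return 2.0 * k + fit.n_strides * math.log(fit.sse)


@dataclass(frozen=True)
class AICResult:
    aic_single: float
    aic_double: float
    delta: float  # aic_double - aic_single
    selected: str  # "single" | "double"
    k_single: int = 4
    k_double: int = 6

    def to_json(self) -> dict:
        return {
            "aic_single": self.aic_single,
            "aic_double": self.aic_double,
            "delta": self.delta,
            "selected": self.selected,
            "k_single": self.k_single,
            "k_double": self.k_double,
        }


def select_model(fit_single: FitResult, fit_double: FitResult) -> AICResult:
    """Apply the delta-AIC rule: pick the double model iff its AIC is more
    than 2 below the single model's (delta strictly less than -2; a delta of
    exactly -2 keeps the single model)."""
    if fit_single.n_strides != fit_double.n_strides:
        raise ValueError("fits compare different series lengths")
    a1 = aic(fit_single, 4)
    a2 = aic(fit_double, 6)
    delta = a2 - a1
    return AICResult(
        aic_single=a1,
        aic_double=a2,
        delta=delta,
        selected="double" if delta < -2.0 else "single",
    )


# ---------------------------------------------------------------------------
# Linearized intervals


def jacobian(theta: ThetaSingle | ThetaDouble, n_strides: int) -> np.ndarray:
    """Sensitivity matrix of the trend to its parameters, row per stride.

    Single model row n: [e^{bn}, a n e^{bn}, 1]; double model row n:
    [e^{bs n}, as n e^{bs n}, e^{bf n}, af n e^{bf n}, 1].
    """
    n = np.arange(1, int(n_strides) + 1, dtype=float)
    if isinstance(theta, ThetaSingle):
        e = np.exp(theta.b * n)
        return np.column_stack([e, theta.a * n * e, np.ones_like(n)])
    es = np.exp(theta.bs * n)
    ef = np.exp(theta.bf * n)
    return np.column_stack(
        [es, theta.as_ * n * es, ef, theta.af * n * ef, np.ones_like(n)]
    )


@dataclass(frozen=True)
class LinearizationArtifacts:
    jacobian: np.ndarray
    s2: float
    vcov: np.ndarray | None  # None when J^T J is numerically singular
    p: int
    condition_number: float


def linearization(fit: FitResult) -> LinearizationArtifacts:
    """Jacobian, residual variance and linearized covariance of a fit."""
    J = jacobian(fit.theta_hat, fit.n_strides)
    p = fit.n_params
    s2 = fit.sse / (fit.n_strides - p)
    JtJ = J.T @ J
    cond = float(np.linalg.cond(JtJ))
    vcov = None
    if np.isfinite(cond) and cond < 1e12:
        vcov = s2 * np.linalg.inv(JtJ)
    return LinearizationArtifacts(
        jacobian=J, s2=s2, vcov=vcov, p=p, condition_number=cond
    )


@dataclass(frozen=True)
class IntervalEstimate:
    """A (1-alpha) confidence interval; undefined endpoints are None ("UD")."""

    estimate: float
    lower: float | None
    upper: float | None
    alpha: float = 0.05
    method: str = "linearized"
    note: str = ""

    @property
    def width(self) -> float | None:
        if self.lower is None or self.upper is None:
            return None
        return self.upper - self.lower

    def to_json(self) -> dict:
        return {
            "estimate": self.estimate,
            "lower": "UD" if self.lower is None else self.lower,
            "upper": "UD" if self.upper is None else self.upper,
            "alpha": self.alpha,
            "method": self.method,
            "note": self.note,
        }


def t_intervals(
    J: np.ndarray,
    sse: float,
    estimates: np.ndarray,
    alpha: float = 0.05,
    note: str = "",
) -> list[IntervalEstimate]:
    """Linearization t-intervals from an explicit design/Jacobian matrix."""
    n_obs, p = J.shape
    if n_obs <= p:
        raise ValueError("need more observations than parameters")
    s2 = sse / (n_obs - p)
    JtJ = J.T @ J
    cond = float(np.linalg.cond(JtJ))
    if not np.isfinite(cond) or cond >= 1e12:
        return [
            IntervalEstimate(
                estimate=float(est),
                lower=None,
                upper=None,
                alpha=alpha,
                method="linearized",
                note=f"J^T J numerically singular (cond={cond:.3g})",
            )
            for est in estimates
        ]
    vcov = s2 * np.linalg.inv(JtJ)
    tq = stats.t.ppf(1.0 - alpha / 2.0, n_obs - p)
    out = []
    for j, est in enumerate(np.asarray(estimates, dtype=float)):
        half = tq * math.sqrt(max(vcov[j, j], 0.0))
        out.append(
            IntervalEstimate(
                estimate=est,
                lower=est - half,
                upper=est + half,
                alpha=alpha,
                method="linearized",
                note=note,
            )
        )
    return out


def ci_linearized(fit: FitResult, alpha: float = 0.05) -> dict[str, IntervalEstimate]:
    """Linearized intervals for every regression parameter of a fit."""
    J = jacobian(fit.theta_hat, fit.n_strides)
    estimates = fit.theta_hat.to_array()
    intervals = t_intervals(J, fit.sse, estimates, alpha=alpha)
    return dict(zip(fit.theta_hat.names, intervals))


# ---------------------------------------------------------------------------
# Profile (F-based) intervals


def profile_interval(
    profile_sse: Callable[[float], float],
    estimate: float,
    sse_hat: float,
    n_obs: int,
    p: int,
    bracket_lower: float,
    bracket_upper: float,
    alpha: float = 0.05,
    extend_to: float = PROFILE_EXTENSION,
    note: str = "",
) -> IntervalEstimate:
    """Invert the F-statistic for one parameter given its SSE profile.

    ``profile_sse(v)`` must return the SSE minimised over all remaining
    parameters with the profiled one fixed at ``v``.  Each endpoint is the
    root of g(v) = (N-p)(S~(v) - S)/S - F_{1-alpha}(1, N-p) bracketed between
    the estimate and the corresponding fitting bound; if g does not change
    sign there the far end is extended toward +/-``extend_to``, and if it
    still does not, the endpoint is undefined.
    """
    if n_obs <= p:
        raise ValueError("need more observations than parameters")
    if sse_hat <= 0:
        return IntervalEstimate(
            estimate=estimate, lower=None, upper=None, alpha=alpha,
            method="profile", note="zero SSE at the estimate: F statistic undefined",
        )
    nu = n_obs - p
    fq = stats.f.ppf(1.0 - alpha, 1, nu)

    def g(v: float) -> float:
        return nu * (profile_sse(v) - sse_hat) / sse_hat - fq

    def solve(side: str) -> tuple[float | None, str]:
        far = bracket_lower if side == "lower" else bracket_upper
        near = estimate
        if far == near:
            far = near  # degenerate bracket; forces extension below
        try:
            g_far = g(far) if far != near else -fq
        except Exception as err:  # inner re-optimisation failure
            return None, f"{side}: profile optimisation failed ({err})"
        if not (g_far > 0):
            far = -extend_to if side == "lower" else extend_to
            try:
                g_far = g(far)
            except Exception as err:
                return None, f"{side}: profile optimisation failed ({err})"
            if not (g_far > 0):
                return None, f"{side}: no sign change up to {far:g}"
        lo, hi = (far, near) if side == "lower" else (near, far)
        xtol = 1e-8 * max(abs(hi - lo), 1.0)
        root = brentq(g, lo, hi, xtol=xtol)
        return float(root), ""

    lower, note_lo = solve("lower")
    upper, note_up = solve("upper")
    notes = "; ".join(s for s in (note, note_lo, note_up) if s)
    return IntervalEstimate(
        estimate=estimate, lower=lower, upper=upper,
        alpha=alpha, method="profile", note=notes,
    )


def ci_profile(
    fit: FitResult,
    series: SymmetrySeries,
    param_index: int,
    alpha: float = 0.05,
    config: FitConfig | None = None,
) -> IntervalEstimate:
    """Profile interval for one regression parameter of a fitted model.

    The inner re-optimisations warm-start from the full estimate (and from
    the best solution found at the nearest previously profiled value), using
    the bounded local refinement stage; the profiled value itself may leave
    the fitting box when the bracket is extended.
    """
    config = config or FitConfig()
    theta_hat = fit.theta_hat.to_array()
    estimate = float(theta_hat[param_index])
    cache: dict[float, np.ndarray] = {estimate: theta_hat}

    def profile_sse(v: float) -> float:
        # warm start from the solution at the nearest already-profiled value
        nearest = min(cache, key=lambda kv: abs(kv - v))
        start = cache[nearest].copy()
        start[param_index] = v
        full, sse = refine_with_fixed(
            series, fit.model_kind, start, fit.bound_set, param_index, v, config
        )
        if nearest != estimate:
            # guard against a poor warm start: also try from the estimate
            start2 = theta_hat.copy()
            start2[param_index] = v
            full2, sse2 = refine_with_fixed(
                series, fit.model_kind, start2, fit.bound_set, param_index, v, config
            )
            if sse2 < sse:
                full, sse = full2, sse2
        cache[v] = full
        return sse

    return profile_interval(
        profile_sse,
        estimate,
        fit.sse,
        fit.n_strides,
        fit.n_params,
        float(fit.bound_set.lower[param_index]),
        float(fit.bound_set.upper[param_index]),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Interval comparison


@dataclass(frozen=True)
class IntervalComparison:
    overlap: str  # "yes" | "no"
    significant: bool
    verdict: str

    def to_json(self) -> dict:
        return {
            "overlap": self.overlap,
            "significant": self.significant,
            "verdict": self.verdict,
        }


def compare_intervals(i1: IntervalEstimate, i2: IntervalEstimate) -> IntervalComparison:
    """No-overlap inference on two confidence intervals.

    Only provably disjoint intervals count as a significant difference; an
    undefined endpoint extends its interval indefinitely on that side, so
    overlap can then never be ruled out (reported as overlapping,
    indeterminate).
    """
    disjoint = False
    if i1.upper is not None and i2.lower is not None and i1.upper < i2.lower:
        disjoint = True
    if i2.upper is not None and i1.lower is not None and i2.upper < i1.lower:
        disjoint = True
    if disjoint:
        return IntervalComparison("no", True, "significant (no CI overlap)")
    undefined = any(
        v is None for v in (i1.lower, i1.upper, i2.lower, i2.upper)
    )
    if undefined:
        return IntervalComparison(
            "yes", False, "not significant (overlap indeterminate: UD endpoint)"
        )
    return IntervalComparison("yes", False, "not significant (CIs overlap)")


# ---------------------------------------------------------------------------
# Common-language interval assembly


def _rate_to_strides_interval(
    rate_ci: IntervalEstimate, rate_hat: float
) -> IntervalEstimate:
    """Map a rate-constant CI onto strides-to-50%-change.

    strides = floor(ln2/|b|) is monotone increasing in b on b < 0 (a rate
    closer to zero means a slower trend, hence more strides), so interval
    endpoints map endpoint-wise; a rate endpoint at or above zero has no
    finite stride count (UD).
    """

    def to_strides(b: float | None) -> int | None:
        if b is None or b >= 0:
            return None
        return half_change_strides(b)

    return IntervalEstimate(
        estimate=half_change_strides(rate_hat),
        lower=to_strides(rate_ci.lower),
        upper=to_strides(rate_ci.upper),
        alpha=rate_ci.alpha,
        method=rate_ci.method,
        note="transformed from the rate-constant interval",
    )


def common_language_intervals(
    fit: FitResult,
    series: SymmetrySeries,
    alpha: float = 0.05,
    method: str = "profile",
    config: FitConfig | None = None,
) -> dict[str, IntervalEstimate]:
    """Intervals for the common-language quantities of a fit.

    Quantities that are monotone transforms of a single parameter carry the
    transformed interval of that parameter (final asymmetry from c, strides
    to 50% change from the rates).  Multi-parameter transforms (initial
    asymmetry, total change, overshoot) would need the transformed quantity
    itself to be profiled; their endpoints are reported as undefined with an
    explanatory note.
    """
    names = fit.theta_hat.names
    if method == "profile":
        per_param = {
            name: ci_profile(fit, series, j, alpha=alpha, config=config)
            for j, name in enumerate(names)
        }
    elif method == "linearized":
        per_param = ci_linearized(fit, alpha=alpha)
    else:
        raise ValueError(f"unknown interval method {method!r}")

    theta = fit.theta_hat
    out: dict[str, IntervalEstimate] = {}
    multi_note = (
        "depends on several parameters; interval not available from "
        "single-parameter profiling"
    )
    if fit.model_kind == "single":
        out["final_asymmetry"] = per_param["c"]
        out["half_change_strides"] = _rate_to_strides_interval(
            per_param["b"], theta.b
        )
        out["total_change"] = per_param["a"]
        out["initial_asymmetry"] = IntervalEstimate(
            estimate=theta.a + theta.c, lower=None, upper=None,
            alpha=alpha, method=method, note=multi_note,
        )
    else:
        out["final_asymmetry"] = per_param["c"]
        out["half_change_strides_slow"] = _rate_to_strides_interval(
            per_param["bs"], theta.bs
        )
        out["half_change_strides_fast"] = _rate_to_strides_interval(
            per_param["bf"], theta.bf
        )
        for key, est in (
            ("total_change", theta.as_ + theta.af),
            ("initial_asymmetry", theta.as_ + theta.af + theta.c),
        ):
            out[key] = IntervalEstimate(
                estimate=est, lower=None, upper=None,
                alpha=alpha, method=method, note=multi_note,
            )
    return out
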