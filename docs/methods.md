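# Methods

## Model

A symmetry series `y(n)`, `n = 1..N` strides, is modelled as an exponential
trend plus iid zero-mean Gaussian noise:

* single: `y(n) = a·e^{bn} + c + ε(n)`
* double: `y(n) = aₛ·e^{bₛn} + a_f·e^{b_f n} + c + ε(n)`, `ε(n) ~ N(0, σ²)`

Only decaying trends are admitted (`b, bₛ, b_f ≤ 0`): a growing exponential
has no finite asymptote and no sensible interpretation as a learning curve.
The double model decomposes learning into a fast process that vanishes
within tens of strides and a slow process spanning hundreds; with
opposite-sign amplitudes it can also represent an overshoot — the trend
swinging past its final value, located in closed form at the stride where
the first derivative vanishes. Constant residual variance across strides
and normality are model assumptions, checked visually via the diagnostics
module rather than by formal tests (the histogram can mislead; the QQ plot
carries the most weight).

## Parameter bounds and trend direction

Because symmetry lives in `[-1, 1]`: `c ∈ [-1, 1]`; total change at most 2
in magnitude, so `a ∈ [-2, 2]` and, per term of the double model,
amplitudes in `[-1, 1]`; rates in `[-ln 2, 0]` (half the change in a single
stride is already an impractical extreme). The direction from which the
series approaches its final value — the sign of
`mean(first w strides) - mean(last w strides)`, `w = min(50, ⌊N/2⌋)` —
halves each amplitude box; for the double model the overshoot variant
(opposite-sign amplitude boxes) and the no-overshoot variant are both fitted
and the lower cost kept. The 50-stride rule is a heuristic that can
misdetect on strongly non-monotone series; a zero mean-difference (or the
`direction=race` option) falls back to fitting under both directions and
keeping the lower cost. A fitted amplitude of exactly 0 is flagged as the
degenerate boundary case — a double exponential no better than a single.

## Objective and optimisation

The single model minimises the residual sum of squares subject to the box
bounds. The double model adds two penalties with weights
`λ₁ = λ₂ = 10³`:

* rate separation: `λ₁·max(0, b_f - bₛ + δ)²` with slack `δ = 10⁻³`, which
  both enforces the fast/slow ordering and closes the open set `b_f < bₛ`
  (at `b_f = bₛ` the penalty is exactly `10⁻³`);
* total change: `λ₂·max(0, |aₛ + a_f| - 2)²`.

The reported SSE always excludes the penalties (AIC, the residual scale
`s = √(SSE/(N-p))` with `p` = 3 or 5 regression parameters, and the profile
statistic all consume the pure `Σε̂²`); the penalty value at the optimum is
reported separately and is at most `10⁻³` for any accepted fit.

Each run is two-stage: a global-best particle swarm (100 particles,
positions initialised uniformly in the box, constriction-style coefficients
0.7298 / 1.49618 / 1.49618, particles clipped to the box, stopped once the
best cost improves by less than the coarse tolerance `10⁻³` relatively for
20 consecutive iterations, capped at 1000) seeds a bounded
trust-region-reflective least-squares polish with analytic Jacobians and
cost tolerance `10⁻⁶`. The penalties enter the local stage as extra
residual rows `√λ·max(0, g)`, so the penalized objective stays an exact sum
of squares. The whole procedure runs twice from fresh random swarms
(restart seeds: master, master + 1; direction/variant runs use deterministic
sub-streams of the same master seed), and for the double model one extra
deterministic candidate — the single-model solution embedded as
`aₛ = a_f = a/2`, rates `b` and `b - δ` — is polished under the
no-overshoot bounds. That candidate guarantees the nesting property
SSE(double) ≤ SSE(single) up to the local tolerance regardless of swarm
luck. Ties between overshoot variants (within `10⁻¹²`) resolve to the
no-overshoot variant for the simpler interpretation. Identical seeds and
inputs give bitwise-identical results.

## Model selection and inference

`AIC = 2k + N ln(SSE)`, `k = 4`/`6` counting the residual variance; the
double model is selected iff `ΔAIC < -2` strictly (a delta of exactly −2
keeps the single model). Intervals:

* linearized: `θ̂ⱼ ± √V̂ⱼⱼ·t_{N-p,1-α/2}`, `V̂ = s²(JᵀJ)⁻¹` with the analytic
  Jacobian; a condition number of `JᵀJ` above `10¹²` yields undefined
  endpoints with a diagnostic rather than garbage numbers;
* profile: each endpoint is the root of
  `(N-p)(S̃(θⱼ*) - S)/S - F₁₋α(1, N-p)`, bracketed between the estimate and
  the fitting bound of `θⱼ`, with the far end extended toward ±10² when no
  sign change is found there, and reported "UD" when the extended range
  still contains no root. Roots come from a bracketing solver (Brent) with
  tolerance `10⁻⁸` relative to the bracket span; inner re-minimisations fix
  `θⱼ*` (which may leave the fitting box during extension), keep the other
  parameters bounded, and warm-start from the full estimate and from the
  solution at the nearest previously profiled value, keeping the better of
  the two.

For a model linear in its parameters the two methods coincide through
`F(1, ν) = t²_ν`; the test suite checks this identity on the pure-mean
model in closed form. No-overlap of two 95% intervals is read as a
significant difference; overlap, or indeterminacy due to a "UD" endpoint,
is not. No multiple-comparison correction is applied — a documented
limitation of the interval-overlap heuristic.

Common-language quantities that are monotone transforms of a single
parameter inherit that parameter's interval (final asymmetry from `c`;
strides-to-50% from each rate, endpoint-wise through `⌊ln 2/|b|⌋`).
Initial asymmetry, total change (double model) and the overshoot depend on
several parameters jointly; profiling them would require reparametrising
the objective in the transformed quantity, which this package does not do —
their intervals are reported "UD" with an explanatory note.

## Synthetic data

The generator draws `y(n) = f(n; θ) + A·sin(2πn/T) + ε(n)` with seeded
Gaussian noise; the sinusoid (off by default) emulates the cyclic residual
trends visible in participant-level series, and the periodogram of
residuals from an exponential fit recovers the injected frequency to within
one bin. A spec whose trend ±4σ (plus cyclic amplitude) leaves `[-1, 1]`
is rejected outright instead of clipping draws, which would silently
distort the Gaussian residual model. Four bundled regimes emulate the
magnitudes of published group-averaged fits — residual SD 5–7×10⁻³,
750-stride adaptation and 500-stride de-adaptation, slow/fast half-lives
from ~4 to ~235 strides, one regime with a positive overshoot (half-lives
30/15, separated enough for the direction rule to hold). They are an
emulation of those study conditions, not a replication of any deposited
series. What passing tests on this generator shows is that the estimator
recovers parameters under the model's own assumptions; real series add
features the generator omits (autocorrelated and heteroscedastic residuals,
participant heterogeneity, missing strides), so performance there is not
implied.

## Numerical choices and study sizes

* group averaging truncates to the shortest participant series so each
  per-stride mean covers the same participants; NaN strides are rejected,
  not dropped, because dropping would shift the stride index entering the
  trend.
* stride indices start at 1; trends are evaluated at integer strides.
* `s` uses `N - p` degrees of freedom with `p` regression parameters (3/5);
  the AIC parameter counts (4/6) additionally include the residual
  variance.
* recovery/coverage studies in the tests use 100 seeded simulations at
  N = 750, σ = 0.006 (30 in the acceptance script); model-selection studies
  use 50 runs per truth (25 in the script); the nesting check uses 20
  simulated series across the four bundled regimes. These sizes are the
  package's own balance between Monte-Carlo stability and a fast default
  run.
* the moving-average smoother (odd window, shrinking at the edges) exists
  for plotting only and is never an input to fitting.

## Known limitations

The two-stage optimiser is stochastic in its search (not its result given a
seed): a pathological series could still end in a local minimum; the
penalty weights may need adjustment for outcome measures with other scales
(re-normalising into `[-1, 1]` is the recommended route). Near-equal rates
make the double model weakly identified — parameters then have wide or
undefined profile intervals even when transformed quantities (trend,
overshoot) are stable. Cyclic or autoregressive residual structure is
diagnosed but not modelled.
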