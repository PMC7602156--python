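"""Independent oracles used by the tests.

These deliberately avoid the package's analytic formulas: the overshoot is
located as the turning point of the trend — a derivative sign change on a
dense stride grid, refined with a bounded scalar search — and expected
interval endpoints come from textbook closed forms.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def double_exp(n, as_, bs, af, bf, c):
    n = np.asarray(n, dtype=float)
    return as_ * np.exp(bs * n) + af * np.exp(bf * n) + c


def brute_force_overshoot(as_, bs, af, bf, c, n_hi=300.0, grid=300_001):
    """Locate the trend's turning point on [0, n_hi] without the closed form.

    Scans a dense grid for a sign change of the numerical derivative and
    refines the bracketed extremum with a bounded scalar search.  Returns
    (n_star, y_star), or None when no interior turning point lies in the
    scanned range (the trend is monotone there).
    """
    ns = np.linspace(0.0, n_hi, grid)
    vals = double_exp(ns, as_, bs, af, bf, c)
    d = np.diff(vals)
    change = np.flatnonzero(d[:-1] * d[1:] < 0)
    if change.size == 0:
        return None
    i = int(change[0])
    lo, hi = ns[i], ns[i + 2]
    sign = 1.0 if d[i] > 0 else -1.0  # rising-then-falling => maximum
    res = minimize_scalar(
        lambda n: -sign * double_exp(n, as_, bs, af, bf, c),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    n_star = float(res.x)
    return n_star, float(double_exp(n_star, as_, bs, af, bf, c))


def sample_admissible_overshoot_theta(rng, require_turning_point=True):
    """Random double-exp parameters with opposite-sign amplitudes, separated
    decaying rates, and c = 0 — the admissible overshoot region.

    When ``require_turning_point`` is set, draws whose trend is monotone over
    the oracle's stride range (turning point before stride 0) are rejected
    so that grid extremisation and the closed form describe the same point.
    """
    ln2 = np.log(2.0)
    while True:
        mag_s = rng.uniform(0.1, 1.0)
        mag_f = rng.uniform(0.1, 1.0)
        sign = rng.choice([-1.0, 1.0])
        as_, af = sign * mag_s, -sign * mag_f
        bs = rng.uniform(-ln2 + 0.06, -0.01)
        bf = rng.uniform(-ln2, bs - 0.05)
        if abs(as_ + af) > 2.0:
            continue
        if require_turning_point and not abs(as_ * bs) < abs(af * bf):
            continue  # turning point sits at or before stride 0
        return as_, bs, af, bf, 0.0
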