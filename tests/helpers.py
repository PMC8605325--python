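"""Independent oracles shared by the unit and acceptance suites."""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.stats import binom


def barnard_oracle(n11: int, n12: int, n21: int, n22: int,
                   grid_points: int = 1001) -> float:
    """Full-enumeration Barnard p-value, independent of the package.

    Enumerates every outcome pair (x1, x2) with the observed row totals,
    computes the pooled-score statistic directly, and evaluates the joint
    binomial probability of the 'at least as extreme' set on the nuisance
    grid (plus bounded scalar refinement). No code is shared with
    ``mnlamina.stats``; probabilities come from scipy's binomial pmf.
    """
    n1, n2 = n11 + n12, n21 + n22
    x1 = np.arange(n1 + 1)[:, None]
    x2 = np.arange(n2 + 1)[None, :]
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, (x1 / n1 - x2 / n2) / np.sqrt(var), 0.0)
    extreme = np.abs(stat) >= abs(stat[n11, n21]) - 1e-12

    grid = np.linspace(0.0, 1.0, grid_points + 2)[1:-1]
    pm1 = binom.pmf(np.arange(n1 + 1)[None, :], n1, grid[:, None])
    pm2 = binom.pmf(np.arange(n2 + 1)[None, :], n2, grid[:, None])
    probs = np.einsum("gi,gj,ij->g", pm1, pm2, extreme.astype(float))

    def prob(pi: float) -> float:
        p1 = binom.pmf(np.arange(n1 + 1), n1, pi)
        p2 = binom.pmf(np.arange(n2 + 1), n2, pi)
        return float(np.outer(p1, p2)[extreme].sum())

    k = int(np.argmax(probs))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda p: -prob(p), bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    return float(min(max(probs[k], -res.fun), 1.0))


def interval_bool_oracle(intervals_a, intervals_b, length: int):
    """Base-pair boolean-array subtraction oracle for one chromosome."""
    cov_a = np.zeros(length, dtype=bool)
    cov_b = np.zeros(length, dtype=bool)
    for s, e in intervals_a:
        cov_a[s:e] = True
    for s, e in intervals_b:
        cov_b[s:e] = True
    return cov_a & ~cov_b
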