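"""Categorical and continuous test battery with family-test gating.

The testing policy: for three or more groups a family test is run first
(chi-squared for categorical data; one-way ANOVA when every group passes
Shapiro-Wilk normality, otherwise Kruskal-Wallis) and pairwise
comparisons are only performed when the family test rejects at alpha.
Pairwise categorical comparisons use Barnard's unconditional exact test;
pairwise continuous comparisons are Bonferroni corrected. Binary-binary
association strength is the phi (mean squared contingency) coefficient,
monotonic relationships use Spearman's rank correlation, and post-hoc
chi-square power is computed from the noncentral chi-square distribution.

Barnard's test is implemented here directly (pooled-score statistic,
nuisance-parameter maximisation over a 1001-point grid with
golden-section refinement); it is exact and unconditional: the p-value is
the supremum over the common success probability pi of the probability of
tables at least as extreme as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import optimize, special, stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "PowerSpec",
    "barnard_exact",
    "phi_coefficient",
    "chi_square_family",
    "hierarchical_compare",
    "spearman_rho",
    "chisq_power",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows = predictor (+ then -), columns = outcome (+ then -)."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.n11 + self.n12, self.n21 + self.n22)

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]])


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    adjusted: bool = False
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a post-hoc chi-square power computation.

    ``effect_w`` is Cohen's w; ``N_total`` the pooled sample size.
    """

    effect_w: float
    N_total: int
    df: int
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if self.effect_w < 0 or self.N_total < 1 or self.df < 1:
            raise ValueError("invalid power spec")


# ---------------------------------------------------------------------------
# Barnard's unconditional exact test
# ---------------------------------------------------------------------------

def _score_statistics(n1: int, n2: int) -> np.ndarray:
    """Pooled-score statistic for every table with fixed row totals.

    Entry [x1, x2] is T = (x1/n1 - x2/n2) / sqrt(p(1-p)(1/n1 + 1/n2))
    with p the pooled proportion; 0 where the pooled variance vanishes.
    """
    x1 = np.arange(n1 + 1)[:, None]
    x2 = np.arange(n2 + 1)[None, :]
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    return t


def _extreme_coeffs(n1: int, n2: int, extreme: np.ndarray) -> np.ndarray:
    """Coefficients c_s of the nuisance polynomial.

    P(extreme | pi) = sum_s c_s pi^s (1-pi)^(n1+n2-s) where
    c_s = sum over extreme tables with x1+x2 = s of C(n1,x1) C(n2,x2).
    """
    c1 = special.comb(n1, np.arange(n1 + 1))
    c2 = special.comb(n2, np.arange(n2 + 1))
    weights = np.outer(c1, c2) * extreme
    s_idx = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
    coeffs = np.zeros(n1 + n2 + 1)
    np.add.at(coeffs, s_idx.ravel(), weights.ravel())
    return coeffs


def _poly_prob(coeffs: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Evaluate the nuisance polynomial at pi, stably in log space."""
    n = len(coeffs) - 1
    s = np.arange(n + 1)
    pi = np.atleast_1d(pi)
    with np.errstate(divide="ignore"):
        logterm = (s[None, :] * np.log(pi[:, None])
                   + (n - s)[None, :] * np.log1p(-pi[:, None]))
    mask = coeffs > 0
    vals = np.zeros(len(pi))
    if mask.any():
        logc = np.log(coeffs[mask])
        m = logc[None, :] + logterm[:, mask]
        mx = m.max(axis=1)
        vals = np.exp(mx) * np.exp(m - mx[:, None]).sum(axis=1)
    return np.minimum(vals, 1.0)


def barnard_exact(t: ContingencyTable2x2,
                  alternative: str = "two-sided",
                  grid_points: int = 1001) -> TestResult:
    """Barnard's unconditional exact test on a 2x2 table.

    Columns are treated as (success, failure) within each row; the test
    compares the two row success probabilities using the pooled-variance
    score statistic, maximising the tail probability over the common
    nuisance success probability pi (dense grid plus golden-section
    refinement around the grid optimum).
    """
    n1, n2 = t.row_totals
    if n1 == 0 or n2 == 0:
        raise ValueError("both row totals must be positive")
    if alternative not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    stats_all = _score_statistics(n1, n2)
    t_obs = stats_all[t.n11, t.n21]
    eps = 1e-12
    if alternative == "two-sided":
        extreme = np.abs(stats_all) >= np.abs(t_obs) - eps
    elif t_obs >= 0:
        extreme = stats_all >= t_obs - eps
    else:
        extreme = stats_all <= t_obs + eps
    coeffs = _extreme_coeffs(n1, n2, extreme)
    grid = np.linspace(0.0, 1.0, grid_points + 2)[1:-1]
    probs = _poly_prob(coeffs, grid)
    k = int(np.argmax(probs))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda pi: -_poly_prob(coeffs, pi)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    p = float(min(max(probs[k], -res.fun), 1.0))
    p = max(p, np.finfo(float).tiny)
    return TestResult(statistic=float(t_obs), p_value=p,
                      method="barnard-exact", extra={"alternative": alternative})


# ---------------------------------------------------------------------------
# Association and family tests
# ---------------------------------------------------------------------------

def phi_coefficient(t: ContingencyTable2x2) -> float:
    """Phi (mean squared contingency) coefficient of a 2x2 table.

    phi = (n11 n22 - n12 n21) / sqrt of the product of all four marginals.
    The sign follows the fixed table orientation (rows = predictor with
    the positive level first); callers must orient tables accordingly.
    """
    a, b, c, d = t.n11, t.n12, t.n21, t.n22
    marginals = [(a + b), (c + d), (a + c), (b + d)]
    if min(marginals) == 0:
        raise ValueError("phi undefined: a marginal total is zero")
    return float((a * d - b * c) / np.sqrt(np.prod([float(m) for m in marginals])))


def chi_square_family(table: np.ndarray) -> TestResult:
    """Pearson chi-squared family test on a k x 2 count table.

    df = k - 1. The result is flagged invalid when the table contains a
    zero cell or when more than one expected count falls below five,
    mirroring the stated validity limits of the chi-square test.
    """
    obs = np.asarray(table, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] != 2:
        raise ValueError("need a k x 2 table with k >= 2")
    if obs.sum() == 0:
        raise ValueError("zero grand total")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    flags = []
    if (obs == 0).any():
        flags.append("zero-cell: chi-square not applicable")
    if (expected < 5).sum() > 1:
        flags.append("expected-count<5 in multiple cells")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    df = obs.shape[0] - 1
    return TestResult(statistic=stat, p_value=float(sps.chi2.sf(stat, df)),
                      method="chi-square-family", df=df, flags=flags)


def _pairwise_categorical(table: np.ndarray, alpha: float) -> list[TestResult]:
    k = table.shape[0]
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        t2 = ContingencyTable2x2(*map(int, (*table[i], *table[j])))
        res = barnard_exact(t2)
        res.p_value = min(1.0, res.p_value * m)
        res.adjusted = True
        res.extra["pair"] = (i, j)
        out.append(res)
    return out


def hierarchical_compare(groups, alpha: float = 0.05,
                         kind: str = "categorical") -> dict:
    """Family test followed, on rejection only, by pairwise comparisons.

    Categorical path: ``groups`` is a k x 2 count table; family test is
    Pearson chi-squared, pairwise tests are Bonferroni-adjusted Barnard.
    Continuous path: ``groups`` is a list of observation vectors; each
    group is checked with Shapiro-Wilk, one-way ANOVA is used when all
    groups look normal, Kruskal-Wallis otherwise, and pairwise tests
    (Welch t / Mann-Whitney, matching the family branch) are Bonferroni
    adjusted. Returns ``{"family": TestResult, "pairwise": [...],
    "branch": str}``; pairwise is empty unless family p < alpha.
    """
    if kind == "categorical":
        table = np.asarray(groups)
        family = chi_square_family(table)
        pairwise = _pairwise_categorical(table, alpha) \
            if family.p_value < alpha else []
        return {"family": family, "pairwise": pairwise, "branch": "chi-square"}
    if kind != "continuous":
        raise ValueError(f"unknown kind {kind!r}")
    samples = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 3 for g in samples):
        raise ValueError("each continuous group needs >= 3 observations")
    normal = all(sps.shapiro(g).pvalue >= alpha for g in samples)
    if normal:
        stat, p = sps.f_oneway(*samples)
        family = TestResult(float(stat), float(p), "anova",
                            df=len(samples) - 1)
        branch = "anova"
    else:
        stat, p = sps.kruskal(*samples)
        family = TestResult(float(stat), float(p), "kruskal-wallis",
                            df=len(samples) - 1)
        branch = "kruskal-wallis"
    pairwise: list[TestResult] = []
    if family.p_value < alpha:
        pairs = list(combinations(range(len(samples)), 2))
        for i, j in pairs:
            if branch == "anova":
                s, pv = sps.ttest_ind(samples[i], samples[j], equal_var=False)
                method = "welch-t"
            else:
                s, pv = sps.mannwhitneyu(samples[i], samples[j],
                                         alternative="two-sided")
                method = "mann-whitney"
            pairwise.append(TestResult(float(s), min(1.0, float(pv) * len(pairs)),
                                       method, adjusted=True,
                                       extra={"pair": (i, j)}))
    return {"family": family, "pairwise": pairwise, "branch": branch}


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def chisq_power(spec: PowerSpec) -> float:
    """Power of the chi-square test at effect size w and sample size N.

    Power = P( X > q ) with X ~ noncentral chi2(df, lambda = N w^2) and q
    the alpha upper quantile of the central chi2(df).
    """
    crit = sps.chi2.ppf(1.0 - spec.alpha, spec.df)
    lam = spec.N_total * spec.effect_w ** 2
    if lam == 0:
        return float(spec.alpha)
    return float(sps.ncx2.sf(crit, spec.df, lam))
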