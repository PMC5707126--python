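"""Statistical procedures shared by the screening and expression modules.

Each test returns a :class:`TestResult`. Procedures (rank handling, exact
enumeration, hypergeometric summation, step-up adjustment) are implemented
here; only textbook distribution functions (normal, chi-square, F,
studentized range) are delegated to :mod:`scipy`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats as _sps

__all__ = [
    "TestResult",
    "z_test_case_vs_controls",
    "bonferroni",
    "mann_whitney_u",
    "bh_fdr",
    "fisher_exact_2x2",
    "chi_square_yates",
    "anova_oneway",
    "tukey_hsd",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...] = ()
    correction: str = "none"
    degenerate: bool = False
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def z_test_case_vs_controls(x: float, controls: Sequence[float]) -> TestResult:
    """Two-sided z-test of a single case value against a control sample.

    z = (x - mean) / sd with the n-1 sample standard deviation. A zero
    control sd makes the test degenerate: p = 0 if the case departs from the
    control mean (flagged for manual review), p = 1 otherwise.
    """
    ctrl = np.asarray(controls, dtype=float)
    if ctrl.size < 2:
        raise ValueError("need >= 2 control values")
    mean = float(ctrl.mean())
    sd = float(ctrl.std(ddof=1))
    if sd == 0.0:
        if x == mean:
            return TestResult(0.0, 1.0, "z-test", (1, ctrl.size), degenerate=True)
        return TestResult(math.inf if x > mean else -math.inf, 0.0, "z-test",
                          (1, ctrl.size), degenerate=True)
    z = (x - mean) / sd
    p = 2.0 * _norm_sf(abs(z))
    return TestResult(z, min(1.0, p), "z-test", (1, ctrl.size))


def bonferroni(p: float, m: int) -> float:
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * m)


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _mwu_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = _midranks(np.concatenate([x, y]))
    rx = ranks[: len(x)].sum()
    return rx - len(x) * (len(x) + 1) / 2.0


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_max_n: int = 16) -> TestResult:
    """Two-sided Mann-Whitney U with midranks for ties.

    Exact p by enumeration of all rank assignments when the pooled size is
    at most ``exact_max_n``; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    u = _mwu_statistic(x, y)
    mu = nx * ny / 2.0

    if nx + ny <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(nx + ny)
        obs_dev = abs(u - mu)
        hits = total = 0
        for combo in itertools.combinations(idx, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(combo)] = True
            u_perm = _mwu_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-9:
                hits += 1
        return TestResult(u, hits / total, "mann-whitney-exact", (nx, ny))

    # normal approximation, tie-corrected variance
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    n = nx + ny
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, "mann-whitney-normal", (nx, ny), degenerate=True)
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * _norm_sf(z))
    return TestResult(u, p, "mann-whitney-normal", (nx, ny))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    # P(table | margins) for top-left cell = a
    n = r1 + r2
    return (
        special.gammaln(r1 + 1) - special.gammaln(a + 1) - special.gammaln(r1 - a + 1)
        + special.gammaln(r2 + 1) - special.gammaln(c1 - a + 1)
        - special.gammaln(r2 - c1 + a + 1)
        - (special.gammaln(n + 1) - special.gammaln(c1 + 1) - special.gammaln(n - c1 + 1))
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-tailed Fisher exact test by probability-mass summation.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (within
    relative tolerance 1e-7).
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    p = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(k, r1, r2, c1)
        if lp <= log_obs + 1e-7:
            p += math.exp(lp)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(odds, min(1.0, p), "fisher-exact", (r1, r2))


def chi_square_yates(table: Sequence[Sequence[int]]) -> TestResult:
    """Yates-corrected chi-square for a 2x2 table, 1 df, upper tail."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return TestResult(0.0, 1.0, "chi2-yates", (r1, r2), degenerate=True)
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * num * num / (r1 * r2 * c1 * c2)
    p = float(special.chdtrc(1, chi2))
    return TestResult(chi2, min(1.0, p), "chi2-yates", (r1, r2))


def anova_oneway(*groups: Sequence[float]) -> TestResult:
    """One-way unweighted ANOVA; F from between/within mean squares."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = sum(len(g) for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(0.0, 1.0, "anova", tuple(len(g) for g in gs), degenerate=True)
        return TestResult(math.inf, 0.0, "anova", tuple(len(g) for g in gs), degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(_sps.f.sf(f, df_b, df_w))
    return TestResult(f, min(1.0, p), "anova", tuple(len(g) for g in gs))


def tukey_hsd(*groups: Sequence[float]) -> dict[tuple[int, int], TestResult]:
    """Tukey HSD pairwise comparisons with pooled within-group variance.

    Keys are (i, j) group-index pairs; p-values come from the studentized
    range distribution.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(gs)
    n = sum(len(g) for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_w = n - k
    ms_within = ss_within / df_w
    out: dict[tuple[int, int], TestResult] = {}
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(gs[i]), len(gs[j])
            if ms_within == 0:
                equal = gs[i].mean() == gs[j].mean()
                out[(i, j)] = TestResult(
                    0.0 if equal else math.inf, 1.0 if equal else 0.0,
                    "tukey-hsd", (ni, nj), degenerate=True)
                continue
            se = math.sqrt(ms_within / 2.0 * (1.0 / ni + 1.0 / nj))
            q = abs(gs[i].mean() - gs[j].mean()) / se
            p = float(_sps.studentized_range.sf(q, k, df_w))
            out[(i, j)] = TestResult(q, min(1.0, max(0.0, p)), "tukey-hsd", (ni, nj))
    return out
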