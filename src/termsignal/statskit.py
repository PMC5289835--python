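"""Shared statistical kernel: rank tests, correlation, least squares, curve fit.

The Wilcoxon rank-sum test is implemented to match the long-established
behaviour of mainstream statistical software: midranks for ties, exact null
enumeration (dynamic programming over the Mann-Whitney U distribution) for
small tie-free samples, and otherwise a normal approximation with
tie-corrected variance and a +/-0.5 continuity correction. The exact path is
cross-checked in the test suite against brute-force permutation enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TestResult",
    "OLSResult",
    "wilcoxon_rank_sum",
    "spearman",
    "ols",
    "saturating_fit",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test, with bookkeeping flags."""

    method: str
    statistic: float
    p_value: float
    two_tailed: bool
    n: tuple[int, ...]
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class OLSResult:
    slope: float
    intercept: float | None
    r_squared: float
    p_value: float
    n: int
    through_origin: bool = False


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum / Mann-Whitney
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _count_u(u: int, m: int, n: int) -> int:
    """Number of arrangements of m-vs-n tie-free ranks with Mann-Whitney U = u.

    Standard recursion c(u, m, n) = c(u - n, m - 1, n) + c(u, m, n - 1).
    """
    if u < 0 or u > m * n:
        return 0
    if m == 0 or n == 0:
        return 1 if u == 0 else 0
    return _count_u(u - n, m - 1, n) + _count_u(u, m, n - 1)


def exact_u_sf(u: int, m: int, n: int) -> float:
    """P(U >= u) under the exact tie-free null."""
    total = math.comb(m + n, m)
    return sum(_count_u(k, m, n) for k in range(u, m * n + 1)) / total


def exact_u_cdf(u: int, m: int, n: int) -> float:
    """P(U <= u) under the exact tie-free null."""
    total = math.comb(m + n, m)
    return sum(_count_u(k, m, n) for k in range(0, u + 1)) / total


def wilcoxon_rank_sum(
    x,
    y,
    continuity: bool = True,
    mode: str = "auto",
) -> TestResult:
    """Two-sample Wilcoxon rank-sum test, two-tailed.

    mode 'auto' uses exact enumeration when there are no ties and
    min(n_x, n_y) < 25; otherwise the normal approximation with
    tie-corrected variance (and continuity correction if requested).
    The statistic reported is the Mann-Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    u = float(ranks[:m].sum() - m * (m + 1) / 2.0)

    notes: dict = {"ties": has_ties, "continuity": continuity}
    if np.all(combined == combined[0]):
        notes["degenerate"] = "all values identical"
        return TestResult("wilcoxon rank sum", u, 1.0, True, (m, n), notes)

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (
        mode == "auto" and not has_ties and min(m, n) < 25
    )
    if use_exact and has_ties:
        # exact enumeration assumes distinct ranks; fall back, flag it
        notes["exact_unavailable"] = "ties present"
        use_exact = False

    mean = m * n / 2.0
    if use_exact:
        ui = int(round(u))
        if u > mean:
            p = 2.0 * exact_u_sf(ui, m, n)
        else:
            p = 2.0 * exact_u_cdf(ui, m, n)
        p = min(1.0, p)
        notes["method"] = "exact"
    else:
        N = m + n
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / (N * (N - 1))
        var = m * n / 12.0 * ((N + 1) - tie_term)
        notes["method"] = "normal"
        if var <= 0:
            notes["degenerate"] = "zero variance"
            return TestResult("wilcoxon rank sum", u, 1.0, True, (m, n), notes)
        cc = 0.5 if continuity else 0.0
        d = u - mean
        d -= math.copysign(min(cc, abs(d)), d)
        z = d / math.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        notes["z"] = z
    return TestResult("wilcoxon rank sum", u, p, True, (m, n), notes)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> TestResult:
    """Spearman rank correlation (midranks), with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be the same length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            "spearman", float("nan"), float("nan"), True, (n,),
            {"degenerate": "constant input"},
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return TestResult("spearman", rho, min(1.0, p), True, (n,))


# ---------------------------------------------------------------------------
# Ordinary least squares
# ---------------------------------------------------------------------------

def ols(x, y, through_origin: bool = False) -> OLSResult:
    """Simple least squares of y on x, with R^2 and a two-tailed slope test.

    Through-origin fits (as required for independent contrasts) compute R^2
    about zero and use n - 1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must be the same length")
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) and not through_origin:
        raise ValueError("constant x")
    if through_origin:
        sxx = float(x @ x)
        if sxx == 0:
            raise ValueError("x identically zero")
        slope = float(x @ y) / sxx
        resid = y - slope * x
        ssr = float(resid @ resid)
        sst = float(y @ y)
        df = n - 1
        se = math.sqrt(ssr / df / sxx) if ssr > 0 else 0.0
        intercept = None
    else:
        xm, ym = x.mean(), y.mean()
        sxx = float(((x - xm) ** 2).sum())
        if sxx == 0:
            raise ValueError("constant x")
        slope = float(((x - xm) * (y - ym)).sum()) / sxx
        intercept = ym - slope * xm
        resid = y - (intercept + slope * x)
        ssr = float(resid @ resid)
        sst = float(((y - ym) ** 2).sum())
        df = n - 2
        se = math.sqrt(ssr / df / sxx) if ssr > 0 else 0.0
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    if se == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return OLSResult(slope, intercept, r2, min(1.0, p), n, through_origin)


# ---------------------------------------------------------------------------
# Saturating (power-law) curve fit
# ---------------------------------------------------------------------------

def saturating_fit(x, y):
    """Least-squares fit of the monotone power curve y = a * x**b.

    Returns ((a, b), r_squared, converged). Initialised from a log-log
    regression over strictly positive points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    pos = (x > 0) & (y > 0)
    if pos.sum() >= 3 and not np.all(x[pos] == x[pos][0]):
        init = ols(np.log(x[pos]), np.log(y[pos]))
        p0 = (math.exp(init.intercept), init.slope)
    else:
        p0 = (1.0, 1.0)

    def curve(xv, a, b):
        return a * np.power(np.clip(xv, 1e-12, None), b)

    converged = True
    try:
        params, _ = optimize.curve_fit(curve, x, y, p0=p0, maxfev=10_000)
    except RuntimeError:
        params, converged = np.asarray(p0), False
    resid = y - curve(x, *params)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    return (float(params[0]), float(params[1])), r2, converged
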