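"""Statistical comparisons and density summaries used across the pipeline.

Thin, validated wrappers around :mod:`scipy.stats` plus the two-sided
variance F-test (which scipy does not provide as a two-sample function).
Every test returns a :class:`TestResult` so results serialize uniformly into
the run-level report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int = 0  # 0 for one-sample tests
    tails: str = "two"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "tails": self.tails,
        }


@dataclass
class DensityEstimate:
    """Gaussian-kernel density evaluated on a grid.

    ``bandwidth`` is the kernel standard deviation in data units.  The raw
    density integrates to ~1 over the grid; ``normalized_to_peak`` rescales
    the curve to a maximum of 1 for overlay plots.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    normalized_to_peak: bool = False

    def normalize_to_peak(self) -> "DensityEstimate":
        return DensityEstimate(
            grid=self.grid,
            density=self.density / self.density.max(),
            bandwidth=self.bandwidth,
            normalized_to_peak=True,
        )

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _clean(x, name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise InsufficientDataError(f"{name}: need at least {min_n} values, got {arr.size}")
    if np.any(~np.isfinite(arr)):
        raise DegenerateInputError(f"{name}: non-finite values present")
    return arr


def f_test_variance(x, y) -> TestResult:
    """Two-sided F-test for equality of variances.

    F = s2_x / s2_y with (n_x - 1, n_y - 1) degrees of freedom and
    p = 2 * min(P(F <= f), P(F >= f)), capped at 1.  Swapping the samples
    gives the reciprocal statistic and the identical p-value.
    """
    x = _clean(x, "x", 2)
    y = _clean(y, "y", 2)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        raise DegenerateInputError("variance F-test requires nonzero variance in both samples")
    f = vx / vy
    dist = stats.f(x.size - 1, y.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return TestResult("f_variance", float(f), float(min(p, 1.0)), x.size, y.size)


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    x = _clean(x, "x", 2)
    y = _clean(y, "y", 2)
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult("ks_two_sample", float(res.statistic), float(res.pvalue), x.size, y.size)


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = _clean(x, "x", 3)
    if x.size > 5000:
        raise InsufficientDataError("Shapiro-Wilk supports n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro-Wilk requires non-constant data")
    res = stats.shapiro(x)
    return TestResult("shapiro_wilk", float(res.statistic), float(res.pvalue), x.size)


def t_two_sample(x, y, *, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test (Student by default, Welch optional)."""
    x = _clean(x, "x", 2)
    y = _clean(y, "y", 2)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # degenerate-by-convention: identical constants are indistinguishable,
        # different constants are maximally distinguishable
        p = 1.0 if x[0] == y[0] else 0.0
        return TestResult("t_two_sample", 0.0 if p == 1.0 else np.inf, p, x.size, y.size)
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TestResult("t_two_sample", float(res.statistic), float(res.pvalue), x.size, y.size)


def gaussian_kde(
    x,
    grid=None,
    bandwidth: float | None = None,
    *,
    n_grid: int = 512,
    normalize_to_peak: bool = False,
) -> DensityEstimate:
    """Gaussian-kernel density estimate.

    The default bandwidth is Silverman's rule of thumb.  If no grid is given,
    the density is evaluated on ``n_grid`` points spanning the data range
    padded by four bandwidths, wide enough that the raw density integrates
    to ~1.
    """
    x = _clean(x, "x", 2)
    if np.var(x) == 0:
        raise DegenerateInputError("KDE requires nonzero variance")
    sd = np.std(x, ddof=1)
    if bandwidth is None:
        kde = stats.gaussian_kde(x, bw_method="silverman")
        h = float(kde.factor * sd)
    else:
        if bandwidth <= 0:
            raise DegenerateInputError("bandwidth must be > 0")
        h = float(bandwidth)
        kde = stats.gaussian_kde(x, bw_method=h / sd)
    if grid is None:
        grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    est = DensityEstimate(grid=grid, density=kde(grid), bandwidth=h)
    return est.normalize_to_peak() if normalize_to_peak else est


@dataclass
class ECDF:
    """Right-continuous empirical CDF: F(t) = #{x_i <= t} / n."""

    x: np.ndarray = field(repr=False)
    q: np.ndarray = field(repr=False)

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.searchsorted(self.x, t, side="right") / self.x.size
        return out if out.ndim else float(out)


def ecdf(x) -> ECDF:
    x = _clean(x, "x", 1)
    xs = np.sort(x)
    return ECDF(x=xs, q=np.arange(1, xs.size + 1) / xs.size)
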