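"""Paired method-comparison statistics.

Implements the agreement suite used to compare two counting methods on the
same samples:

* Pearson correlation (r, r²);
* Passing–Bablok regression — the shifted median of all pairwise slopes,
  with rank-based 95% confidence intervals (robust, no distributional
  assumption on either method's error);
* Bland–Altman analysis — mean difference (bias), its t-based 95% CI, and
  1.96 SD limits of agreement;
* subrange filtering to re-run the statistics on a concentration window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "PassingBablokResult",
    "BlandAltmanResult",
    "pearson",
    "passing_bablok",
    "bland_altman",
    "subrange",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired results of two methods on the same samples."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    label_x: str = "method A"
    label_y: str = "method B"

    def __init__(self, x, y, label_x="method A", label_y="method B"):
        xt = tuple(float(v) for v in x)
        yt = tuple(float(v) for v in y)
        if len(xt) != len(yt):
            raise ValueError("x and y must have equal length")
        if any(not math.isfinite(v) for v in xt + yt):
            raise ValueError("paired measurements must be finite")
        object.__setattr__(self, "x", xt)
        object.__setattr__(self, "y", yt)
        object.__setattr__(self, "label_x", label_x)
        object.__setattr__(self, "label_y", label_y)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class PassingBablokResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if not (self.slope_ci[0] <= self.slope <= self.slope_ci[1]):
            raise ValueError("slope CI must contain the slope")
        if not (self.intercept_ci[0] <= self.intercept <= self.intercept_ci[1]):
            raise ValueError("intercept CI must contain the intercept")


@dataclass
class BlandAltmanResult:
    mean_bias: float
    bias_ci: tuple[float, float]
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


# --------------------------------------------------------------------------

def pearson(pairs: PairedMeasurements) -> tuple[float, float]:
    """Product-moment correlation; returns (r, r²)."""
    if pairs.n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    x, y = np.asarray(pairs.x), np.asarray(pairs.y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def _shifted_median(sorted_vals: np.ndarray, offset: int) -> float:
    """Median of a sorted array shifted by ``offset`` ranks (1-based logic)."""
    n = sorted_vals.size
    if n % 2:
        idx = (n + 1) // 2 + offset
        return float(sorted_vals[np.clip(idx - 1, 0, n - 1)])
    i1 = np.clip(n // 2 + offset - 1, 0, n - 1)
    i2 = np.clip(n // 2 + offset, 0, n - 1)
    return float(0.5 * (sorted_vals[i1] + sorted_vals[i2]))


def passing_bablok(pairs: PairedMeasurements) -> PassingBablokResult:
    """Passing–Bablok regression of y on x.

    All pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i) for i < j are formed;
    pairs with x_i = x_j are excluded, as are slopes exactly equal to -1.
    The slope estimate is the median of the sorted slopes shifted by K, the
    number of slopes below -1 (which makes the estimator symmetric under
    swapping x and y).  The 95% CI comes from the normal-approximation rank
    bounds with variance n(n-1)(2n+5)/18; the intercept is
    median(y - slope*x), with its CI evaluated at the slope CI endpoints.
    """
    if pairs.n < 3:
        raise ValueError("Passing-Bablok needs n >= 3")
    x, y = np.asarray(pairs.x), np.asarray(pairs.y)
    n = pairs.n
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = dx != 0
    if not keep.any():
        raise ValueError("all x values identical: slope undefined")
    slopes = dy[keep] / dx[keep]
    slopes = slopes[slopes != -1.0]
    if slopes.size == 0:
        raise ValueError("no usable pairwise slopes")
    slopes.sort()
    big_n = slopes.size
    k_off = int(np.sum(slopes < -1.0))

    b = _shifted_median(slopes, k_off)

    # rank-based CI (normal approximation)
    w = stats.norm.ppf(0.975) * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    lo_idx = np.clip(m1 + k_off, 1, big_n)
    hi_idx = np.clip(m2 + k_off, 1, big_n)
    b_lo = float(slopes[lo_idx - 1])
    b_hi = float(slopes[hi_idx - 1])

    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    if a_lo > a_hi:
        a_lo, a_hi = a_hi, a_lo
    return PassingBablokResult(
        slope=b,
        slope_ci=(min(b_lo, b), max(b_hi, b)),
        intercept=a,
        intercept_ci=(min(a_lo, a), max(a_hi, a)),
        n=n,
    )


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Agreement via the paired differences d = y - x.

    Reports the mean bias, its t-based 95% CI (bias ± t_{0.975,n-1} s/√n),
    and limits of agreement at mean ± 1.96 x sample SD of the differences.
    """
    if pairs.n < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    d = np.asarray(pairs.y) - np.asarray(pairs.x)
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return BlandAltmanResult(
        mean_bias=bias,
        bias_ci=(bias - half, bias + half),
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=n,
    )


def subrange(
    pairs: PairedMeasurements,
    lo: float,
    hi: float,
    reference: str = "A",
) -> PairedMeasurements:
    """Restrict the pairs to those whose reference value lies in [lo, hi].

    ``reference`` selects which value defines membership: method ``"A"``
    (x, the comparator — the default), method ``"B"`` (y), or the pairwise
    ``"mean"``.
    """
    if lo > hi:
        raise ValueError(f"empty range [{lo}, {hi}]")
    if reference not in ("A", "B", "mean"):
        raise ValueError("reference must be 'A', 'B' or 'mean'")
    ref = {
        "A": np.asarray(pairs.x),
        "B": np.asarray(pairs.y),
        "mean": 0.5 * (np.asarray(pairs.x) + np.asarray(pairs.y)),
    }[reference]
    keep = (ref >= lo) & (ref <= hi)
    if not keep.any():
        raise ValueError(f"no pairs with {reference} value in [{lo}, {hi}]")
    return PairedMeasurements(
        x=tuple(np.asarray(pairs.x)[keep]),
        y=tuple(np.asarray(pairs.y)[keep]),
        label_x=pairs.label_x,
        label_y=pairs.label_y,
    )


def plot_bland_altman(pairs: PairedMeasurements, ax=None):
    """Difference-vs-mean plot with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    x = np.asarray(pairs.x)
    y = np.asarray(pairs.y)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(0.5 * (x + y), y - x, s=10)
    ax.axhline(res.mean_bias, color="k")
    for v in (res.loa_low, res.loa_high):
        ax.axhline(v, color="r", ls=":")
    ax.set_xlabel(f"mean of {pairs.label_x} and {pairs.label_y}")
    ax.set_ylabel(f"{pairs.label_y} - {pairs.label_x}")
    return ax
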