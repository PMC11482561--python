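"""Analytical-performance statistics: linearity, LOB, LOD, precision.

These follow the CLSI-style conventions used to verify body-fluid cell
counters:

* linearity — Pearson correlation between expected concentrations and the
  per-level replicate means;
* limit of blank (LOB) — the nonparametric 95th percentile of replicate
  measurements of analyte-free samples, at the CLSI rank position
  ``0.5 + 0.95 N`` with linear interpolation between order statistics;
* limit of detection (LOD) — the lowest level at which strictly more than
  95% of replicate measurements exceed the LOB;
* precision — per-level mean, sample SD and CV%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ReplicateSet",
    "LinearityResult",
    "LobLodResult",
    "PrecisionResult",
    "linearity",
    "limit_of_blank",
    "limit_of_detection",
    "precision",
]


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate measurements of one quality-control level."""

    level_label: str
    expected_concentration: float
    measurements: tuple[float, ...]

    def __init__(self, level_label, expected_concentration, measurements):
        ms = tuple(float(m) for m in measurements)
        if len(ms) < 2:
            raise ValueError("a replicate set needs >= 2 measurements")
        if any(not math.isfinite(m) or m < 0 for m in ms):
            raise ValueError("measurements must be finite and >= 0")
        if expected_concentration < 0:
            raise ValueError("expected_concentration must be >= 0")
        object.__setattr__(self, "level_label", str(level_label))
        object.__setattr__(self, "expected_concentration",
                           float(expected_concentration))
        object.__setattr__(self, "measurements", ms)

    @property
    def mean(self) -> float:
        return float(np.mean(self.measurements))

    @property
    def sd(self) -> float:
        return float(np.std(self.measurements, ddof=1))


@dataclass
class LinearityResult:
    r: float
    r_squared: float
    levels: list[dict] = field(default_factory=list)


@dataclass
class LobLodResult:
    lob: float
    lod: float | None
    exceedance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lod is not None and self.lod < self.lob:
            raise ValueError("LOD cannot be below LOB")


@dataclass
class PrecisionResult:
    levels: list[dict] = field(default_factory=list)


# --------------------------------------------------------------------------

def linearity(levels: list[ReplicateSet]) -> LinearityResult:
    """Pearson correlation of expected concentration vs replicate means.

    Each level contributes one point: its expected value against the mean of
    its replicates (the averages, not the pooled raw values, are the
    measured values).
    """
    if len(levels) < 3:
        raise ValueError("linearity needs >= 3 levels")
    expected = np.array([l.expected_concentration for l in levels])
    measured = np.array([l.mean for l in levels])
    if np.ptp(expected) == 0 or np.ptp(measured) == 0:
        raise ValueError("zero variance: Pearson r undefined")
    r = float(stats.pearsonr(expected, measured).statistic)
    return LinearityResult(
        r=r,
        r_squared=r * r,
        levels=[
            {"level_label": l.level_label,
             "expected": l.expected_concentration,
             "measured_mean": l.mean, "sd": l.sd}
            for l in levels
        ],
    )


def limit_of_blank(
    blank_measurements: list[float], percentile: float = 95.0
) -> float:
    """Nonparametric percentile of blank-sample measurements.

    Rank position = 0.5 + (percentile/100) x N, linearly interpolated
    between order statistics and clipped to the observed range.  Fewer than
    20 blanks triggers a warning (the estimate is then poorly supported).
    """
    x = np.asarray(blank_measurements, dtype=float)
    if x.size == 0:
        raise ValueError("no blank measurements supplied")
    if not np.all(np.isfinite(x)):
        raise ValueError("blank measurements must be finite")
    if x.size < 20:
        import warnings
        warnings.warn(
            f"only {x.size} blank measurements (>= 20 recommended)",
            stacklevel=2,
        )
    xs = np.sort(x)
    rank = 0.5 + (percentile / 100.0) * x.size  # 1-based
    if rank <= 1:
        return float(xs[0])
    if rank >= x.size:
        return float(xs[-1])
    lo = int(math.floor(rank))
    frac = rank - lo
    return float(xs[lo - 1] + frac * (xs[lo] - xs[lo - 1]))


def limit_of_detection(
    levels: list[ReplicateSet], lob: float
) -> LobLodResult:
    """Lowest level whose measurements exceed the LOB more than 95% of the
    time.

    The exceedance fraction per level counts measurements strictly greater
    than the LOB; a level qualifies only with fraction strictly above 0.95
    (19/20 does not qualify).  If no level qualifies the LOD is undefined
    (``None``).
    """
    if not levels:
        return LobLodResult(lob=lob, lod=None, exceedance=[])
    ordered = sorted(levels, key=lambda l: l.expected_concentration)
    rows = []
    lod = None
    for l in ordered:
        n = len(l.measurements)
        if n < 20:
            import warnings
            warnings.warn(
                f"level {l.level_label}: only {n} replicates "
                "(>= 20 recommended)", stacklevel=2,
            )
        frac = sum(m > lob for m in l.measurements) / n
        rows.append({
            "level_label": l.level_label,
            "expected": l.expected_concentration,
            "exceedance_fraction": frac,
        })
        if lod is None and frac > 0.95:
            lod = l.expected_concentration
    return LobLodResult(lob=lob, lod=lod, exceedance=rows)


def precision(levels: list[ReplicateSet]) -> PrecisionResult:
    """Per-level mean, sample SD (n-1 denominator) and CV%.

    A level with mean 0 gets ``cv_percent=None`` (flagged, not infinite).
    """
    rows = []
    for l in levels:
        m, s = l.mean, l.sd
        rows.append({
            "level_label": l.level_label,
            "expected": l.expected_concentration,
            "n": len(l.measurements),
            "mean": m,
            "sd": s,
            "cv_percent": (100.0 * s / m) if m != 0 else None,
        })
    return PrecisionResult(levels=rows)
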