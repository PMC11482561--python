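"""Two-channel quadrant gating of detected cells.

Each detection carries a background-corrected green-fluorescence (GF) and
cyan-fluorescence (CF) intensity.  The (CF, GF) plane is split into four
quadrants at a pair of cuts:

    C1  both channels <= cut      (double negative: background / debris)
    C2  GF > cut, CF <= cut       (WBC: nucleic-acid stain positive)
    C3  CF > cut, GF <= cut       (RBC: glycophorin-A stain positive)
    C4  both channels > cut       (overlaps, doublets, bright artifacts)

Events exactly on a cut fall to the non-positive side, so zone assignment is
a total function.  C4 events — which the instrument resolves with an image
classifier — are resolved here by deterministic, auditable size/intensity
rules, and the WBC/RBC totals are adjusted accordingly.

Count bookkeeping: ``artifact_count`` collects C1 events plus C4 events
attributed to artifacts, so

    adjusted_wbc + adjusted_rbc + artifact_count - doublet_count
        = number of finite-intensity events

(each doublet is one event but contributes one to each class total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detect import CellDetection

__all__ = [
    "GateThresholds",
    "SizeRules",
    "GateResult",
    "HistogramSummary",
    "assign_zones",
    "auto_threshold",
    "resolve_c4",
    "gate_events",
    "build_histogram",
]

ZONES = ("C1", "C2", "C3", "C4")


@dataclass(frozen=True)
class GateThresholds:
    """Intensity cuts for the quadrant gate.

    In ``auto`` mode the cuts are recomputed per event set (see
    :func:`auto_threshold`) and recorded in the result.
    """

    gf_cut: float = 150.0
    cf_cut: float = 150.0
    mode: str = "fixed"
    fallback_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gf_cut) and math.isfinite(self.cf_cut)):
            raise ValueError("gate cuts must be finite")
        if self.mode not in ("fixed", "auto"):
            raise ValueError("mode must be 'fixed' or 'auto'")


@dataclass(frozen=True)
class SizeRules:
    """Size conventions used to resolve double-positive (C4) events.

    Radii are in µm.  ``doublet_factor`` scales the largest single-cell
    radius into the doublet cutoff (default 1.5x).
    """

    wbc_radius_um: tuple[float, float] = (3.5, 6.0)
    rbc_radius_um: tuple[float, float] = (2.5, 4.0)
    pixel_size_um: float = 1.0
    doublet_factor: float = 1.5
    # detected radii are only accurate to ~1 px; size cuts get this slack
    tolerance_um: float = 1.0

    @property
    def union_min_um(self) -> float:
        return min(self.wbc_radius_um[0], self.rbc_radius_um[0])

    @property
    def max_single_um(self) -> float:
        return max(self.wbc_radius_um[1], self.rbc_radius_um[1])

    @property
    def doublet_cutoff_um(self) -> float:
        return self.doublet_factor * self.max_single_um


@dataclass
class GateResult:
    """Zone assignment plus adjusted class counts for one event set."""

    zones: list[str]
    zone_counts: dict[str, int]
    adjusted_wbc: int = 0
    adjusted_rbc: int = 0
    artifact_count: int = 0
    doublet_count: int = 0
    invalid_count: int = 0
    c4_attributions: list[str] = field(default_factory=list)
    thresholds_used: GateThresholds = field(default_factory=GateThresholds)


@dataclass
class HistogramSummary:
    """G1/G2 population totals and per-channel binned intensities."""

    g1_count: int  # WBC side
    g2_count: int  # RBC side
    gf_bin_edges: np.ndarray
    gf_bin_counts: np.ndarray
    cf_bin_edges: np.ndarray
    cf_bin_counts: np.ndarray


# --------------------------------------------------------------------------
# Zone assignment
# --------------------------------------------------------------------------

def assign_zones(
    events: list[CellDetection], thresholds: GateThresholds
) -> GateResult:
    """Assign every finite-intensity event to exactly one quadrant.

    Events with a non-finite intensity are excluded and counted in
    ``invalid_count``.
    """
    zones: list[str] = []
    invalid = 0
    for e in events:
        gf, cf = e.gf_intensity, e.cf_intensity
        if gf is None or cf is None or not (
            math.isfinite(gf) and math.isfinite(cf)
        ):
            invalid += 1
            zones.append("INVALID")
            continue
        gf_pos = gf > thresholds.gf_cut
        cf_pos = cf > thresholds.cf_cut
        zones.append(
            "C4" if (gf_pos and cf_pos)
            else "C2" if gf_pos
            else "C3" if cf_pos
            else "C1"
        )
    counts = {z: zones.count(z) for z in ZONES}
    return GateResult(
        zones=zones, zone_counts=counts, invalid_count=invalid,
        thresholds_used=thresholds,
    )


def auto_threshold(
    events: list[CellDetection],
    min_events: int = 10,
    fallback_quantile: float = 0.5,
) -> GateThresholds:
    """Data-driven cuts: Otsu's threshold on log1p intensity per channel.

    Otsu on the log scale separates a unimodal background population from a
    bright signal population.  If a channel is degenerate (no spread, or
    Otsu cannot split it) the cut falls back to the given quantile of the
    positive intensities and the channel is flagged in ``fallback_used``.
    """
    from skimage.filters import threshold_otsu

    finite = [
        e for e in events
        if e.gf_intensity is not None and e.cf_intensity is not None
        and math.isfinite(e.gf_intensity) and math.isfinite(e.cf_intensity)
    ]
    if len(finite) < min_events:
        raise ValueError(
            f"auto thresholding needs >= {min_events} finite events "
            f"(got {len(finite)}); use fixed-mode thresholds"
        )
    cuts = {}
    fallback = []
    for name, vals in (
        ("gf", np.array([e.gf_intensity for e in finite])),
        ("cf", np.array([e.cf_intensity for e in finite])),
    ):
        logv = np.log1p(np.clip(vals, 0.0, None))
        try:
            if np.ptp(logv) <= 0:
                raise ValueError("degenerate channel")
            t = threshold_otsu(logv)
            # Otsu can settle inside a wide background mode; placing the cut
            # midway between the two class means keeps a margin to both
            # populations when they are separated
            below, above = logv[logv <= t], logv[logv > t]
            if below.size and above.size:
                t = 0.5 * (below.mean() + above.mean())
            cuts[name] = float(np.expm1(t))
        except ValueError:
            pos = vals[vals > 0]
            cuts[name] = float(np.quantile(pos, fallback_quantile)) if pos.size else 0.0
            fallback.append(name)
    return GateThresholds(
        gf_cut=cuts["gf"], cf_cut=cuts["cf"], mode="auto",
        fallback_used=tuple(fallback),
    )


# --------------------------------------------------------------------------
# C4 resolution
# --------------------------------------------------------------------------

def resolve_c4(
    c4_events: list[CellDetection],
    size_rules: SizeRules,
    thresholds: GateThresholds,
) -> list[str]:
    """Attribute every double-positive event, in rule order:

    (a) radius below the single-cell size range -> ``ARTIFACT`` (bright
        specks / stain aggregates);
    (b) radius at or above the doublet cutoff (1.5x the largest single-cell
        radius) -> ``DOUBLET``, contributing one to each class;
    (c) otherwise the class with the larger cut-normalised intensity
        (gf/gf_cut vs cf/cf_cut) wins; exact ties -> ``ARTIFACT``.
    """
    out = []
    for e in c4_events:
        r_um = e.radius_px * size_rules.pixel_size_um
        if r_um < size_rules.union_min_um - size_rules.tolerance_um:
            out.append("ARTIFACT")
        elif r_um >= size_rules.doublet_cutoff_um:
            out.append("DOUBLET")
        else:
            gf_ratio = e.gf_intensity / thresholds.gf_cut if thresholds.gf_cut else float("inf")
            cf_ratio = e.cf_intensity / thresholds.cf_cut if thresholds.cf_cut else float("inf")
            if gf_ratio > cf_ratio:
                out.append("WBC")
            elif cf_ratio > gf_ratio:
                out.append("RBC")
            else:
                out.append("ARTIFACT")
    return out


def gate_events(
    events: list[CellDetection],
    thresholds: GateThresholds | None = None,
    size_rules: SizeRules = SizeRules(),
) -> GateResult:
    """Full gate: zone assignment, C4 resolution and adjusted class totals.

    With ``thresholds=None`` the cuts are computed by :func:`auto_threshold`.
    """
    if thresholds is None:
        thresholds = auto_threshold(events)
    res = assign_zones(events, thresholds)
    c4 = [e for e, z in zip(events, res.zones) if z == "C4"]
    attributions = resolve_c4(c4, size_rules, thresholds)
    res.c4_attributions = attributions
    res.doublet_count = attributions.count("DOUBLET")
    res.adjusted_wbc = (res.zone_counts["C2"] + attributions.count("WBC")
                        + res.doublet_count)
    res.adjusted_rbc = (res.zone_counts["C3"] + attributions.count("RBC")
                        + res.doublet_count)
    res.artifact_count = res.zone_counts["C1"] + attributions.count("ARTIFACT")
    return res


# --------------------------------------------------------------------------
# Histogram summary
# --------------------------------------------------------------------------

def build_histogram(
    gate_result: GateResult,
    events: list[CellDetection],
    n_bins: int = 64,
) -> HistogramSummary:
    """G1/G2 totals (WBC/RBC populations) plus per-channel intensity bins."""
    gf = np.array([
        e.gf_intensity for e, z in zip(events, gate_result.zones)
        if z != "INVALID"
    ], dtype=float)
    cf = np.array([
        e.cf_intensity for e, z in zip(events, gate_result.zones)
        if z != "INVALID"
    ], dtype=float)
    hist = {}
    for name, vals in (("gf", gf), ("cf", cf)):
        if vals.size:
            lo, hi = float(vals.min()), float(vals.max())
            if lo == hi:
                hi = lo + 1.0
        else:
            lo, hi = 0.0, 1.0
        counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
        hist[name] = (edges, counts)
    return HistogramSummary(
        g1_count=gate_result.adjusted_wbc,
        g2_count=gate_result.adjusted_rbc,
        gf_bin_edges=hist["gf"][0], gf_bin_counts=hist["gf"][1],
        cf_bin_edges=hist["cf"][0], cf_bin_counts=hist["cf"][1],
    )


def plot_dotplot(events, gate_result, ax=None):
    """Quadrant dot plot (CF on x, GF on y) with the cuts drawn."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    colors = {"C1": "0.6", "C2": "tab:green", "C3": "tab:red", "C4": "tab:purple"}
    for z in ZONES:
        xs = [e.cf_intensity for e, zz in zip(events, gate_result.zones) if zz == z]
        ys = [e.gf_intensity for e, zz in zip(events, gate_result.zones) if zz == z]
        ax.scatter(xs, ys, s=8, c=colors[z], label=z)
    t = gate_result.thresholds_used
    ax.axvline(t.cf_cut, color="k", lw=0.8)
    ax.axhline(t.gf_cut, color="k", lw=0.8)
    ax.set_xlabel("CF intensity")
    ax.set_ylabel("GF intensity")
    ax.legend(fontsize=7)
    return ax
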