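"""Quadrant gating: zone assignment, auto thresholds, C4 resolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csfscan import (
    CellDetection,
    GateThresholds,
    SizeRules,
    assign_zones,
    auto_threshold,
    build_histogram,
    gate_events,
    resolve_c4,
)

CUTS = GateThresholds(gf_cut=100.0, cf_cut=100.0)


def ev(gf, cf, r=4.0):
    return CellDetection(0.0, 0.0, r, gf_intensity=gf, cf_intensity=cf)


@pytest.mark.parametrize("gf,cf,zone", [
    (900, 0, "C2"),       # WBC: GF positive only
    (0, 800, "C3"),       # RBC: CF positive only
    (900, 800, "C4"),     # double positive
    (0, 0, "C1"),         # double negative
    (100, 100, "C1"),     # exactly on both cuts -> non-positive side
    (100.0001, 100, "C2"),
])
def test_quadrant_assignment(gf, cf, zone):
    res = assign_zones([ev(gf, cf)], CUTS)
    assert res.zones == [zone]


def test_nonfinite_intensity_excluded_and_reported():
    res = assign_zones([ev(float("nan"), 0), ev(900, 0)], CUTS)
    assert res.invalid_count == 1
    assert res.zones == ["INVALID", "C2"]
    assert sum(res.zone_counts.values()) == 1


def test_zone_counts_match_constructed_classes():
    rng = np.random.default_rng(0)
    events = (
        [ev(a, c) for a, c in zip(rng.normal(900, 50, 600), rng.normal(5, 5, 600))]
        + [ev(a, c) for a, c in zip(rng.normal(5, 5, 400), rng.normal(900, 50, 400))]
    )
    res = assign_zones(events, CUTS)
    assert res.zone_counts == {"C1": 0, "C2": 600, "C3": 400, "C4": 0}


@given(st.lists(
    st.tuples(st.floats(-100, 2000), st.floats(-100, 2000)),
    min_size=0, max_size=60,
))
@settings(derandomize=True, max_examples=60)
def test_zones_partition_events(points):
    """Every finite-intensity event lands in exactly one quadrant."""
    events = [ev(g, c) for g, c in points]
    res = assign_zones(events, CUTS)
    assert sum(res.zone_counts.values()) + res.invalid_count == len(events)


def test_raising_gf_cut_never_increases_wbc():
    rng = np.random.default_rng(1)
    events = [ev(g, c, r=rng.uniform(2, 10))
              for g, c in rng.uniform(0, 1200, size=(300, 2))]
    prev = math.inf
    for cut in (50.0, 150.0, 400.0, 800.0):
        res = gate_events(events, GateThresholds(gf_cut=cut, cf_cut=100.0))
        assert res.adjusted_wbc <= prev
        prev = res.adjusted_wbc


# --------------------------------------------------------------------------
# Auto thresholds
# --------------------------------------------------------------------------

def test_otsu_cut_separates_bimodal_channel():
    rng = np.random.default_rng(2)
    events = [ev(v, v) for v in rng.normal(10, 2, 200)] + \
             [ev(v, v) for v in rng.normal(1000, 80, 200)]
    thr = auto_threshold(events)
    assert 10 < thr.gf_cut < 1000
    assert 10 < thr.cf_cut < 1000
    assert thr.fallback_used == ()


def test_degenerate_channel_uses_flagged_fallback():
    events = [ev(50.0, 50.0) for _ in range(20)]
    thr = auto_threshold(events)
    assert "gf" in thr.fallback_used and "cf" in thr.fallback_used
    assert thr.gf_cut == pytest.approx(50.0)


def test_too_few_events_instructs_fixed_mode():
    with pytest.raises(ValueError, match="fixed"):
        auto_threshold([ev(1, 1)] * 5)


def test_auto_matches_fixed_on_separated_classes():
    rng = np.random.default_rng(3)
    events = (
        [ev(a, abs(c)) for a, c in zip(rng.normal(900, 60, 300), rng.normal(0, 5, 300))]
        + [ev(abs(a), c) for a, c in zip(rng.normal(0, 5, 200), rng.normal(900, 60, 200))]
    )
    auto = gate_events(events, None)
    fixed = gate_events(events, GateThresholds(gf_cut=150, cf_cut=150))
    assert auto.zone_counts == fixed.zone_counts


# --------------------------------------------------------------------------
# C4 resolution
# --------------------------------------------------------------------------

RULES = SizeRules()  # WBC 3.5-6 µm, RBC 2.5-4 µm, doublet cutoff 9 µm


def test_empty_c4_set_means_no_adjustments():
    assert resolve_c4([], RULES, CUTS) == []


def test_oversized_double_positive_is_doublet():
    e = ev(900, 800, r=1.6 * RULES.max_single_um)
    assert resolve_c4([e], RULES, CUTS) == ["DOUBLET"]
    res = gate_events([e], CUTS, RULES)
    assert (res.adjusted_wbc, res.adjusted_rbc) == (1, 1)
    assert res.doublet_count == 1


def test_undersized_double_positive_is_artifact():
    e = ev(900, 800, r=1.0)  # below any cell class
    assert resolve_c4([e], RULES, CUTS) == ["ARTIFACT"]


def test_intensity_ratio_breaks_single_cell_c4():
    wbc_like = ev(900, 150, r=5.0)
    rbc_like = ev(150, 900, r=3.5)
    tie = ev(500, 500, r=4.0)
    assert resolve_c4([wbc_like, rbc_like, tie], RULES, CUTS) == \
        ["WBC", "RBC", "ARTIFACT"]


def test_count_conservation_with_doublets():
    rng = np.random.default_rng(4)
    events = [ev(g, c, r=rng.uniform(2, 12))
              for g, c in rng.uniform(0, 1500, size=(400, 2))]
    res = gate_events(events, CUTS)
    assert (res.adjusted_wbc + res.adjusted_rbc + res.artifact_count
            - res.doublet_count) == len(events)


def test_engineered_overlaps_recovered_within_tolerance():
    """Event sets where ~10% of WBC-RBC pairs merged into one oversized
    double-positive event: adjusted totals stay within 5% of the true class
    counts (across 20 seeds)."""
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        n_wbc = n_rbc = 100
        n_merged = 10
        events = (
            [ev(g, abs(c), r=rng.uniform(3.5, 6.0)) for g, c in
             zip(rng.normal(900, 60, n_wbc - n_merged), rng.normal(0, 5, n_wbc - n_merged))]
            + [ev(abs(g), c, r=rng.uniform(2.5, 4.0)) for g, c in
               zip(rng.normal(0, 5, n_rbc - n_merged), rng.normal(900, 60, n_rbc - n_merged))]
            + [ev(g, c, r=rng.uniform(9.1, 11.0)) for g, c in
               zip(rng.normal(900, 60, n_merged), rng.normal(900, 60, n_merged))]
        )
        res = gate_events(events, GateThresholds(gf_cut=150, cf_cut=150))
        assert abs(res.adjusted_wbc - n_wbc) <= 0.05 * n_wbc
        assert abs(res.adjusted_rbc - n_rbc) <= 0.05 * n_rbc


# --------------------------------------------------------------------------
# Histogram summary
# --------------------------------------------------------------------------

def test_histogram_counts_mirror_adjusted_totals():
    events = [ev(900, 0)] * 7 + [ev(0, 900)] * 3
    res = gate_events(events, CUTS)
    hist = build_histogram(res, events)
    assert (hist.g1_count, hist.g2_count) == (7, 3)
    assert hist.gf_bin_counts.sum() == len(events)
    assert hist.cf_bin_counts.sum() == len(events)


def test_histogram_of_no_events():
    res = gate_events([], CUTS)
    hist = build_histogram(res, [])
    assert (hist.g1_count, hist.g2_count) == (0, 0)
    assert hist.gf_bin_counts.sum() == 0
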