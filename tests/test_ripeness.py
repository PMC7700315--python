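"""Trajectory assembly, trend classification and indicator rules."""

import numpy as np
import pandas as pd
import pytest

from mangocolor import ncs, ripeness, synthetic
from mangocolor.histogram import ColorHistogramSet, DominantCode, MeasurementRecord


def fake_record(hour, table, cultivar="NDM", tissue="pulp", n=1000):
    """A MeasurementRecord carrying just a code table (for aggregation tests)."""
    series = pd.Series(table, dtype=float).rename_axis("code")
    hue = pd.Series(100.0, index=pd.Index(["Y20R"], name="hue"))
    hist = ColorHistogramSet(hue_hist=hue, saturation_hist=hue.copy(),
                             blackness_hist=hue.copy(), code_table=series,
                             n_color=n, n_fruit=n)
    dom = DominantCode(marginal_code=ncs.parse_code("0560-Y20R"), marginal_peaks={},
                       joint_code=ncs.parse_code("0560-Y20R"), joint_share_pct=0.0)
    return MeasurementRecord(sample_id=f"s{hour}", cultivar=cultivar, tissue=tissue,
                             hour=hour, pixel_percentages={}, histograms=hist, dominant=dom)


def records_from_series_spec(spec, cultivar="NDM", tissue="pulp"):
    """Noise-free records straight from the generator's truth compositions."""
    recs = []
    for hour, comp in synthetic.simulate_series(spec):
        table = {str(c): 100.0 * f for c, f in comp.entries}
        recs.append(fake_record(hour, table, cultivar=cultivar, tissue=tissue))
    return recs


def test_assemble_averages_replicates():
    recs = [fake_record(0, {"0560-Y20R": 20.0}), fake_record(0, {"0560-Y20R": 30.0}),
            fake_record(12, {"0560-Y20R": 10.0})]
    series = ripeness.assemble_series(recs)
    assert series.hours == (0.0, 12.0)
    assert series.replicates == (2, 1)
    assert series.tables[0]["0560-Y20R"] == pytest.approx(25.0)


def test_assemble_single_record():
    series = ripeness.assemble_series([fake_record(6, {"0510-G": 50.0})])
    assert series.hours == (6.0,) and series.replicates == (1,)


def test_assemble_order_invariant(rng):
    recs = [fake_record(h, {"0560-Y20R": float(h)}) for h in (48, 0, 24, 12, 36)]
    a = ripeness.assemble_series(recs)
    b = ripeness.assemble_series([recs[i] for i in rng.permutation(len(recs))])
    assert a.hours == b.hours
    for ta, tb in zip(a.tables, b.tables):
        pd.testing.assert_series_equal(ta, tb)


def test_assemble_rejects_mixed_series():
    with pytest.raises(ValueError):
        ripeness.assemble_series([fake_record(0, {}, cultivar="NDM"),
                                  fake_record(0, {}, cultivar="MHC")])
    with pytest.raises(ValueError):
        ripeness.assemble_series([fake_record(0, {}, tissue="peel"),
                                  fake_record(0, {}, tissue="pulp")])


def test_series_top_codes_by_peak(rng):
    recs = [fake_record(0, {"0510-G": 49.0, "0530-Y": 10.0}),
            fake_record(12, {"0510-G": 2.0, "0530-Y": 12.0})]
    out = ripeness.series_top_codes(ripeness.assemble_series(recs))
    assert str(out[0]) == "0510-G"          # peaks at 49 % despite collapsing later
    # random series agrees with a brute-force max-over-time oracle
    chart = ncs.default_chart()
    labels = [str(chart.entries[i].code) for i in rng.choice(512, 12, replace=False)]
    recs = [fake_record(h, dict(zip(labels, rng.uniform(0, 30, len(labels)))))
            for h in (0, 12, 24)]
    series = ripeness.assemble_series(recs)
    got = [str(c) for c in ripeness.series_top_codes(series, k=6)]
    peak = {}
    for t in series.tables:
        for k, v in t.items():
            peak[k] = max(peak.get(k, 0.0), v)
    oracle = sorted(peak, key=lambda k: (-peak[k], chart.number_of(ncs.parse_code(k))))[:6]
    assert got == oracle


def test_series_top_codes_constant_series_matches_top_k():
    table = {"0510-G": 30.0, "0530-Y": 20.0, "1050-Y40R": 10.0}
    series = ripeness.assemble_series([fake_record(h, table) for h in (0, 12)])
    from mangocolor.histogram import top_k_codes
    assert ripeness.series_top_codes(series) == top_k_codes(pd.Series(table))


def test_trend_monotone_logistic():
    spec = synthetic.SeriesSpec.of("0560-Y40R", "0560-Y20R",
                                   hours=tuple(range(0, 71, 5)), rate_per_h=0.3)
    series = ripeness.assemble_series(records_from_series_spec(spec))
    t = ripeness.trend(series, "0560-Y40R")
    assert t.direction == "rising"
    # generator endpoints, allowing for the mixture renormalisation
    assert t.start_pct == pytest.approx(100 * spec.rising_start, abs=1.5)
    assert t.end_pct == pytest.approx(100 * spec.rising_end, abs=1.5)
    assert ripeness.trend(series, "0560-Y20R").direction == "falling"


def test_trend_flat_and_peaked():
    flat = ripeness.assemble_series([fake_record(h, {"0510-G": 20.0}) for h in (0, 12, 24)])
    assert ripeness.trend(flat, "0510-G").direction == "flat"
    tri = ripeness.assemble_series([
        fake_record(0, {"1060-Y40R": 1.0}), fake_record(30, {"1060-Y40R": 40.0}),
        fake_record(60, {"1060-Y40R": 10.0})])
    t = ripeness.trend(tri, "1060-Y40R")
    assert t.direction == "peaked"
    assert t.peak_hour == 30.0 and t.peak_pct == 40.0


def test_ripeness_fraction_values():
    rule = ripeness.find_rule("NDM", "pulp")
    half = pd.Series({"0560-Y40R": 20.0, "0560-Y20R": 20.0})
    assert ripeness.ripeness_fraction(half, rule) == pytest.approx(0.5)
    ripe = pd.Series({"0560-Y40R": 20.0})
    assert ripeness.ripeness_fraction(ripe, rule) == pytest.approx(1.0)
    # invariance to shares of non-indicator codes
    with_extra = pd.Series({"0560-Y40R": 20.0, "0560-Y20R": 20.0, "0510-G": 55.0})
    assert ripeness.ripeness_fraction(with_extra, rule) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        ripeness.ripeness_fraction(pd.Series({"0510-G": 10.0}), rule)
    with pytest.raises(ValueError):
        ripeness.ripeness_fraction(half, ripeness.find_rule("NDM", "peel"))


def test_ripeness_fraction_monotone_on_logistic_series():
    spec = synthetic.SeriesSpec.of("0560-Y40R", "0560-Y20R")
    series = ripeness.assemble_series(records_from_series_spec(spec))
    rule = ripeness.find_rule("NDM", "pulp")
    fracs = [ripeness.ripeness_fraction(t, rule) for t in series.tables]
    assert np.all(np.diff(fracs) >= -1e-12)


def test_builtin_rules_presets():
    rules = ripeness.builtin_rules()
    assert len(rules) == 6
    supported = [r for r in rules if r.applicable]
    assert len(supported) == 5
    for r in supported:
        for code in (r.rising_code, r.falling_code):
            if code is not None:
                ncs.parse_code(str(code))       # every preset parses strictly
    pairs = {(r.cultivar, r.tissue) for r in rules}
    assert pairs == {("NDM", "pulp"), ("MHC", "pulp"), ("NDM", "peel"),
                     ("MHC", "peel"), ("Kent", "pulp"), ("Kent", "peel")}
    assert str(ripeness.find_rule("NDM", "peel").rising_code) == "1050-Y40R"
    assert str(ripeness.find_rule("MHC", "peel").rising_code) == "1060-Y40R"
    assert str(ripeness.find_rule("Kent", "pulp").rising_code) == "0550-Y20R"


def test_kent_peel_yields_structured_not_applicable():
    series = ripeness.assemble_series(
        [fake_record(h, {"1020-G": 40.0}, cultivar="Kent", tissue="peel")
         for h in (0, 12)])
    result = ripeness.evaluate_rule(series)
    assert result["status"] == "not applicable"
    assert "green" in result["note"]


def test_series_long_frame_export():
    series = ripeness.assemble_series(
        [fake_record(h, {"0560-Y20R": 10.0 + h}) for h in (0, 12)])
    df = ripeness.series_to_long_frame(series)
    assert set(df.columns) == {"cultivar", "tissue", "hour", "code", "share_pct",
                               "replicates"}
    assert len(df) == 2
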