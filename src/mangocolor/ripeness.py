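"""Ripeness trajectories: timed code tables and cultivar indicator rules.

During post-ripening (here: controlled maturation after harvest, measured
over 0-70 h) the pixel share of characteristic codes shifts — typically a
greener/yellower code falls while a redder one rises as carotenoids
accumulate.  This module aggregates per-image measurements into per-hour
series, ranks the dominant codes over a whole series, classifies the trend
of any code's share, and evaluates cultivar-specific indicator rules.

Built-in indicator presets cover the cultivars Nam Dokmai (NDM),
Mahachanok (MHC) and Kent: the pulp of NDM and MHC is tracked by the
falling/rising pair 0560-Y20R / 0560-Y40R, their peels by the rising codes
1050-Y40R and 1060-Y40R respectively (the MHC peel share peaks and then
recedes), and Kent pulp by the peaked indicator 0550-Y20R.  Kent peel stays
rich green throughout ripening, so no peel color indicator exists for it;
its preset is an explicit not-applicable marker rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ncs
from .histogram import top_k_codes

__all__ = [
    "RipenessSeries",
    "IndicatorRule",
    "Trend",
    "assemble_series",
    "series_top_codes",
    "trend",
    "ripeness_fraction",
    "builtin_rules",
    "evaluate_rule",
    "series_to_long_frame",
]

#: Share band (percentage points) below which a trajectory counts as flat;
#: matches the measurement system's +/-5 % color tolerance.
FLAT_BAND_PCT = 5.0


@dataclass(frozen=True)
class RipenessSeries:
    """Averaged code tables over strictly increasing ripening hours."""

    cultivar: str
    tissue: str
    hours: tuple                   # strictly increasing, h
    tables: tuple                  # pd.Series (code str -> % of fruit) per hour
    replicates: tuple              # replicate count per hour

    def share(self, code) -> np.ndarray:
        """Share trajectory of one code, percent, zeros where absent."""
        label = str(code)
        return np.array([float(t.get(label, 0.0)) for t in self.tables])


@dataclass(frozen=True)
class IndicatorRule:
    """Cultivar/tissue-specific ripeness indicator.

    A rule names a rising code whose share grows with maturity and
    optionally a falling code it displaces.  ``applicable=False`` marks
    combinations for which peel/pulp color carries no ripeness signal.
    """

    cultivar: str
    tissue: str
    rising_code: ncs.NCSCode | None = None
    falling_code: ncs.NCSCode | None = None
    applicable: bool = True
    note: str = ""


@dataclass(frozen=True)
class Trend:
    start_pct: float
    end_pct: float
    peak_pct: float
    peak_hour: float
    direction: str                 # rising | falling | peaked | flat


def assemble_series(records) -> RipenessSeries:
    """Aggregate measurement records into one series.

    All records must share cultivar and tissue; replicates at the same hour
    are averaged arithmetically per code, hours are sorted ascending.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to assemble")
    cultivars = {r.cultivar for r in records}
    tissues = {r.tissue for r in records}
    if len(cultivars) > 1 or len(tissues) > 1:
        raise ValueError("records mix cultivars or tissues; assemble one series per pair")
    by_hour: dict = {}
    for r in records:
        by_hour.setdefault(float(r.hour), []).append(r.histograms.code_table)
    hours = sorted(by_hour)
    tables, reps = [], []
    for h in hours:
        group = by_hour[h]
        merged = pd.concat(group, axis=1).fillna(0.0).mean(axis=1)
        merged = merged.rename_axis("code")
        tables.append(merged)
        reps.append(len(group))
    return RipenessSeries(cultivar=cultivars.pop(), tissue=tissues.pop(),
                          hours=tuple(hours), tables=tuple(tables), replicates=tuple(reps))


def series_top_codes(series: RipenessSeries, k: int = 6,
                     chart: ncs.ColorChart | None = None) -> list:
    """The k series-dominant codes, ranked by the maximum share each code
    attains at any time point; ties break by chart number."""
    chart = chart or ncs.default_chart()
    peak = pd.concat(list(series.tables), axis=1).fillna(0.0).max(axis=1)
    return top_k_codes(peak, k=k, chart=chart)


def trend(series: RipenessSeries, code, flat_band: float = FLAT_BAND_PCT) -> Trend:
    """Classify the trajectory of one code's share over the series.

    flat    — total excursion (max - min) within ``flat_band`` points;
    peaked  — an interior maximum exceeds both endpoints by more than the band;
    rising / falling — otherwise, by the sign of end - start.
    """
    shares = series.share(code)
    if shares.size == 0:
        raise ValueError("empty series")
    start, end = float(shares[0]), float(shares[-1])
    peak_idx = int(np.argmax(shares))
    peak = float(shares[peak_idx])
    peak_hour = float(series.hours[peak_idx])
    if peak - float(shares.min()) <= flat_band:
        direction = "flat"
    elif 0 < peak_idx < shares.size - 1 and peak - max(start, end) > flat_band:
        direction = "peaked"
    elif end >= start:
        direction = "rising"
    else:
        direction = "falling"
    return Trend(start_pct=start, end_pct=end, peak_pct=peak,
                 peak_hour=peak_hour, direction=direction)


def ripeness_fraction(code_table: pd.Series, rule: IndicatorRule) -> float:
    """share(rising) / (share(rising) + share(falling)) for one time point.

    The fraction runs from 0 (unripe: only the falling code present) to 1
    (ripe: the rising code has fully displaced it) and ignores the shares
    of all non-indicator codes.
    """
    if rule.rising_code is None or rule.falling_code is None:
        raise ValueError("ripeness_fraction needs a rule with both rising and falling codes")
    up = float(code_table.get(str(rule.rising_code), 0.0))
    down = float(code_table.get(str(rule.falling_code), 0.0))
    if up + down == 0:
        raise ValueError("both indicator codes have zero share; fraction undefined")
    return up / (up + down)


def builtin_rules() -> list:
    """The cultivar indicator presets (5 supported + the Kent-peel marker)."""
    p = ncs.parse_code
    return [
        IndicatorRule("NDM", "pulp", rising_code=p("0560-Y40R"), falling_code=p("0560-Y20R"),
                      note="pulp shifts from yellow toward orange during post-ripening"),
        IndicatorRule("MHC", "pulp", rising_code=p("0560-Y40R"), falling_code=p("0560-Y20R"),
                      note="same yellow-to-orange pulp pair as NDM, larger amplitude"),
        IndicatorRule("NDM", "peel", rising_code=p("1050-Y40R"),
                      note="peel orange tone rises continuously with maturity"),
        IndicatorRule("MHC", "peel", rising_code=p("1060-Y40R"),
                      note="peel indicator rises to a peak and then recedes"),
        IndicatorRule("Kent", "pulp", rising_code=p("0550-Y20R"),
                      note="pulp indicator with a peaked profile"),
        IndicatorRule("Kent", "peel", applicable=False,
                      note="peel stays rich green; color carries no ripeness signal"),
    ]


def find_rule(cultivar: str, tissue: str) -> IndicatorRule:
    for r in builtin_rules():
        if r.cultivar.lower() == cultivar.lower() and r.tissue == tissue:
            return r
    raise KeyError(f"no built-in indicator rule for {cultivar}/{tissue}")


def evaluate_rule(series: RipenessSeries, rule: IndicatorRule | None = None) -> dict:
    """Evaluate an indicator rule over a series.

    Returns a structured dict: for inapplicable rules (e.g. Kent peel) the
    status is ``"not applicable"`` with the rule's note instead of numbers.
    """
    rule = rule or find_rule(series.cultivar, series.tissue)
    if not rule.applicable:
        return {"status": "not applicable", "cultivar": rule.cultivar,
                "tissue": rule.tissue, "note": rule.note}
    out = {"status": "ok", "cultivar": rule.cultivar, "tissue": rule.tissue,
           "rising_code": str(rule.rising_code),
           "rising_trend": trend(series, rule.rising_code)}
    if rule.falling_code is not None:
        out["falling_code"] = str(rule.falling_code)
        out["falling_trend"] = trend(series, rule.falling_code)
        fracs = []
        for t in series.tables:
            try:
                fracs.append(ripeness_fraction(t, rule))
            except ValueError:
                fracs.append(np.nan)
        out["ripeness_fraction"] = np.array(fracs)
    return out


def series_to_long_frame(series: RipenessSeries) -> pd.DataFrame:
    """Long-format export: one row per (hour, code) with the share percent."""
    rows = []
    for h, table, n in zip(series.hours, series.tables, series.replicates):
        for label, share in table.items():
            rows.append({"cultivar": series.cultivar, "tissue": series.tissue,
                         "hour": h, "code": label, "share_pct": float(share),
                         "replicates": n})
    return pd.DataFrame(rows)
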