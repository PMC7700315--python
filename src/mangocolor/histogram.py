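"""Code quantization, pixel-percentage histograms, dominant code, exports.

Every evaluable (COLOR) pixel is quantized onto the code chart by
nearest-bin search along the three axes independently: hue angle to the
nearest of the 16 token anchors, saturation (x100) to the nearest
chromaticness step, and blackness (100 x (1 - max RGB channel)) to the
nearest blackness step; exact midpoints resolve to the lower step.

Three marginal histograms (COLOR: 16 hue bins, SATURATION: 8 bins,
BRIGHTNESS: 4 bins) are expressed as percentages of the COLOR pixels and
each sums to 100.  The joint code table is expressed as a percentage of
the whole fruit surface so its entries are directly comparable with the
black/red shares of the PIXEL section; the table sums to the COLOR share.

The dominant code is reported by two rules: the composition of the three
marginal argmax bins (the rule behind the classic worked example where
43.7 % hue, 50.9 % saturation and 69.2 % brightness yield 1050-Y40R), and
the argmax of the joint table, which may name a different code.
"""

from __future__ import annotations

import ast
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import colorspace, ncs
from .segmentation import SegmentationResult

__all__ = [
    "QuantizedField",
    "ColorHistogramSet",
    "DominantCode",
    "MeasurementRecord",
    "quantize_pixel",
    "quantize_field",
    "modal_refine",
    "build_histograms",
    "dominant_code",
    "top_k_codes",
    "default_palette",
    "pseudo_color",
    "export_measurement",
    "read_measurement",
    "measure_from_masks",
]

SECTION_ORDER = ("META", "PIXEL", "COLOR", "SATURATION", "BRIGHTNESS", "CODES", "DOMINANT")


@dataclass(frozen=True)
class QuantizedField:
    """Per-pixel chart axis indices (valid wherever ``valid`` is True)."""

    hue_idx: np.ndarray
    chroma_idx: np.ndarray
    black_idx: np.ndarray
    valid: np.ndarray


def quantize_pixel(hue_deg: float, saturation: float, intensity: float,
                   chart: ncs.ColorChart | None = None) -> ncs.NCSCode:
    """Quantize one HSI pixel to its chart code.

    The blackness axis is measured against the brightest in-gamut color of
    the same hue and saturation, i.e. ``100 * (1 - intensity /
    max_intensity(hue, saturation))`` — equivalently 100 x (1 - max RGB
    channel).
    """
    chart = chart or ncs.default_chart()
    value = float(intensity) / float(colorspace.max_intensity(hue_deg, saturation))
    hi, ci, bi = chart.quantize_hsv(hue_deg, saturation, min(value, 1.0))
    return chart.code_at(int(hi), int(ci), int(bi))


def quantize_field(rgb_unit: np.ndarray, color_mask: np.ndarray,
                   chart: ncs.ColorChart | None = None) -> QuantizedField:
    """Vectorised quantization of an image's COLOR pixels."""
    chart = chart or ncs.default_chart()
    hi, ci, bi = chart.quantize_rgb(rgb_unit)
    return QuantizedField(hue_idx=hi, chroma_idx=ci, black_idx=bi,
                          valid=np.asarray(color_mask, bool))


def modal_refine(qfield: QuantizedField, chart: ncs.ColorChart | None = None) -> QuantizedField:
    """Majority-vote regularisation of quantized codes.

    Each valid pixel's code is replaced by the most frequent code among its
    3x3 valid neighbours (itself included); ties keep the pixel's own code.
    The operation is the identity on locally constant code fields and on
    majority-stable boundaries, so noiseless scenes are untouched, while
    isolated noise-flipped pixels near bin edges are voted back to their
    surroundings.
    """
    chart = chart or ncs.default_chart()
    nC, nB = len(chart.chromaticness_steps), len(chart.blackness_steps)
    code_id = (qfield.hue_idx * nC + qfield.chroma_idx) * nB + qfield.black_idx
    valid = qfield.valid
    H, W = code_id.shape
    padded = np.full((H + 2, W + 2), -1, dtype=np.int64)
    padded[1:-1, 1:-1] = np.where(valid, code_id, -1)
    stack = np.stack([padded[1 + dr:H + 1 + dr, 1 + dc:W + 1 + dc]
                      for dr in (-1, 0, 1) for dc in (-1, 0, 1)])
    best = code_id.copy()
    best_cnt = (stack == code_id[None]).sum(axis=0)      # self count (ties keep self)
    for k in range(9):
        cand = stack[k]
        cnt = (stack == cand[None]).sum(axis=0)
        better = valid & (cand >= 0) & (cnt > best_cnt)
        best = np.where(better, cand, best)
        best_cnt = np.where(better, cnt, best_cnt)
    hi, rem = np.divmod(best, nC * nB)
    ci, bi = np.divmod(rem, nB)
    return QuantizedField(hue_idx=hi, chroma_idx=ci, black_idx=bi, valid=valid)


@dataclass(frozen=True)
class ColorHistogramSet:
    """Marginal histograms (percent of COLOR pixels) and joint code table
    (percent of fruit surface)."""

    hue_hist: pd.Series
    saturation_hist: pd.Series
    blackness_hist: pd.Series
    code_table: pd.Series
    n_color: int
    n_fruit: int

    @property
    def color_pct(self) -> float:
        """COLOR share of the fruit surface (what the code table sums to)."""
        return 100.0 * self.n_color / self.n_fruit if self.n_fruit else 0.0


def build_histograms(qfield: QuantizedField, seg: SegmentationResult,
                     chart: ncs.ColorChart | None = None) -> ColorHistogramSet:
    """Histogram accounting over the COLOR pixels of a segmented image."""
    chart = chart or ncs.default_chart()
    mask = qfield.valid & seg.color_mask
    n_color = int(mask.sum())
    n_fruit = seg.fruit_pixels
    hue_index = pd.Index([str(t) for t in chart.hue_tokens], name="hue")
    sat_index = pd.Index(chart.chromaticness_steps, name="chromaticness")
    bla_index = pd.Index(chart.blackness_steps, name="blackness")
    if n_color == 0:
        warnings.warn("no COLOR pixels; returning empty histograms")
        return ColorHistogramSet(
            hue_hist=pd.Series(0.0, index=hue_index),
            saturation_hist=pd.Series(0.0, index=sat_index),
            blackness_hist=pd.Series(0.0, index=bla_index),
            code_table=pd.Series(dtype=float), n_color=0, n_fruit=n_fruit)
    hi = qfield.hue_idx[mask]
    ci = qfield.chroma_idx[mask]
    bi = qfield.black_idx[mask]
    nH, nC, nB = len(hue_index), len(sat_index), len(bla_index)
    hue_hist = pd.Series(100.0 * np.bincount(hi, minlength=nH) / n_color, index=hue_index)
    sat_hist = pd.Series(100.0 * np.bincount(ci, minlength=nC) / n_color, index=sat_index)
    bla_hist = pd.Series(100.0 * np.bincount(bi, minlength=nB) / n_color, index=bla_index)
    joint = np.bincount((hi * nC + ci) * nB + bi, minlength=nH * nC * nB)
    nz = np.nonzero(joint)[0]
    codes = []
    for flat in nz:
        h, rem = divmod(int(flat), nC * nB)
        c, b = divmod(rem, nB)
        codes.append(str(chart.code_at(h, c, b)))
    table = pd.Series(100.0 * joint[nz] / n_fruit, index=pd.Index(codes, name="code"))
    return ColorHistogramSet(hue_hist=hue_hist, saturation_hist=sat_hist,
                             blackness_hist=bla_hist, code_table=table,
                             n_color=n_color, n_fruit=n_fruit)


@dataclass(frozen=True)
class DominantCode:
    """Dominant code by the marginal-argmax rule and by the joint-table rule."""

    marginal_code: ncs.NCSCode
    marginal_peaks: dict           # axis -> peak share % of COLOR pixels
    joint_code: ncs.NCSCode
    joint_share_pct: float         # % of fruit surface
    tie_flagged: bool = dc_field(default=False)


def dominant_code(hist: ColorHistogramSet, chart: ncs.ColorChart | None = None) -> DominantCode:
    """Compose the argmax bin of each marginal into one code; also report the
    joint-table argmax.  Marginal ties resolve to the lower-index bin and are
    flagged."""
    chart = chart or ncs.default_chart()
    if hist.n_color == 0:
        raise ValueError("cannot determine a dominant code without COLOR pixels")
    tie = False
    picks = []
    for series in (hist.hue_hist, hist.saturation_hist, hist.blackness_hist):
        vals = series.to_numpy()
        idx = int(np.argmax(vals))
        tie = tie or (np.sum(vals == vals[idx]) > 1)
        picks.append(idx)
    code = chart.code_at(picks[0], picks[1], picks[2])
    peaks = {"hue": float(hist.hue_hist.iloc[picks[0]]),
             "saturation": float(hist.saturation_hist.iloc[picks[1]]),
             "brightness": float(hist.blackness_hist.iloc[picks[2]])}
    joint_label = hist.code_table.idxmax()
    joint = ncs.parse_code(joint_label)
    return DominantCode(marginal_code=code, marginal_peaks=peaks, joint_code=joint,
                        joint_share_pct=float(hist.code_table.max()), tie_flagged=tie)


def top_k_codes(code_table: pd.Series, k: int = 6,
                chart: ncs.ColorChart | None = None) -> list:
    """The k codes with the largest shares, ties broken by chart number."""
    if k < 1:
        raise ValueError("k must be >= 1")
    chart = chart or ncs.default_chart()
    items = [(ncs.parse_code(label), float(share)) for label, share in code_table.items()]
    items.sort(key=lambda cs: (-cs[1], chart.number_of(cs[0])))
    return [c for c, _ in items[:k]]


def default_palette(chart: ncs.ColorChart | None = None) -> dict:
    """Display colors: one vivid color per hue token plus black/red/background."""
    chart = chart or ncs.default_chart()
    pal = {}
    for tok, angle in zip(chart.hue_tokens, chart.hue_angles):
        rgb = colorspace.hsi_to_rgb(angle, 0.85, 0.9 * float(colorspace.max_intensity(angle, 0.85)))
        pal[str(tok)] = tuple(int(v) for v in np.round(rgb * 255))
    pal["black"] = (0, 0, 0)
    pal["red"] = (255, 0, 0)
    pal["background"] = (255, 255, 255)
    return pal


def pseudo_color(qfield: QuantizedField, seg: SegmentationResult,
                 chart: ncs.ColorChart | None = None, palette: dict | None = None) -> np.ndarray:
    """Render the scene with each pixel replaced by its class display color:
    the 16 hue-token colors for COLOR pixels, plus black, red and background."""
    chart = chart or ncs.default_chart()
    palette = palette or default_palette(chart)
    out = np.zeros(seg.background_mask.shape + (3,), dtype=np.uint8)
    out[seg.background_mask] = palette["background"]
    out[seg.black_mask] = palette["black"]
    out[seg.red_mask] = palette["red"]
    for idx, tok in enumerate(chart.hue_tokens):
        m = seg.color_mask & (qfield.hue_idx == idx)
        out[m] = palette[str(tok)]
    return out


@dataclass(frozen=True)
class MeasurementRecord:
    """One image's complete color measurement."""

    sample_id: str
    cultivar: str
    tissue: str                    # "peel" or "pulp"
    hour: float                    # post-ripening time, h
    pixel_percentages: dict        # black/red/color % of fruit surface
    histograms: ColorHistogramSet
    dominant: DominantCode

    def __post_init__(self):
        if self.tissue not in ("peel", "pulp"):
            raise ValueError("tissue must be 'peel' or 'pulp'")
        if self.hour < 0:
            raise ValueError("ripening hour must be >= 0")


def measure_from_masks(qfield: QuantizedField, seg: SegmentationResult,
                       sample_id: str = "sample", cultivar: str = "NDM",
                       tissue: str = "peel", hour: float = 0.0,
                       chart: ncs.ColorChart | None = None) -> MeasurementRecord:
    """Assemble a MeasurementRecord from quantized pixels and segmentation."""
    chart = chart or ncs.default_chart()
    hist = build_histograms(qfield, seg, chart)
    dom = dominant_code(hist, chart)
    return MeasurementRecord(sample_id=sample_id, cultivar=cultivar, tissue=tissue,
                             hour=hour, pixel_percentages=seg.percentages,
                             histograms=hist, dominant=dom)


def _rows_for_export(record: MeasurementRecord, chart: ncs.ColorChart) -> list:
    rows = []

    def add(section, key, raw, number=""):
        display = f"{raw:.1f}" if isinstance(raw, float) else str(raw)
        rows.append({"section": section, "key": str(key), "number": number,
                     "display": display, "raw": repr(raw)})

    add("META", "sample_id", record.sample_id)
    add("META", "cultivar", record.cultivar)
    add("META", "tissue", record.tissue)
    add("META", "hour", float(record.hour))
    add("META", "n_fruit", int(record.histograms.n_fruit))
    add("META", "n_color", int(record.histograms.n_color))
    for key in ("black", "red", "color"):
        add("PIXEL", key.upper(), float(record.pixel_percentages[key]))
    for tok, v in record.histograms.hue_hist.items():
        add("COLOR", tok, float(v))
    for step, v in record.histograms.saturation_hist.items():
        add("SATURATION", step, float(v))
    for step, v in record.histograms.blackness_hist.items():
        add("BRIGHTNESS", step, float(v))
    for label, v in record.histograms.code_table.items():
        add("CODES", label, float(v), number=chart.number_of(ncs.parse_code(label)))
    add("DOMINANT", "marginal_code", str(record.dominant.marginal_code))
    add("DOMINANT", "joint_code", str(record.dominant.joint_code))
    add("DOMINANT", "joint_share", float(record.dominant.joint_share_pct))
    for axis, v in record.dominant.marginal_peaks.items():
        add("DOMINANT", f"peak_{axis}", float(v))
    return rows


def export_measurement(record: MeasurementRecord, path,
                       xlsx_path=None, chart: ncs.ColorChart | None = None) -> None:
    """Write a measurement as delimited text (CSV), optionally a spreadsheet twin.

    Sections appear in fixed order (PIXEL, then the three marginal
    histograms, then the code table); shares are displayed with one decimal
    place while a parallel machine-precision column preserves raw values so
    export -> reimport round-trips exactly.
    """
    chart = chart or ncs.default_chart()
    df = pd.DataFrame(_rows_for_export(record, chart))
    df.to_csv(path, index=False)
    if xlsx_path is not None:
        df.to_excel(xlsx_path, index=False)


def read_measurement(path, chart: ncs.ColorChart | None = None) -> MeasurementRecord:
    """Reconstruct a MeasurementRecord from its CSV export."""
    chart = chart or ncs.default_chart()
    df = pd.read_csv(path, dtype={"section": str, "key": str, "raw": str})
    by = {s: g for s, g in df.groupby("section")}

    def raw_map(section):
        g = by.get(section)
        if g is None:
            return {}
        return {str(k): ast.literal_eval(r) for k, r in zip(g["key"], g["raw"])}

    meta = raw_map("META")
    pixel = {k.lower(): v for k, v in raw_map("PIXEL").items()}
    hue = raw_map("COLOR")
    sat = raw_map("SATURATION")
    bla = raw_map("BRIGHTNESS")
    codes = raw_map("CODES")
    dom = raw_map("DOMINANT")
    hist = ColorHistogramSet(
        hue_hist=pd.Series({str(t): hue[str(t)] for t in chart.hue_tokens},
                           name=None).rename_axis("hue"),
        saturation_hist=pd.Series({s: sat[str(s)] for s in chart.chromaticness_steps}
                                  ).rename_axis("chromaticness"),
        blackness_hist=pd.Series({b: bla[str(b)] for b in chart.blackness_steps}
                                 ).rename_axis("blackness"),
        code_table=pd.Series(codes, dtype=float).rename_axis("code"),
        n_color=int(meta["n_color"]), n_fruit=int(meta["n_fruit"]))
    dominant = DominantCode(
        marginal_code=ncs.parse_code(dom["marginal_code"]),
        marginal_peaks={a: dom[f"peak_{a}"] for a in ("hue", "saturation", "brightness")},
        joint_code=ncs.parse_code(dom["joint_code"]),
        joint_share_pct=float(dom["joint_share"]))
    return MeasurementRecord(sample_id=str(meta["sample_id"]), cultivar=str(meta["cultivar"]),
                             tissue=str(meta["tissue"]), hour=float(meta["hour"]),
                             pixel_percentages=pixel, histograms=hist, dominant=dominant)
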