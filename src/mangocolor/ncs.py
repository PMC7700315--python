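"""NCS-style color code space: parsing, enumeration, hue geometry, chart.

A code such as ``2010-G40Y`` names a color by three perceptual attributes:
blackness (first digit pair, percent), chromaticness (second digit pair,
percent) and a hue token on the green-to-red arc (``G40Y`` = 60 % green,
40 % yellow).  Whiteness is the complement ``100 - blackness -
chromaticness``.  The measurement chart spans 16 hue tokens (G, G10Y ...
G90Y, Y, Y10R ... Y50R), 8 chromaticness steps (10, 15, 20, 30, 40, 50, 60,
80) and 4 blackness steps (5, 10, 20, 40): 512 codes in total.

Hue tokens are anchored on the conventional HSI hue circle at G = 120°,
Y = 60°, R = 0° and spaced linearly (6° per 10 % step).  Each chart entry
carries a representative 8-bit RGB color obtained by inverting the HSI
mapping at the anchor hue, ``chromaticness/100`` saturation and the largest
in-gamut intensity scaled by ``(100 - blackness)/100``; quantizing that
color recovers the entry's own code (exhaustively tested).

The chart numbering (hue outermost, then chromaticness, then blackness,
1-based) is this package's own deterministic convention; the number-to-code
map is exported so results can be re-mapped onto any other numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import colorspace

__all__ = [
    "HueToken",
    "NCSCode",
    "ChartEntry",
    "ColorChart",
    "HUE_TOKEN_NAMES",
    "CHROMATICNESS_STEPS",
    "BLACKNESS_STEPS",
    "HUE_ANCHORS_DEG",
    "parse_hue_token",
    "parse_code",
    "format_code",
    "whiteness",
    "hue_composition",
    "hue_token_to_angle",
    "representative_rgb",
    "build_chart",
    "default_chart",
]

#: The 16 admissible hue shades, green through red, in chart order.
HUE_TOKEN_NAMES: tuple = tuple(
    ["G"] + [f"G{p}Y" for p in range(10, 100, 10)]
    + ["Y"] + [f"Y{p}R" for p in range(10, 60, 10)]
)
CHROMATICNESS_STEPS: tuple = (10, 15, 20, 30, 40, 50, 60, 80)
BLACKNESS_STEPS: tuple = (5, 10, 20, 40)

#: Elementary-hue anchors on the HSI hue circle, degrees.
HUE_ANCHORS_DEG = {"G": 120.0, "Y": 60.0, "R": 0.0}

_HUE_RE = re.compile(r"^([GY])(?:(\d{2})([YR]))?$")
_CODE_RE = re.compile(r"^(?:NCS\s+)?(?:S\s*)?(\d{2})(\d{2})[-\s]\s*(\S+)$", re.IGNORECASE)


@dataclass(frozen=True)
class HueToken:
    """A hue shade on the green-yellow-red arc, e.g. G40Y = 60 % G + 40 % Y."""

    first: str
    second: str | None = None
    second_proportion: int = 0

    def __post_init__(self):
        if self.first not in ("G", "Y"):
            raise ValueError(f"first elementary must be G or Y, got {self.first!r}")
        if self.second is None:
            if self.second_proportion != 0:
                raise ValueError("pure elementary token cannot carry a proportion")
        else:
            expected = {"G": "Y", "Y": "R"}[self.first]
            if self.second != expected:
                raise ValueError(
                    f"second elementary after {self.first} must be {expected}, got {self.second!r}")
            if self.second_proportion % 10 or not 10 <= self.second_proportion <= 90:
                raise ValueError(
                    f"second proportion must be a multiple of 10 in 10..90, got {self.second_proportion}")

    def __str__(self) -> str:
        if self.second is None:
            return self.first
        return f"{self.first}{self.second_proportion}{self.second}"

    @property
    def composition(self) -> tuple:
        """(first %, second %) — proportions sum to 100."""
        return (100 - self.second_proportion, self.second_proportion)


@dataclass(frozen=True)
class NCSCode:
    """A color code <blackness><chromaticness>-<hue>, e.g. 1050-Y40R."""

    blackness: int
    chromaticness: int
    hue: HueToken

    def __str__(self) -> str:
        return f"{self.blackness:02d}{self.chromaticness:02d}-{self.hue}"

    @property
    def whiteness(self) -> int:
        return whiteness(self)


@dataclass(frozen=True)
class ChartEntry:
    number: int            # 1-based chart index
    code: NCSCode
    anchor_hue_deg: float
    representative_rgb: tuple  # 8-bit (R, G, B)


def parse_hue_token(text: str, strict: bool = True) -> HueToken:
    """Parse a hue token such as ``G``, ``G40Y`` or ``Y20R``.

    In strict mode the token must be one of the chart's 16 shades; lenient
    mode additionally admits the full G..Y..R arc (e.g. ``Y60R``).
    """
    m = _HUE_RE.match(text.strip().upper())
    if not m:
        raise ValueError(f"malformed hue token {text!r}")
    first, prop, second = m.group(1), m.group(2), m.group(3)
    if second is None:
        token = HueToken(first)
    else:
        token = HueToken(first, second, int(prop))
    if strict and str(token) not in HUE_TOKEN_NAMES:
        raise ValueError(f"hue token {token} outside the supported G..Y50R range")
    return token


def parse_code(text: str, strict: bool = True) -> NCSCode:
    """Parse a code string like ``1050-Y40R``, ``S 2010-G40Y`` or ``NCS S 1020 G``.

    The first digit pair is blackness, the second chromaticness.  Strict
    mode restricts blackness/chromaticness to the chart step sets and the
    hue to the 16 supported shades; lenient mode accepts any percent pair
    and any token on the G..R arc (needed for off-grid color-check
    references such as ``S 1040 Y60R``).
    """
    m = _CODE_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed color code {text!r}")
    blackness, chromaticness = int(m.group(1)), int(m.group(2))
    hue = parse_hue_token(m.group(3), strict=strict)
    if strict:
        if blackness not in BLACKNESS_STEPS:
            raise ValueError(f"blackness {blackness} not in steps {BLACKNESS_STEPS}")
        if chromaticness not in CHROMATICNESS_STEPS:
            raise ValueError(f"chromaticness {chromaticness} not in steps {CHROMATICNESS_STEPS}")
    # codes with blackness + chromaticness > 100 are representable (the full
    # 16 x 8 x 4 grid contains them, e.g. 4080-Y); only whiteness() objects
    return NCSCode(blackness, chromaticness, hue)


def format_code(code: NCSCode, prefix: str = "") -> str:
    """Render a code in its text form, optionally with a ``"NCS S "`` prefix."""
    return f"{prefix}{code}"


def whiteness(code: NCSCode, clamp: bool = False) -> int:
    """Whiteness = 100 - blackness - chromaticness.

    Raises for inadmissible codes whose blackness + chromaticness exceed
    100, unless ``clamp`` floors the result at zero.
    """
    w = 100 - code.blackness - code.chromaticness
    if w < 0:
        if clamp:
            return 0
        raise ValueError(f"blackness + chromaticness exceed 100 for {code}")
    return w


def hue_composition(token: HueToken) -> tuple:
    """Elementary-color proportions of a hue token, e.g. G40Y -> (60, 40)."""
    return token.composition


def hue_token_to_angle(token: HueToken) -> float:
    """Hue-circle angle of a token: linear between G=120°, Y=60°, R=0°."""
    start = HUE_ANCHORS_DEG[token.first]
    if token.second is None:
        return start
    end = HUE_ANCHORS_DEG[token.second]
    return start + (end - start) * token.second_proportion / 100.0


def representative_rgb(code: NCSCode) -> tuple:
    """8-bit RGB of a code: inverse HSI at the anchor hue, chroma/100
    saturation and the gamut-maximal intensity scaled by (100-blackness)/100."""
    h = hue_token_to_angle(code.hue)
    s = code.chromaticness / 100.0
    i = (1.0 - code.blackness / 100.0) * float(colorspace.max_intensity(h, s))
    rgb = colorspace.hsi_to_rgb(h, s, i)
    return tuple(int(v) for v in np.clip(np.round(rgb * 255.0), 0, 255).astype(int))


def _nearest_step(values: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Index of the nearest step; exact midpoints resolve to the lower step."""
    return np.argmin(np.abs(np.asarray(values, float)[..., None] - steps), axis=-1)


class ColorChart:
    """Ordered table of every code combination with representative colors.

    Also owns the quantizer that maps (hue angle, saturation, brightness
    value) triples onto chart codes by nearest-bin search along each axis.
    """

    def __init__(self, hue_tokens: Sequence[HueToken],
                 chromaticness_steps: Sequence[int],
                 blackness_steps: Sequence[int]):
        for name, steps in (("hue", [str(t) for t in hue_tokens]),
                            ("chromaticness", chromaticness_steps),
                            ("blackness", blackness_steps)):
            if len(set(steps)) != len(steps):
                raise ValueError(f"duplicate {name} steps in chart config")
        self.hue_tokens = tuple(hue_tokens)
        self.chromaticness_steps = tuple(int(c) for c in chromaticness_steps)
        self.blackness_steps = tuple(int(b) for b in blackness_steps)
        self.hue_angles = np.array([hue_token_to_angle(t) for t in self.hue_tokens])
        if not np.all(np.diff(self.hue_angles) < 0):
            raise ValueError("hue tokens must be ordered from green to red")
        self._chroma_arr = np.asarray(self.chromaticness_steps, float)
        self._black_arr = np.asarray(self.blackness_steps, float)
        nc, nb = len(self.chromaticness_steps), len(self.blackness_steps)
        self.entries: list[ChartEntry] = []
        self._number_by_code: dict[NCSCode, int] = {}
        for hi, tok in enumerate(self.hue_tokens):
            for ci, c in enumerate(self.chromaticness_steps):
                for bi, b in enumerate(self.blackness_steps):
                    code = NCSCode(b, c, tok)
                    number = hi * nc * nb + ci * nb + bi + 1
                    self.entries.append(ChartEntry(
                        number=number, code=code,
                        anchor_hue_deg=float(self.hue_angles[hi]),
                        representative_rgb=representative_rgb(code)))
                    self._number_by_code[code] = number

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def number_of(self, code: NCSCode) -> int:
        return self._number_by_code[code]

    def code_of(self, number: int) -> NCSCode:
        return self.entries[number - 1].code

    def quantize_hsv(self, hue_deg, saturation, value):
        """Quantize (hue angle, saturation, brightness value) to axis indices.

        ``value`` is the maximum RGB channel (``colorspace.brightness_value``);
        blackness is measured as ``100 * (1 - value)``.  Returns integer index
        arrays (hue_idx, chroma_idx, black_idx) into the chart's axes.
        """
        hi = _nearest_step(hue_deg, self.hue_angles)
        ci = _nearest_step(np.asarray(saturation, float) * 100.0, self._chroma_arr)
        bi = _nearest_step((1.0 - np.asarray(value, float)) * 100.0, self._black_arr)
        return hi, ci, bi

    def quantize_rgb(self, rgb_unit):
        """Quantize unit-range RGB pixels; returns (hue_idx, chroma_idx, black_idx)."""
        hsi = colorspace.rgb_to_hsi(rgb_unit)
        value = colorspace.brightness_value(rgb_unit)
        return self.quantize_hsv(hsi.hue_deg, hsi.saturation, value)

    def code_at(self, hue_idx: int, chroma_idx: int, black_idx: int) -> NCSCode:
        return NCSCode(self.blackness_steps[black_idx],
                       self.chromaticness_steps[chroma_idx],
                       self.hue_tokens[hue_idx])

    def quantize_code(self, rgb_unit) -> NCSCode:
        """Quantize a single unit-range RGB triple to its chart code."""
        hi, ci, bi = self.quantize_rgb(np.asarray(rgb_unit, float))
        return self.code_at(int(hi), int(ci), int(bi))

    def to_frame(self) -> pd.DataFrame:
        """Chart export: number, code, blackness, chromaticness, hue, anchor, RGB."""
        rows = [{
            "number": e.number, "code": str(e.code),
            "blackness": e.code.blackness, "chromaticness": e.code.chromaticness,
            "hue": str(e.code.hue), "anchor_deg": e.anchor_hue_deg,
            "R": e.representative_rgb[0], "G": e.representative_rgb[1],
            "B": e.representative_rgb[2],
        } for e in self.entries]
        return pd.DataFrame(rows)


def build_chart(hue_tokens: Iterable | None = None,
                chromaticness_steps: Iterable | None = None,
                blackness_steps: Iterable | None = None) -> ColorChart:
    """Build a chart; defaults give the full 512-entry (16 x 8 x 4) table."""
    if hue_tokens is None:
        toks = [parse_hue_token(n) for n in HUE_TOKEN_NAMES]
    else:
        toks = [t if isinstance(t, HueToken) else parse_hue_token(t) for t in hue_tokens]
    return ColorChart(
        toks,
        tuple(chromaticness_steps) if chromaticness_steps is not None else CHROMATICNESS_STEPS,
        tuple(blackness_steps) if blackness_steps is not None else BLACKNESS_STEPS,
    )


_DEFAULT_CHART: ColorChart | None = None


def default_chart() -> ColorChart:
    """The shared full 512-code chart (built once, cached)."""
    global _DEFAULT_CHART
    if _DEFAULT_CHART is None:
        _DEFAULT_CHART = build_chart()
    return _DEFAULT_CHART
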