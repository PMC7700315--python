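"""Camera calibration: response curves, flat-field correction, color check.

The camera's channel response is modelled per channel as a monotone
piecewise-linear map through (measured, reference) node pairs on the unit
interval, mirroring the practice of reading values off a plotted nonlinear
response curve by linear interpolation between reference points.  Uneven
chamber illumination is corrected by flat-fielding against a white
reference frame.  Before each measurement session a color check verifies
that known reference patches quantize to their expected codes within a
pixel-fraction tolerance (default ±5 %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.isotonic import IsotonicRegression

from . import colorspace, ncs

__all__ = [
    "CalibrationModel",
    "ColorCheckReport",
    "PatchResult",
    "CHECK_CODES",
    "fit_calibration",
    "identity_calibration",
    "apply_calibration",
    "flat_field",
    "color_check",
    "brown_reference_ramp",
]

#: The five reference colors of the pre-measurement color check.
CHECK_CODES = ("S 1020 G", "S 1040 Y60R", "S 0530 Y", "S 0515 G20Y", "S 2020 G80Y")

CHANNEL_NAMES = ("R", "G", "B")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-channel monotone piecewise-linear response correction.

    ``nodes[c]`` is a pair of arrays (measured, reference), sorted and
    strictly increasing in measured value, both on [0, 1].  Application
    interpolates linearly between nodes and clamps outside the node range.
    """

    nodes: tuple  # 3 x (measured array, reference array)

    def apply_channel(self, channel: int, values: np.ndarray) -> np.ndarray:
        x, y = self.nodes[channel]
        return np.interp(np.asarray(values, float), x, y)

    def apply_unit_rgb(self, rgb: np.ndarray) -> np.ndarray:
        out = np.empty_like(np.asarray(rgb, float))
        for c in range(3):
            out[..., c] = self.apply_channel(c, rgb[..., c])
        return out


def _fit_channel(measured, reference, name: str):
    m = np.asarray(measured, float)
    r = np.asarray(reference, float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError(f"channel {name}: measured/reference must be matching 1-D arrays")
    if np.any((m < 0) | (m > 1)) or np.any((r < 0) | (r > 1)):
        raise ValueError(f"channel {name}: calibration values must lie in [0, 1]")
    order = np.argsort(m, kind="stable")
    m, r = m[order], r[order]
    # average reference values at duplicate measured values
    xs, inverse = np.unique(m, return_inverse=True)
    ys = np.zeros_like(xs)
    counts = np.zeros_like(xs)
    np.add.at(ys, inverse, r)
    np.add.at(counts, inverse, 1)
    ys = ys / counts
    if xs.size < 2:
        raise ValueError(f"channel {name}: need at least 2 distinct measured nodes")
    if np.any(np.diff(ys) < 0):
        warnings.warn(f"channel {name}: non-monotone reference sequence; applying isotonic repair")
        ys = IsotonicRegression(increasing=True).fit_transform(xs, ys)
    return xs, ys


def fit_calibration(pairs) -> CalibrationModel:
    """Fit the per-channel response model.

    Parameters
    ----------
    pairs : sequence of 3 items, or mapping with keys 'R','G','B'
        Each item is a sequence of (measured, reference) pairs in [0, 1].
    """
    if isinstance(pairs, dict):
        per_channel = [pairs[k] for k in CHANNEL_NAMES]
    else:
        per_channel = list(pairs)
        if len(per_channel) != 3:
            raise ValueError("expected calibration pairs for exactly 3 channels")
    nodes = []
    for name, chan in zip(CHANNEL_NAMES, per_channel):
        arr = np.asarray(chan, float).reshape(-1, 2)
        nodes.append(_fit_channel(arr[:, 0], arr[:, 1], name))
    return CalibrationModel(nodes=tuple(nodes))


def identity_calibration() -> CalibrationModel:
    """The no-op model mapping every channel value to itself."""
    node = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    return CalibrationModel(nodes=(node, node, node))


def _requantize(unit: np.ndarray) -> np.ndarray:
    """Unit floats to 8-bit by round-half-up, clipped to [0, 255]."""
    return np.clip(np.floor(unit * 255.0 + 0.5), 0, 255).astype(np.uint8)


def apply_calibration(model: CalibrationModel, image: np.ndarray) -> np.ndarray:
    """Map an 8-bit RGB image through the response model, re-quantized to 8-bit."""
    unit = colorspace.normalize_rgb(image)
    return _requantize(model.apply_unit_rgb(unit))


def flat_field(image: np.ndarray, white_reference: np.ndarray,
               epsilon: float = 1e-3, smooth_sigma: float = 0.0) -> np.ndarray:
    """Correct uneven illumination by dividing out a white reference frame.

    The reference is normalised per channel to its median, so a perfectly
    uniform reference leaves the image unchanged up to rounding and a linear
    illumination ramp is divided out exactly.  ``smooth_sigma`` optionally
    Gaussian-smooths a noisy reference first (a clean reference frame is
    assumed by default).  ``epsilon`` guards zero reference pixels; with
    ``epsilon=0`` a zero pixel raises.
    """
    img = colorspace.normalize_rgb(image)
    ref = colorspace.normalize_rgb(white_reference)
    if img.shape != ref.shape:
        raise ValueError("image and white reference must share dimensions")
    if smooth_sigma > 0:
        ref = np.stack([ndimage.gaussian_filter(ref[..., c], smooth_sigma)
                        for c in range(3)], axis=-1)
    if np.any(ref <= 0):
        if epsilon <= 0:
            raise ValueError("white reference contains zero pixels and epsilon is 0")
        ref = np.maximum(ref, epsilon)
    gain = ref / np.median(ref, axis=(0, 1), keepdims=True)
    corrected = np.clip(img / gain, 0.0, 1.0)
    return _requantize(corrected)


@dataclass(frozen=True)
class PatchResult:
    expected: ncs.NCSCode
    observed_dominant: ncs.NCSCode
    matching_fraction_pct: float
    passed: bool


@dataclass(frozen=True)
class ColorCheckReport:
    patches: tuple          # PatchResult per reference patch
    tolerance_pct: float
    passed: bool = field(default=False)

    def to_rows(self):
        return [{
            "expected": str(p.expected), "observed": str(p.observed_dominant),
            "matching_pct": p.matching_fraction_pct, "passed": p.passed,
        } for p in self.patches]


def _extended_quantizer_axes(chart: ncs.ColorChart, expected: ncs.NCSCode):
    """Axis step sets augmented with the expected code's (possibly off-grid)
    hue angle, chromaticness and blackness, so off-grid reference patches can
    be recognised as themselves rather than as their nearest chart code."""
    angles = list(chart.hue_angles)
    tokens = list(chart.hue_tokens)
    a = ncs.hue_token_to_angle(expected.hue)
    if not any(np.isclose(a, x) for x in angles):
        tokens.append(expected.hue)
        angles.append(a)
    chroma = sorted(set(chart.chromaticness_steps) | {expected.chromaticness})
    black = sorted(set(chart.blackness_steps) | {expected.blackness})
    return np.asarray(angles), tokens, np.asarray(chroma, float), np.asarray(black, float)


def _quantize_patch(chart, expected, rgb_unit):
    angles, tokens, chroma, black = _extended_quantizer_axes(chart, expected)
    hsi = colorspace.rgb_to_hsi(rgb_unit)
    value = colorspace.brightness_value(rgb_unit)
    hi = np.argmin(np.abs(hsi.hue_deg[..., None] - angles), axis=-1)
    ci = np.argmin(np.abs(hsi.saturation[..., None] * 100.0 - chroma), axis=-1)
    bi = np.argmin(np.abs((1.0 - value[..., None]) * 100.0 - black), axis=-1)
    return hi, ci, bi, tokens, chroma, black


def color_check(image: np.ndarray, patch_layout, expected_codes=None,
                tolerance: float = 5.0, chart: ncs.ColorChart | None = None) -> ColorCheckReport:
    """Verify reference patches against their expected codes.

    Parameters
    ----------
    image : 8-bit RGB array
    patch_layout : sequence of (row0, col0, row1, col1) rectangles
        One half-open rectangle per expected code.
    expected_codes : sequence of codes or code strings
        Defaults to the five standard check colors.
    tolerance : float
        A patch passes when at least ``100 - tolerance`` percent of its
        pixels quantize to the expected code.

    Raises
    ------
    ValueError
        If a rectangle lies outside the image bounds or the layout and
        code list disagree in length.
    """
    chart = chart or ncs.default_chart()
    if expected_codes is None:
        expected_codes = CHECK_CODES
    codes = [c if isinstance(c, ncs.NCSCode) else ncs.parse_code(c, strict=False)
             for c in expected_codes]
    rects = list(patch_layout)
    if len(rects) != len(codes):
        raise ValueError("patch layout and expected code list differ in length")
    h, w = image.shape[:2]
    results = []
    for code, (r0, c0, r1, c1) in zip(codes, rects):
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"patch rectangle {(r0, c0, r1, c1)} outside image bounds")
        patch = colorspace.normalize_rgb(image[r0:r1, c0:c1])
        hi, ci, bi, tokens, chroma, black = _quantize_patch(chart, code, patch)
        exp_hi = int(np.argmin(np.abs(np.asarray([ncs.hue_token_to_angle(t) for t in tokens])
                                      - ncs.hue_token_to_angle(code.hue))))
        exp_ci = int(np.argmin(np.abs(chroma - code.chromaticness)))
        exp_bi = int(np.argmin(np.abs(black - code.blackness)))
        match = (hi == exp_hi) & (ci == exp_ci) & (bi == exp_bi)
        frac = 100.0 * float(np.mean(match))
        # dominant observed code, reported on the extended axes
        flat = (hi.ravel() * len(chroma) + ci.ravel()) * len(black) + bi.ravel()
        top = int(np.bincount(flat).argmax())
        t_hi, rem = divmod(top, len(chroma) * len(black))
        t_ci, t_bi = divmod(rem, len(black))
        observed = ncs.NCSCode(int(black[t_bi]), int(chroma[t_ci]), tokens[t_hi])
        results.append(PatchResult(code, observed, frac, frac >= 100.0 - tolerance))
    return ColorCheckReport(patches=tuple(results), tolerance_pct=tolerance,
                            passed=all(p.passed for p in results))


def brown_reference_ramp(n: int = 15):
    """Synthetic stand-in for a 15-step brown intensity-reference series.

    The official oven-browning reference values are not public; this ramp
    exists purely to exercise the response-curve fitting and is
    non-normative.  Browns are generated at hue 40°, saturation 0.55, with
    intensity descending across the series; returns (rgb_triples, intensities).
    """
    intens = np.linspace(0.85, 0.15, n)
    scale = colorspace.max_intensity(40.0, 0.55)
    rgb = colorspace.hsi_to_rgb(np.full(n, 40.0), np.full(n, 0.55),
                                np.minimum(intens, scale))
    return np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8), intens
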