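"""Synthetic fixtures: chart images, fruit scenes, ripening series.

No public image set accompanies the measurement protocol, so every pipeline
stage is exercised against generated scenes that carry machine-readable
ground truth: an elliptical "fruit" on a uniform chroma-key background,
painted with a known mixture of chart colors (plus optional pure-black and
out-of-arc red fractions), with optional Gaussian channel noise and a
multiplicative illumination ramp.  Composition fractions are realised as
contiguous angular sectors by default (so connected-component logic is also
exercised); a speckle mode scatters them randomly instead.

Scene geometry defaults mirror the measuring camera: 1280 x 1024 pixels,
8 bits per channel.  Tests scale the canvas down for speed; the generator
is exact at any size (sector pixel counts match the requested fractions to
the single pixel by largest-remainder rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import colorspace, ncs
from .segmentation import BackgroundSpec

__all__ = [
    "CompositionSpec",
    "SeriesSpec",
    "FruitTruth",
    "make_chart_image",
    "make_fruit_image",
    "make_white_reference",
    "simulate_series",
]

#: Render color for the out-of-arc RED class: hue 10 degrees, vivid.
_RED_HSI = (10.0, 0.7, None)

DEFAULT_SHAPE = (1024, 1280)   # rows x cols, the camera's 1280 x 1024 frame


@dataclass(frozen=True)
class CompositionSpec:
    """Ground-truth color mixture of a synthetic fruit.

    ``entries`` maps chart codes to fractions of the fruit surface; together
    with ``black_fraction`` and ``red_fraction`` they must sum to 1.
    """

    entries: tuple                 # ((NCSCode, fraction), ...)
    black_fraction: float = 0.0
    red_fraction: float = 0.0

    def __post_init__(self):
        total = sum(f for _, f in self.entries) + self.black_fraction + self.red_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, expected 1")
        if any(f < 0 for _, f in self.entries) or self.black_fraction < 0 or self.red_fraction < 0:
            raise ValueError("fractions must be non-negative")

    @classmethod
    def of(cls, mapping: dict, black: float = 0.0, red: float = 0.0) -> "CompositionSpec":
        """Build from a {code or code string: fraction} mapping."""
        entries = tuple(
            (c if isinstance(c, ncs.NCSCode) else ncs.parse_code(str(c)), float(f))
            for c, f in mapping.items())
        return cls(entries=entries, black_fraction=float(black), red_fraction=float(red))


@dataclass(frozen=True)
class FruitTruth:
    """Machine-readable ground truth accompanying a generated fruit scene."""

    background_mask: np.ndarray
    black_mask: np.ndarray
    red_mask: np.ndarray
    color_mask: np.ndarray
    code_pixels: dict              # code str -> exact pixel count
    fruit_pixels: int

    @property
    def code_fractions_pct(self) -> dict:
        """Exact code shares as percent of the fruit surface."""
        return {k: 100.0 * v / self.fruit_pixels for k, v in self.code_pixels.items()}


def make_chart_image(codes=None, patch_px: int = 32, n_cols: int | None = None,
                     chart: ncs.ColorChart | None = None):
    """Render codes as a grid of uniform patches of their representative colors.

    Returns ``(image, layout)`` where layout is the list of half-open
    (row0, col0, row1, col1) rectangles in code order, suitable for
    ``calibration.color_check``.
    """
    chart = chart or ncs.default_chart()
    if codes is None:
        codes = [e.code for e in chart]
    codes = [c if isinstance(c, ncs.NCSCode) else ncs.parse_code(str(c), strict=False)
             for c in codes]
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    n = len(codes)
    cols = n_cols or int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    img = np.zeros((rows * patch_px, cols * patch_px, 3), dtype=np.uint8)
    layout = []
    for i, code in enumerate(codes):
        r, c = divmod(i, cols)
        r0, c0 = r * patch_px, c * patch_px
        img[r0:r0 + patch_px, c0:c0 + patch_px] = ncs.representative_rgb(code)
        layout.append((r0, c0, r0 + patch_px, c0 + patch_px))
    return img, layout


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` matching fractions to one pixel."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _red_rgb() -> np.ndarray:
    h, s, _ = _RED_HSI
    i = 0.6 * float(colorspace.max_intensity(h, s))
    return np.clip(np.round(colorspace.hsi_to_rgb(h, s, i) * 255), 0, 255).astype(np.uint8)


def make_fruit_image(spec: CompositionSpec, shape: tuple = DEFAULT_SHAPE,
                     center: tuple | None = None, axes: tuple | None = None,
                     noise_sigma: float = 0.0, illumination: float = 0.0,
                     seed: int | None = None, speckle: bool = False,
                     background: BackgroundSpec | None = None):
    """Render an elliptical fruit with a known color composition.

    Parameters
    ----------
    spec : CompositionSpec
        Target mixture; realised to within one pixel.
    shape : (rows, cols)
        Canvas size; default mirrors the camera frame.
    noise_sigma : float
        Gaussian channel noise in digital levels (std dev on 0-255 scale).
    illumination : float
        Amplitude of a multiplicative left-to-right ramp, e.g. 0.2 scales
        columns from x0.9 to x1.1 across the frame.
    speckle : bool
        Scatter composition fractions randomly instead of contiguous
        angular sectors.

    Returns
    -------
    (image, FruitTruth) — the 8-bit scene and its exact ground truth.
    Identical arguments and seed reproduce the image bit for bit.
    """
    rng = np.random.default_rng(seed)
    background = background or BackgroundSpec()
    nrow, ncol = shape
    cy, cx = center if center is not None else ((nrow - 1) / 2.0, (ncol - 1) / 2.0)
    ay, ax = axes if axes is not None else (0.38 * nrow, 0.38 * ncol)
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    fruit = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    n_fruit = int(fruit.sum())
    if n_fruit == 0:
        raise ValueError("ellipse geometry yields no fruit pixels")

    frs, fcs = np.nonzero(fruit)
    if speckle:
        order = rng.permutation(n_fruit)
    else:
        order = np.argsort(np.arctan2(frs - cy, fcs - cx), kind="stable")

    labels = [str(code) for code, _ in spec.entries] + ["__black__", "__red__"]
    fractions = np.array([f for _, f in spec.entries]
                         + [spec.black_fraction, spec.red_fraction])
    counts = _largest_remainder_counts(fractions, n_fruit)
    colors = [np.asarray(ncs.representative_rgb(code), np.uint8) for code, _ in spec.entries]
    colors += [np.zeros(3, np.uint8), _red_rgb()]

    img = np.empty((nrow, ncol, 3), dtype=np.uint8)
    img[...] = np.asarray(background.color_rgb, np.uint8)
    black_mask = np.zeros(shape, bool)
    red_mask = np.zeros(shape, bool)
    code_pixels: dict = {}
    start = 0
    for label, cnt, col in zip(labels, counts, colors):
        sel = order[start:start + cnt]
        start += cnt
        img[frs[sel], fcs[sel]] = col
        if label == "__black__":
            black_mask[frs[sel], fcs[sel]] = True
        elif label == "__red__":
            red_mask[frs[sel], fcs[sel]] = True
        elif cnt:
            code_pixels[label] = code_pixels.get(label, 0) + int(cnt)

    out = img.astype(float)
    if illumination:
        ramp = 1.0 + illumination * (np.arange(ncol) / max(ncol - 1, 1) - 0.5)
        out *= ramp[None, :, None]
    if noise_sigma:
        out += rng.normal(0.0, noise_sigma, size=out.shape)
    img = np.clip(np.round(out), 0, 255).astype(np.uint8)

    color_mask = fruit & ~black_mask & ~red_mask
    truth = FruitTruth(background_mask=~fruit, black_mask=black_mask, red_mask=red_mask,
                       color_mask=color_mask, code_pixels=code_pixels, fruit_pixels=n_fruit)
    return img, truth


def make_white_reference(shape: tuple = DEFAULT_SHAPE, illumination: float = 0.0,
                         level: int = 255) -> np.ndarray:
    """A nominally uniform white frame carrying the same illumination ramp
    as :func:`make_fruit_image`, for flat-field correction tests."""
    nrow, ncol = shape
    out = np.full((nrow, ncol, 3), float(level))
    if illumination:
        ramp = 1.0 + illumination * (np.arange(ncol) / max(ncol - 1, 1) - 0.5)
        out *= ramp[None, :, None]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SeriesSpec:
    """Parameters of a simulated ripening series.

    The rising code's share follows a logistic from ``rising_start`` to
    ``rising_end`` (fractions of the fruit surface) with midpoint
    ``midpoint_h`` hours and rate ``rate_per_h``; the falling code mirrors
    the motion between its own endpoints.  ``peak_hour`` switches the
    rising code to a rise-and-fall (Gaussian bump) profile, as seen for
    peel colors that overshoot and recede late in ripening.  Background
    codes hold constant shares; the whole mixture is renormalised to 1.
    """

    rising_code: ncs.NCSCode
    falling_code: ncs.NCSCode
    background: tuple | None = None  # ((NCSCode, fraction), ...); None = defaults
    hours: tuple = (0, 12, 24, 36, 48, 60, 70)
    midpoint_h: float = 36.0
    rate_per_h: float = 0.15
    rising_start: float = 0.092
    rising_end: float = 0.291
    falling_start: float = 0.27
    falling_end: float = 0.049
    peak_hour: float | None = None  # bump profile when set
    peak_value: float = 0.426
    peak_width_h: float = 18.0
    seed: int = 0

    @classmethod
    def of(cls, rising, falling, background: dict | None = None, **kw) -> "SeriesSpec":
        parse = lambda c: c if isinstance(c, ncs.NCSCode) else ncs.parse_code(str(c))
        if background is not None:
            kw["background"] = tuple((parse(c), float(f)) for c, f in background.items())
        return cls(rising_code=parse(rising), falling_code=parse(falling), **kw)

    def background_entries(self) -> tuple:
        if self.background is not None:
            return self.background
        # near-constant bystander colors filling most of the non-indicator
        # surface, so indicator endpoints survive renormalisation
        return tuple((ncs.parse_code(c), f) for c, f in
                     (("0520-G90Y", 0.25), ("0530-Y", 0.25), ("1030-Y10R", 0.14)))


def _logistic(t, lo, hi, mid, rate):
    return lo + (hi - lo) / (1.0 + np.exp(-rate * (t - mid)))


def simulate_series(spec: SeriesSpec) -> list:
    """Ground-truth compositions over time: list of (hour, CompositionSpec)."""
    out = []
    for h in spec.hours:
        if spec.peak_hour is None:
            up = _logistic(h, spec.rising_start, spec.rising_end,
                           spec.midpoint_h, spec.rate_per_h)
        else:
            base = spec.rising_start
            up = base + (spec.peak_value - base) * np.exp(
                -(((h - spec.peak_hour) / spec.peak_width_h) ** 2))
        down = _logistic(h, spec.falling_start, spec.falling_end,
                         spec.midpoint_h, spec.rate_per_h)
        mix = {spec.rising_code: float(up), spec.falling_code: float(down)}
        for code, f in spec.background_entries():
            mix[code] = mix.get(code, 0.0) + float(f)
        total = sum(mix.values())
        comp = CompositionSpec.of({c: f / total for c, f in mix.items()})
        out.append((float(h), comp))
    return out
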