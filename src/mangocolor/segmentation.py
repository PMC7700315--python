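"""Fruit-region extraction and black/red/COLOR pixel accounting.

The fruit is found by chroma-keying the (nominally uniform) background,
keeping the largest connected non-background component and filling holes.
Fruit pixels are then split into three disjoint classes: BLACK (too dark to
carry reliable hue information), RED (chromatic hue beyond the red end of
the code chart's green-to-red arc) and COLOR — the evaluable remainder on
which every histogram and code share is based.  All class percentages are
reported relative to the total fruit surface and sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import colorspace, ncs

__all__ = [
    "BackgroundSpec",
    "ClassThresholds",
    "SegmentationResult",
    "EmptySceneError",
    "detect_foreground",
    "classify_pixels",
    "segment",
]


class EmptySceneError(ValueError):
    """Raised when no foreground component is found in the scene."""


@dataclass(frozen=True)
class BackgroundSpec:
    """Nominal background color (8-bit RGB) and a chroma-key distance threshold
    in normalised RGB (Euclidean).  Default: saturated blue, far outside the
    chart's green-to-red arc."""

    color_rgb: tuple = (0, 0, 255)
    distance_threshold: float = 0.25


@dataclass(frozen=True)
class ClassThresholds:
    """Cutoffs for the out-of-range classes.

    black_intensity_floor : fruit pixels with intensity below this are BLACK.
    hue_margin_deg : the evaluable hue window extends this many degrees past
        the chart arc on both ends (arc = [angle(Y50R), angle(G)] = [30, 120]).
    min_chromatic_saturation : pixels below this saturation have no usable
        hue and are never classified RED.
    """

    black_intensity_floor: float = 0.10
    hue_margin_deg: float = 3.0
    min_chromatic_saturation: float = 0.05


@dataclass(frozen=True)
class SegmentationResult:
    """Disjoint background/black/red/COLOR masks with fruit-surface percentages."""

    background_mask: np.ndarray
    black_mask: np.ndarray
    red_mask: np.ndarray
    color_mask: np.ndarray

    @property
    def fruit_mask(self) -> np.ndarray:
        return ~self.background_mask

    @property
    def fruit_pixels(self) -> int:
        return int(self.fruit_mask.sum())

    @property
    def percentages(self) -> dict:
        """Black/red/COLOR shares of the fruit surface, in percent (sum 100)."""
        n = self.fruit_pixels
        if n == 0:
            return {"black": 0.0, "red": 0.0, "color": 0.0}
        return {
            "black": 100.0 * self.black_mask.sum() / n,
            "red": 100.0 * self.red_mask.sum() / n,
            "color": 100.0 * self.color_mask.sum() / n,
        }


def detect_foreground(image: np.ndarray, background: BackgroundSpec | None = None,
                      keep_all_components: bool = False) -> np.ndarray:
    """Background mask of an 8-bit RGB scene by chroma-key + components.

    Pixels within the chroma distance of the nominal background color are
    background; of the remaining components the largest is kept as the fruit
    (all are kept in multi-object mode) and its holes are filled.

    Returns the boolean background mask (True = background).

    Raises
    ------
    EmptySceneError
        If no non-background component exists.
    """
    background = background or BackgroundSpec()
    unit = colorspace.normalize_rgb(image)
    ref = np.asarray(background.color_rgb, float) / 255.0
    dist = np.sqrt(((unit - ref) ** 2).sum(axis=-1))
    candidate = dist > background.distance_threshold
    labels, n = ndimage.label(candidate)
    if n == 0:
        raise EmptySceneError("no foreground component found")
    if keep_all_components:
        fruit = candidate
    else:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fruit = labels == (1 + int(np.argmax(sizes)))
    fruit = ndimage.binary_fill_holes(fruit)
    return ~fruit


def classify_pixels(hsi: colorspace.HSIField, background_mask: np.ndarray,
                    thresholds: ClassThresholds | None = None) -> SegmentationResult:
    """Split fruit pixels into disjoint BLACK / RED / COLOR classes.

    BLACK takes precedence over RED; COLOR is the remainder, so the three
    classes partition the fruit surface exactly.
    """
    th = thresholds or ClassThresholds()
    fruit = ~np.asarray(background_mask, bool)
    hue_lo = ncs.hue_token_to_angle(ncs.parse_hue_token("Y50R")) - th.hue_margin_deg
    hue_hi = ncs.HUE_ANCHORS_DEG["G"] + th.hue_margin_deg
    black = fruit & (hsi.intensity < th.black_intensity_floor)
    chromatic = hsi.chromatic & (hsi.saturation >= th.min_chromatic_saturation)
    out_of_arc = chromatic & ((hsi.hue_deg < hue_lo) | (hsi.hue_deg > hue_hi))
    red = fruit & ~black & out_of_arc
    color = fruit & ~black & ~red
    return SegmentationResult(background_mask=~fruit, black_mask=black,
                              red_mask=red, color_mask=color)


def segment(image: np.ndarray, background: BackgroundSpec | None = None,
            thresholds: ClassThresholds | None = None,
            keep_all_components: bool = False) -> tuple:
    """Foreground detection + pixel classification in one call.

    Returns ``(SegmentationResult, HSIField)`` for the whole image.
    """
    bg = detect_foreground(image, background, keep_all_components)
    hsi = colorspace.rgb_to_hsi(colorspace.normalize_rgb(image))
    return classify_pixels(hsi, bg, thresholds), hsi
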