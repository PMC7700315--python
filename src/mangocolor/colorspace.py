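"""RGB <-> HSI conversion for 8-bit color images.

The measurement pipeline works in a geometric HSI space: intensity is the
channel mean, saturation is ``1 - min/mean`` and hue comes from the classical
arccos construction on the RGB chromaticity triangle, reflected into
(180, 360) degrees when blue exceeds green.  Achromatic pixels (R = G = B)
have no defined hue; they are reported as 0 degrees and flagged so downstream
histograms can exclude them.

All functions are vectorised over arbitrary leading array dimensions; the
last axis of an RGB array holds the three channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HSIField",
    "normalize_rgb",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "max_intensity",
    "brightness_value",
]


@dataclass(frozen=True)
class HSIField:
    """Per-pixel hue angle, saturation fraction and intensity fraction.

    Attributes
    ----------
    hue_deg : ndarray
        Hue angle in [0, 360); 0 where the hue is undefined.
    saturation : ndarray
        Saturation in [0, 1]; 0 for achromatic pixels.
    intensity : ndarray
        Channel mean in [0, 1]; 0 only for pure black.
    chromatic : ndarray of bool
        True where the hue angle is defined (pixel not achromatic).
    """

    hue_deg: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray
    chromatic: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.hue_deg.shape


def normalize_rgb(rgb) -> np.ndarray:
    """Scale 8-bit RGB values from [0, 255] to unit floats by division by 255.

    Raises
    ------
    ValueError
        If any component falls outside [0, 255].
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("RGB components must lie in [0, 255]")
    return arr / 255.0


def rgb_to_hsi(rgb) -> HSIField:
    """Convert unit-range RGB to hue (degrees), saturation and intensity.

    Parameters
    ----------
    rgb : array_like, shape (..., 3)
        Normalised RGB with components in [0, 1].
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold the three RGB channels")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    intensity = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(intensity > 0, 1.0 - mn / np.where(intensity > 0, intensity, 1.0), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den_sq = (r - g) ** 2 + (r - b) * (g - b)
    chromatic = den_sq > 0
    den = np.sqrt(np.where(chromatic, den_sq, 1.0))
    cos_ang = np.clip(num / den, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos_ang))
    hue = np.where(b > g, 360.0 - ang, ang)
    hue = np.where(chromatic, hue, 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)
    return HSIField(hue_deg=hue, saturation=saturation, intensity=intensity,
                    chromatic=np.asarray(chromatic, dtype=bool))


def _sector_inverse(h, s, i) -> np.ndarray:
    """Raw (unclipped) sector-formula inverse; may leave RGB gamut."""
    shape = np.broadcast(h, s, i).shape
    h, s, i = np.broadcast_to(h, shape), np.broadcast_to(s, shape), np.broadcast_to(i, shape)
    out = np.empty(shape + (3,), dtype=float)
    # channel roles rotate by sector: (primary, derived, minimum)
    roles = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    for sector, (a, bb, c) in enumerate(roles):
        mask = (h >= sector * 120.0) & (h < (sector + 1) * 120.0)
        hh = np.radians(h - sector * 120.0)
        lo = i * (1.0 - s)
        hi = i * (1.0 + s * np.cos(hh) / np.cos(np.radians(60.0) - hh))
        mid = 3.0 * i - (lo + hi)
        out[..., a] = np.where(mask, hi, out[..., a])
        out[..., bb] = np.where(mask, mid, out[..., bb])
        out[..., c] = np.where(mask, lo, out[..., c])
    return out


def hsi_to_rgb(hue_deg, saturation, intensity, return_clipped: bool = False):
    """Invert the HSI mapping with the standard 120-degree sector formulas.

    For in-gamut requests ``rgb_to_hsi(hsi_to_rgb(h, s, i))`` round-trips to
    within 1e-6.  Out-of-gamut requests (a channel above 1) are clipped; set
    ``return_clipped=True`` to also receive a boolean flag array marking the
    affected pixels.
    """
    h = np.mod(np.asarray(hue_deg, dtype=float), 360.0)
    s = np.asarray(saturation, dtype=float)
    i = np.asarray(intensity, dtype=float)
    if np.any(s < 0) or np.any(s > 1) or np.any(i < 0) or np.any(i > 1):
        raise ValueError("saturation and intensity must lie in [0, 1]")
    out = _sector_inverse(h, s, i)
    clipped = np.any((out < -1e-12) | (out > 1.0 + 1e-12), axis=-1)
    out = np.clip(out, 0.0, 1.0)
    if return_clipped:
        return out, clipped
    return out


def max_intensity(hue_deg, saturation) -> np.ndarray:
    """Largest intensity representable in RGB gamut at a given hue/saturation.

    The sector inverse is linear in intensity, so the in-gamut ceiling is the
    reciprocal of the largest channel of the inverse evaluated at intensity 1.
    """
    h = np.mod(np.asarray(hue_deg, dtype=float), 360.0)
    s = np.asarray(saturation, dtype=float)
    probe = _sector_inverse(h, s, np.ones(np.broadcast(h, s).shape))
    return 1.0 / probe.max(axis=-1)


def brightness_value(rgb) -> np.ndarray:
    """Maximum channel of unit-range RGB.

    Equals ``intensity / max_intensity(hue, saturation)`` for every pixel and
    is the quantity the code chart's blackness axis is measured against.
    """
    return np.asarray(rgb, dtype=float).max(axis=-1)
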