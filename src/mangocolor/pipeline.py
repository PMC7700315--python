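"""Pipeline configuration and the end-to-end single-image measurement.

The measurement workflow chains the stages in fixed order: optional
flat-field correction, response-curve calibration, foreground detection,
black/red/COLOR classification, code quantization, histogram accounting
and export.  :class:`PipelineConfig` bundles every tunable of that chain
and round-trips losslessly through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import calibration as cal
from . import colorspace, ncs, segmentation
from .histogram import MeasurementRecord, measure_from_masks, modal_refine, quantize_field

__all__ = ["PipelineConfig", "load_calibration_file", "save_calibration_file",
           "measure_image"]


@dataclass
class PipelineConfig:
    """All tunables of the measurement chain; JSON round-trip lossless."""

    hue_tokens: list | None = None              # None = the 16 defaults
    chromaticness_steps: list | None = None
    blackness_steps: list | None = None
    black_intensity_floor: float = 0.10
    hue_margin_deg: float = 3.0
    min_chromatic_saturation: float = 0.05
    background_rgb: list = field(default_factory=lambda: [0, 0, 255])
    background_distance: float = 0.25
    check_tolerance_pct: float = 5.0
    spatial_vote: bool = True       # 3x3 majority-vote code regularisation
    calibration_path: str | None = None
    output_dir: str = "."

    def chart(self) -> ncs.ColorChart:
        return ncs.build_chart(self.hue_tokens, self.chromaticness_steps,
                               self.blackness_steps)

    def thresholds(self) -> segmentation.ClassThresholds:
        return segmentation.ClassThresholds(
            black_intensity_floor=self.black_intensity_floor,
            hue_margin_deg=self.hue_margin_deg,
            min_chromatic_saturation=self.min_chromatic_saturation)

    def background(self) -> segmentation.BackgroundSpec:
        return segmentation.BackgroundSpec(
            color_rgb=tuple(self.background_rgb),
            distance_threshold=self.background_distance)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def save_calibration_file(model: cal.CalibrationModel, path) -> None:
    data = {name: np.column_stack(model.nodes[i]).tolist()
            for i, name in enumerate(cal.CHANNEL_NAMES)}
    Path(path).write_text(json.dumps(data, indent=2))


def load_calibration_file(path) -> cal.CalibrationModel:
    data = json.loads(Path(path).read_text())
    return cal.fit_calibration({k: np.asarray(v, float) for k, v in data.items()})


def measure_image(image: np.ndarray, config: PipelineConfig | None = None,
                  model: cal.CalibrationModel | None = None,
                  white_reference: np.ndarray | None = None,
                  sample_id: str = "sample", cultivar: str = "NDM",
                  tissue: str = "peel", hour: float = 0.0):
    """Run the full measurement chain on one 8-bit RGB image.

    Returns ``(MeasurementRecord, QuantizedField, SegmentationResult)`` so
    callers can also render the pseudo-color image or export masks.
    """
    config = config or PipelineConfig()
    chart = config.chart()
    if white_reference is not None:
        image = cal.flat_field(image, white_reference)
    if model is None and config.calibration_path:
        model = load_calibration_file(config.calibration_path)
    if model is not None:
        image = cal.apply_calibration(model, image)
    bg_mask = segmentation.detect_foreground(image, config.background())
    unit = colorspace.normalize_rgb(image)
    hsi = colorspace.rgb_to_hsi(unit)
    seg = segmentation.classify_pixels(hsi, bg_mask, config.thresholds())
    qfield = quantize_field(unit, seg.color_mask, chart)
    if config.spatial_vote:
        qfield = modal_refine(qfield, chart)
    record = measure_from_masks(qfield, seg, sample_id=sample_id, cultivar=cultivar,
                                tissue=tissue, hour=hour, chart=chart)
    return record, qfield, seg
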