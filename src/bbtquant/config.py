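"""Pipeline-wide configuration with the clinically fixed defaults.

Every threshold the pipeline applies is collected here so a single YAML file
reproduces a run: 25 px box padding before segmentation, the leftmost 10% of
the image as the calibration ROI, intensity threshold 25 for scale-bar
binarisation, and the 10% area-change criterion for flagging longitudinal
change.  All fields serialise to/from YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass
class PipelineConfig:
    padding_px: int = 25
    roi_fraction: float = 0.10
    binarize_threshold: int = 25
    area_change_pct: float = 10.0
    boundary_tolerance_mode: str = "auto"  # 'auto' (0.75% of diagonal) or an int px
    rounding_mode: str = "round"  # report-ratio rounding: 'round' | 'truncate'
    seed: int = 0
    ocr_backend: str = "fixture"  # 'fixture' (template matcher) | 'easyocr'
    channels_mode: str = "raw_plus_fusion"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def make_ocr_backend(self):
        if self.ocr_backend == "fixture":
            from .ocr import TemplateOcr

            return TemplateOcr(threshold=self.binarize_threshold)
        if self.ocr_backend == "easyocr":
            from .ocr import EasyOcrAdapter

            return EasyOcrAdapter()
        raise ValueError(f"unknown OCR backend {self.ocr_backend!r}")
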