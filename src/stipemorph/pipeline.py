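"""End-to-end feature extraction: image + mask -> 12-feature phenotype record.

`extract_features` chains the measurement stages (component cleanup,
contour, area/perimeter, outer rectangle, thickness profile, skeleton
curvature, masked color statistics, canonical centerline) and converts
pixel quantities to physical units with the mm-per-pixel calibration
coefficient.  `run_batch` maps the extraction over a dataset manifest,
isolating per-sample failures so one bad segmentation does not abort a
batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from stipemorph.analysis import GradingConfig
from stipemorph.calibration import DEFAULT_MM_PER_PX, CalibrationModel, px_to_mm
from stipemorph.centerline import canonical_keypoints, centerline_length
from stipemorph.color import masked_color_stats
from stipemorph.geometry import (
    bounding_rect,
    curvature_of_mask,
    extract_contour,
    measure_region,
    thickness_profile,
)
from stipemorph.io_formats import (
    DatasetManifest,
    PhenotypeRecord,
    read_image_and_mask,
)
from stipemorph.segmentation import ChromaKeyParams, chroma_key_segment, largest_component

logger = logging.getLogger("stipemorph")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters with the reference-rig defaults."""

    mm_per_px: float = DEFAULT_MM_PER_PX
    grading: GradingConfig = field(default_factory=GradingConfig)
    chroma: ChromaKeyParams = field(default_factory=ChromaKeyParams)
    thickness_method: str = "normal"

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")

    @property
    def calibration(self) -> CalibrationModel:
        return CalibrationModel(c=self.mm_per_px)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        calib = raw.get("calibration", {})
        if "mm_per_px" in calib:
            kwargs["mm_per_px"] = float(calib["mm_per_px"])
        if "grading" in raw and "bounds_mm" in raw["grading"]:
            kwargs["grading"] = GradingConfig(bounds_mm=tuple(raw["grading"]["bounds_mm"]))
        chroma = raw.get("chroma", {})
        if chroma:
            kwargs["chroma"] = ChromaKeyParams(
                background=chroma.get("background", "green"),
                dominance_margin=int(chroma.get("dominance_margin", 30)),
            )
        if "thickness_method" in raw:
            kwargs["thickness_method"] = raw["thickness_method"]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "calibration": {"mm_per_px": self.mm_per_px},
                    "grading": {"bounds_mm": list(self.grading.bounds_mm)},
                    "chroma": {
                        "background": self.chroma.background,
                        "dominance_margin": self.chroma.dominance_margin,
                    },
                    "thickness_method": self.thickness_method,
                }
            )
        )


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    config: PipelineConfig | None = None,
    weight_g: Optional[float] = None,
) -> PhenotypeRecord:
    """Measure the 12 basic phenotypic features of one stipe.

    The mask is reduced to its largest 8-connected component, measured in
    pixel space, and converted with the calibration coefficient: lengths by
    ``c``, areas by ``c²`` and curvature by ``1/c`` (per-pixel to per-mm).
    The canonical centerline polyline length fills the optional 13th field
    and ``weight_g`` is passed through untouched.
    """
    cfg = config if config is not None else PipelineConfig()
    cal = cfg.calibration

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as e:
            raise ValueError(f"feature extraction failed at stage '{name}': {e}") from e

    m = stage("largest_component", largest_component, mask)
    stage("extract_contour", extract_contour, m)  # validates a traceable boundary
    area_px, perim_px = stage("measure_region", measure_region, m)
    box = stage("bounding_rect", bounding_rect, m)
    thick = stage("thickness_profile", thickness_profile, m, box, method=cfg.thickness_method)
    kappa_px = stage("curvature_of_mask", curvature_of_mask, m)
    color = stage("masked_color_stats", masked_color_stats, image, m)
    kps = stage("canonical_keypoints", canonical_keypoints, m)
    center_px = centerline_length(kps)

    return PhenotypeRecord(
        outer_rect_length_mm=px_to_mm(box.length, cal),
        outer_rect_width_mm=px_to_mm(box.width_short, cal),
        area_mm2=px_to_mm(area_px, cal, power=2),
        perimeter_mm=px_to_mm(perim_px, cal),
        thickness_max_mm=px_to_mm(thick.max, cal),
        thickness_min_mm=px_to_mm(thick.min, cal),
        thickness_mean_mm=px_to_mm(thick.mean, cal),
        curvature_per_mm=px_to_mm(kappa_px, cal, power=-1),
        r_mean=color.r_mean,
        g_mean=color.g_mean,
        b_mean=color.b_mean,
        gray_mean=color.gray_mean,
        centerline_length_mm=px_to_mm(center_px, cal),
        weight_g=weight_g,
    )


def run_batch(
    manifest: DatasetManifest,
    config: PipelineConfig | None = None,
    base_dir=".",
) -> tuple[list[PhenotypeRecord], list[tuple[str, str, str]]]:
    """Extract features for every manifest row, in manifest order.

    Rows whose extraction fails are logged and skipped; the function
    returns ``(records, failures)`` where each failure is
    ``(sample_id, background, message)``.
    """
    cfg = config if config is not None else PipelineConfig()
    base = Path(base_dir)
    records: list[PhenotypeRecord] = []
    failures: list[tuple[str, str, str]] = []
    for rec in manifest.records:
        try:
            if rec.mask_path is not None:
                image, mask = read_image_and_mask(base / rec.image_path, base / rec.mask_path)
            else:
                from PIL import Image

                image = np.asarray(Image.open(base / rec.image_path).convert("RGB"))
                chroma = ChromaKeyParams(
                    background=rec.background,
                    dominance_margin=cfg.chroma.dominance_margin,
                )
                mask = chroma_key_segment(image, chroma)
            features = extract_features(image, mask, cfg, weight_g=rec.weight_g)
        except (ValueError, FileNotFoundError, OSError) as e:
            logger.warning("sample=%s background=%s FAILED: %s", rec.sample_id, rec.background, e)
            failures.append((rec.sample_id, rec.background, str(e)))
            continue
        logger.info(
            "sample=%s background=%s length_mm=%.3f width_mm=%.3f area_mm2=%.3f",
            rec.sample_id,
            rec.background,
            features.outer_rect_length_mm,
            features.outer_rect_width_mm,
            features.area_mm2,
        )
        records.append(features)
    logger.info("batch complete: %d ok, %d failed", len(records), len(failures))
    return records, failures
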