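"""External artifacts: images, masks, feature tables, pose annotations, manifests.

File dialects
-------------
* Images: PNG/JPEG via Pillow; masks are single-channel PNGs binarized at
  value > 127.
* Feature table: CSV with a fixed column order (the 12 mandatory phenotype
  fields, then the optional centerline length and weight), values
  round-tripping at 6 significant digits.
* Pose annotation: one object per text line,
  ``class cx cy w h x1 y1 v1 ... x5 y5 v5`` (20 tokens), all fractions of
  the image dimensions at 6 decimals, visibility flag 2 = labeled-visible.
* Manifest: CSV with columns (sample_id, background, image_path, mask_path,
  weight_g); one row per (sample, background) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

MASK_THRESHOLD = 127  # 8-bit mask value above which a pixel is foreground

#: Fixed column order of the feature table (12 mandatory + 2 optional).
FEATURE_COLUMNS = (
    "outer_rect_length_mm",
    "outer_rect_width_mm",
    "area_mm2",
    "perimeter_mm",
    "thickness_max_mm",
    "thickness_min_mm",
    "thickness_mean_mm",
    "curvature_per_mm",
    "r_mean",
    "g_mean",
    "b_mean",
    "gray_mean",
)
OPTIONAL_COLUMNS = ("centerline_length_mm", "weight_g")

BACKGROUNDS = ("red", "green")


@dataclass(frozen=True)
class PhenotypeRecord:
    """The 12 basic phenotypic features of one stipe, in physical units."""

    outer_rect_length_mm: float
    outer_rect_width_mm: float
    area_mm2: float
    perimeter_mm: float
    thickness_max_mm: float
    thickness_min_mm: float
    thickness_mean_mm: float
    curvature_per_mm: float
    r_mean: float
    g_mean: float
    b_mean: float
    gray_mean: float
    centerline_length_mm: Optional[float] = None
    weight_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outer_rect_length_mm < self.outer_rect_width_mm:
            raise ValueError("outer rectangle length must be >= width")
        if not (
            self.thickness_min_mm <= self.thickness_mean_mm <= self.thickness_max_mm
        ):
            raise ValueError("thickness order violated: need min <= mean <= max")
        for name in ("r_mean", "g_mean", "b_mean", "gray_mean"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255], got {v}")
        for name in (
            "outer_rect_length_mm",
            "outer_rect_width_mm",
            "area_mm2",
            "perimeter_mm",
            "thickness_min_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in FEATURE_COLUMNS + OPTIONAL_COLUMNS}


@dataclass(frozen=True)
class PoseAnnotation:
    """Normalized box + five-keypoint quintuplet for one centerline object."""

    class_id: int
    box_center_x: float
    box_center_y: float
    box_w: float
    box_h: float
    keypoints: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        if len(self.keypoints) != 5:
            raise ValueError(f"exactly 5 keypoints required, got {len(self.keypoints)}")
        if not (self.box_w > 0 and self.box_h > 0):
            raise ValueError("box width and height must be > 0")
        for v in (self.box_center_x, self.box_center_y, self.box_w, self.box_h):
            if not 0 <= v <= 1:
                raise ValueError(f"box fraction {v} outside [0, 1]")
        for x, y, vis in self.keypoints:
            if not (0 <= x <= 1 and 0 <= y <= 1):
                raise ValueError(f"keypoint fraction ({x}, {y}) outside [0, 1]")
            if vis not in (0, 1, 2):
                raise ValueError(f"visibility flag must be 0, 1 or 2, got {vis}")


@dataclass(frozen=True)
class ManifestRecord:
    sample_id: str
    background: str
    image_path: str
    mask_path: Optional[str] = None
    weight_g: Optional[float] = None


@dataclass(frozen=True)
class DatasetManifest:
    """One record per (sample, background) pair; pairs are unique."""

    records: tuple[ManifestRecord, ...]

    def __post_init__(self) -> None:
        keys = [(r.sample_id, r.background) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sample_id, background) pair in manifest")

    def __len__(self) -> int:
        return len(self.records)


def read_image_and_mask(image_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Load an RGB image and its binary mask; dimensions must match.

    The mask is decoded as single-channel and binarized at value > 127.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(p)
    img = np.asarray(Image.open(image_path).convert("RGB"))
    mask_raw = np.asarray(Image.open(mask_path).convert("L"))
    if img.shape[:2] != mask_raw.shape:
        raise ValueError(
            f"image dimensions {img.shape[:2]} do not match mask {mask_raw.shape}"
        )
    return img, mask_raw > MASK_THRESHOLD


def write_mask(mask: np.ndarray, path) -> None:
    """Save a boolean mask as an 8-bit single-channel PNG (255 = foreground)."""
    Image.fromarray(np.asarray(mask, dtype=bool).astype(np.uint8) * 255).save(path)


def write_image(image: np.ndarray, path) -> None:
    """Save an H×W×3 uint8 RGB image."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def write_feature_table(records: Sequence[PhenotypeRecord], path) -> int:
    """Write records as CSV in the fixed column order; returns the row count.

    Values are formatted at 6 significant digits, which round-trips through
    :func:`read_feature_table` losslessly at that precision.
    """
    recs = list(records)
    if not recs:
        raise ValueError("write_feature_table requires at least one record")
    df = pd.DataFrame([r.as_row() for r in recs], columns=list(FEATURE_COLUMNS + OPTIONAL_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6g")
    return len(recs)


def read_feature_table(path) -> list[PhenotypeRecord]:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing mandatory columns: {missing}")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: float(row[c]) for c in FEATURE_COLUMNS}
        for c in OPTIONAL_COLUMNS:
            if c in df.columns and not pd.isna(row[c]):
                kwargs[c] = float(row[c])
        out.append(PhenotypeRecord(**kwargs))
    return out


def write_pose_annotation(annotation: PoseAnnotation, path) -> None:
    """Write one pose annotation as a single 20-token text line."""
    parts = [str(annotation.class_id)] + [
        f"{v:.6f}"
        for v in (
            annotation.box_center_x,
            annotation.box_center_y,
            annotation.box_w,
            annotation.box_h,
        )
    ]
    for x, y, vis in annotation.keypoints:
        parts += [f"{x:.6f}", f"{y:.6f}", str(vis)]
    Path(path).write_text(" ".join(parts) + "\n")


def read_pose_annotation(path) -> PoseAnnotation:
    """Read a single-object pose annotation line (1 + 4 + 15 = 20 tokens)."""
    tokens = Path(path).read_text().split()
    if len(tokens) != 20:
        raise ValueError(f"pose annotation must have 20 tokens, got {len(tokens)}")
    cls = int(tokens[0])
    cx, cy, w, h = (float(t) for t in tokens[1:5])
    kps = []
    for i in range(5):
        x, y, v = tokens[5 + 3 * i : 8 + 3 * i]
        kps.append((float(x), float(y), int(v)))
    return PoseAnnotation(
        class_id=cls,
        box_center_x=cx,
        box_center_y=cy,
        box_w=w,
        box_h=h,
        keypoints=tuple(kps),
    )


def pose_annotation_roundtrip(annotation: PoseAnnotation, path) -> PoseAnnotation:
    """Write then re-read an annotation (equal to the input within 1e-6)."""
    write_pose_annotation(annotation, path)
    return read_pose_annotation(path)


def build_manifest(
    sample_ids: Sequence[str],
    backgrounds: Sequence[str],
    path_template: str = "{sample_id}_{background}.png",
    mask_template: Optional[str] = None,
    weights: Optional[dict] = None,
) -> DatasetManifest:
    """Build a manifest with one record per (sample, background) pair.

    ``path_template`` (and optional ``mask_template``) are formatted with
    ``sample_id`` and ``background``; the record count is
    ``len(sample_ids) * len(backgrounds)``.
    """
    ids = list(sample_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique")
    bgs = list(backgrounds)
    for b in bgs:
        if b not in BACKGROUNDS:
            raise ValueError(f"unknown background {b!r}; expected one of {BACKGROUNDS}")
    records = []
    for sid in ids:
        for bg in bgs:
            records.append(
                ManifestRecord(
                    sample_id=sid,
                    background=bg,
                    image_path=path_template.format(sample_id=sid, background=bg),
                    mask_path=(
                        mask_template.format(sample_id=sid, background=bg)
                        if mask_template
                        else None
                    ),
                    weight_g=(weights or {}).get(sid),
                )
            )
    return DatasetManifest(records=tuple(records))


def write_manifest(manifest: DatasetManifest, path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "background": r.background,
                "image_path": r.image_path,
                "mask_path": r.mask_path,
                "weight_g": r.weight_g,
            }
            for r in manifest.records
        ]
    )
    df.to_csv(path, index=False)


def read_manifest(path) -> DatasetManifest:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            ManifestRecord(
                sample_id=str(row["sample_id"]),
                background=str(row["background"]),
                image_path=str(row["image_path"]),
                mask_path=(
                    None
                    if "mask_path" not in df.columns or pd.isna(row["mask_path"])
                    else str(row["mask_path"])
                ),
                weight_g=(
                    None
                    if "weight_g" not in df.columns or pd.isna(row["weight_g"])
                    else float(row["weight_g"])
                ),
            )
        )
    return DatasetManifest(records=tuple(records))
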