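"""Color statistics restricted to the foreground mask.

Channel means, per-channel 256-bin histograms and the mean luminance are
computed over foreground pixels only.  Luminance uses the ITU-R BT.601
weights gray = 0.299 R + 0.587 G + 0.114 B, the default of common imaging
stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class ColorStats:
    r_mean: float
    g_mean: float
    b_mean: float
    gray_mean: float
    histograms: tuple[np.ndarray, np.ndarray, np.ndarray]

    @property
    def pixel_count(self) -> int:
        return int(self.histograms[0].sum())


def masked_color_stats(image: np.ndarray, mask: np.ndarray) -> ColorStats:
    """Compute color statistics of the pixels inside the mask.

    Background pixels never influence any statistic; each histogram sums to
    the foreground pixel count.
    """
    img = np.asarray(image)
    m = np.asarray(mask, dtype=bool)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    if img.shape[:2] != m.shape:
        raise ValueError(f"image {img.shape[:2]} and mask {m.shape} dimensions differ")
    if not m.any():
        raise ValueError("masked_color_stats requires a nonempty mask")
    fg = img[m].astype(np.float64)  # N×3
    means = fg.mean(axis=0)
    gray_mean = float((fg @ np.asarray(GRAY_WEIGHTS)).mean())
    hists = tuple(
        np.bincount(img[..., ch][m].astype(np.int64), minlength=256) for ch in range(3)
    )
    return ColorStats(
        r_mean=float(means[0]),
        g_mean=float(means[1]),
        b_mean=float(means[2]),
        gray_mean=gray_mean,
        histograms=hists,  # type: ignore[arg-type]
    )
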