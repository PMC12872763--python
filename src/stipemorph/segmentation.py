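"""Mask acquisition: chroma-key fallback and connected-component cleanup.

Stipes are imaged on uniform red or green background plates, so when no
segmentation mask is supplied a classical chroma key recovers the object: a
pixel is background iff its background-channel intensity dominates both
other channels by at least ``dominance_margin``; the foreground is the
complement with interior holes filled (glare inside the stipe must not
puncture the mask).  External learned segmenters can be plugged in through
the provider callable contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

_CHANNEL = {"red": 0, "green": 1}

#: 8-connectivity structuring element shared across the package.
STRUCT_8 = np.ones((3, 3), dtype=bool)

#: Signature for external box-prompted mask providers: (image, box or None) -> mask.
MaskProvider = Callable[[np.ndarray, Optional[tuple[int, int, int, int]]], np.ndarray]


@dataclass(frozen=True)
class ChromaKeyParams:
    background: str = "green"
    dominance_margin: int = 30

    def __post_init__(self) -> None:
        if self.background not in _CHANNEL:
            raise ValueError(f"background must be 'red' or 'green', got {self.background!r}")
        if not 0 <= self.dominance_margin <= 255:
            raise ValueError("dominance_margin must lie in [0, 255]")


def chroma_key_segment(image: np.ndarray, params: ChromaKeyParams | None = None) -> np.ndarray:
    """Segment the foreground of an image on a uniform red/green background.

    Returns a boolean mask of the same height/width as the image, with
    interior holes filled.
    """
    p = params if params is not None else ChromaKeyParams()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    chans = img.astype(np.int16)
    bg = _CHANNEL[p.background]
    others = [i for i in range(3) if i != bg]
    is_background = (chans[..., bg] - chans[..., others[0]] >= p.dominance_margin) & (
        chans[..., bg] - chans[..., others[1]] >= p.dominance_margin
    )
    mask = ~is_background
    return ndimage.binary_fill_holes(mask)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Size ties are broken by the smallest top-left bounding-box corner in
    row-major order.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("largest_component requires a nonempty mask")
    labels, n = ndimage.label(m, structure=STRUCT_8)
    if n == 1:
        return m
    sizes = ndimage.sum_labels(m, labels, index=range(1, n + 1))
    best = None
    best_key = None
    objects = ndimage.find_objects(labels)
    for i in range(n):
        sl = objects[i]
        # larger size wins; ties go to the smallest (row, col) bbox corner
        key = (-sizes[i], sl[0].start, sl[1].start)
        if best_key is None or key < best_key:
            best_key = key
            best = i + 1
    return labels == best
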