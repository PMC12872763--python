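"""Synthetic fixtures with analytic ground truth.

Three shapes are rendered as binary masks (pixel is foreground iff its
center satisfies the analytic inequality, which is unbiased for area to
first order):

* ``rectangle`` — a straight band of length L and thickness T; truth:
  area L·T, curvature 0, thickness T, centerline L.
* ``curved_band`` — an annular sector of centerline radius R, half-thickness
  t and angular extent θ, oriented with its chord horizontal; truth:
  area 2Rtθ, perimeter 2Rθ + 4t, thickness 2t, curvature 1/R, centerline Rθ.
* ``disc`` — a filled disc of diameter d (a stand-in for coin reference
  objects); truth: area π(d/2)², perimeter πd, bounding extents d×d.

``render`` paints a mask onto a uniform red or green background plate and
can fuzz the boundary with seeded radial noise, emulating the fluffy edge
of real stipes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_MARGIN = 8  # background border around every fixture, px

BACKGROUND_COLORS = {"red": (200, 0, 0), "green": (0, 200, 0)}
DEFAULT_FOREGROUND = (120, 110, 100)

MIN_THETA = 0.05  # rad; below this the sector rasterization degenerates


@dataclass(frozen=True)
class GroundTruth:
    """Analytic ground truth of a synthetic fixture (pixel units)."""

    area_px2: float
    perimeter_px: float
    thickness_px: float
    curvature_per_px: float
    centerline_px: float
    extent_long_px: float
    extent_short_px: float


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic fixture."""

    shape: str  # rectangle | curved_band | disc
    params: dict = field(default_factory=dict)
    foreground: tuple[int, int, int] = DEFAULT_FOREGROUND
    background: str = "green"
    fuzz_px: float = 0.0
    seed: int = 0

    def build(self) -> tuple[np.ndarray, GroundTruth]:
        if self.shape == "rectangle":
            return make_rectangle(**self.params)
        if self.shape == "curved_band":
            return make_curved_band(**self.params)
        if self.shape == "disc":
            return make_disc(**self.params)
        raise ValueError(f"unknown fixture shape {self.shape!r}")


def make_rectangle(length: int, thickness: int) -> tuple[np.ndarray, GroundTruth]:
    """Straight axis-aligned band of ``length`` × ``thickness`` pixels."""
    if length <= thickness or thickness < 1:
        raise ValueError(
            f"rectangle requires length > thickness >= 1, got ({length}, {thickness})"
        )
    mask = np.zeros((thickness + 2 * _MARGIN, length + 2 * _MARGIN), dtype=bool)
    mask[_MARGIN : _MARGIN + thickness, _MARGIN : _MARGIN + length] = True
    truth = GroundTruth(
        area_px2=float(length * thickness),
        perimeter_px=2.0 * (length + thickness),
        thickness_px=float(thickness),
        curvature_per_px=0.0,
        centerline_px=float(length),
        extent_long_px=float(length),
        extent_short_px=float(thickness),
    )
    return mask, truth


def make_curved_band(
    radius: float, half_thickness: float, theta: float
) -> tuple[np.ndarray, GroundTruth]:
    """Annular sector (curved band) with chord horizontal.

    The band is the set {R−t <= r <= R+t, |φ| <= θ/2} where φ is measured
    from the downward vertical through the arc apex, so the length axis is
    x and the band bulges downward in image coordinates.
    """
    R, t = float(radius), float(half_thickness)
    if not (R > t >= 1):
        raise ValueError(f"curved band requires R > t >= 1, got (R={R}, t={t})")
    if not (MIN_THETA <= theta <= math.pi):
        raise ValueError(f"theta must lie in [{MIN_THETA}, pi], got {theta}")
    half_span = (R + t) * math.sin(theta / 2.0)
    y_top = (R - t) * math.cos(theta / 2.0) if theta <= math.pi else 0.0
    y_bot = R + t
    w = int(math.ceil(2 * half_span)) + 2 * _MARGIN + 1
    h = int(math.ceil(y_bot - y_top)) + 2 * _MARGIN + 1
    # circle center in image coordinates (above the band, may be off-image)
    cx = (w - 1) / 2.0
    cy = _MARGIN - y_top
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    r = np.hypot(dx, dy)
    phi = np.arctan2(dx, dy)  # angle from the downward vertical
    mask = (r >= R - t) & (r <= R + t) & (np.abs(phi) <= theta / 2.0) & (dy > 0)
    truth = GroundTruth(
        area_px2=2.0 * R * t * theta,
        perimeter_px=2.0 * R * theta + 4.0 * t,
        thickness_px=2.0 * t,
        curvature_per_px=1.0 / R,
        centerline_px=R * theta,
        extent_long_px=2.0 * half_span,
        extent_short_px=y_bot - y_top,
    )
    return mask, truth


def make_disc(diameter: int) -> tuple[np.ndarray, GroundTruth]:
    """Filled disc of ``diameter`` pixels (pixel-count extent d×d)."""
    d = int(diameter)
    if d < 3:
        raise ValueError(f"disc diameter must be >= 3 px, got {d}")
    radius = (d - 1) / 2.0
    n = d + 2 * _MARGIN
    c = _MARGIN + radius
    yy, xx = np.mgrid[0:n, 0:n]
    mask = (xx - c) ** 2 + (yy - c) ** 2 <= radius**2 + 1e-9
    truth = GroundTruth(
        area_px2=math.pi * (d / 2.0) ** 2,
        perimeter_px=math.pi * d,
        thickness_px=float(d),
        curvature_per_px=2.0 / d,
        centerline_px=float(d),
        extent_long_px=float(d),
        extent_short_px=float(d),
    )
    return mask, truth


def render(
    mask: np.ndarray,
    fg_color: tuple[int, int, int] = DEFAULT_FOREGROUND,
    background: str = "green",
    fuzz_px: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Paint a mask onto a uniform background plate as an RGB uint8 image.

    With ``fuzz_px > 0`` the boundary is perturbed by a seeded radial
    displacement: each pixel within ``fuzz_px`` of the boundary flips
    according to a uniform per-pixel threshold in [−fuzz, fuzz] applied to
    its signed distance from the boundary.  The same seed always produces a
    bit-identical image.
    """
    if background not in BACKGROUND_COLORS:
        raise ValueError(f"background must be 'red' or 'green', got {background!r}")
    m = np.asarray(mask, dtype=bool)
    if fuzz_px > 0:
        m = _fuzz_mask(m, fuzz_px, seed)
    img = np.empty(m.shape + (3,), dtype=np.uint8)
    img[:] = np.asarray(BACKGROUND_COLORS[background], dtype=np.uint8)
    img[m] = np.asarray(fg_color, dtype=np.uint8)
    return img


def _fuzz_mask(mask: np.ndarray, amplitude: float, seed: int) -> np.ndarray:
    """Perturb the mask boundary by <= ``amplitude`` px of seeded noise."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = inside - outside  # > 0 inside, < 0 outside
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-amplitude, amplitude, size=mask.shape)
    out = signed > noise
    near = np.abs(signed) <= amplitude
    result = mask.copy()
    result[near] = out[near]
    return ndimage.binary_fill_holes(result)
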