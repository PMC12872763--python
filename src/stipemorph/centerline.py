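"""Five-keypoint canonical centerline of an elongated mask.

The centerline is represented by five control points ordered along the
length axis: the two extreme foreground pixels (endpoints) and three
interior points evenly distributed at fractions 1/4, 1/2 and 3/4 of the
length-axis span, each placed at the midpoint between the upper and lower
mask edges of its cross-section.  The centerline length is the 4-segment
polyline length through the five points, and the quintuplet can be emitted
as a normalized pose annotation (class 0, visibility 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from stipemorph.geometry import BoundingBox, bounding_rect, _axis_views
from stipemorph.io_formats import PoseAnnotation

INTERIOR_FRACTIONS = (1 / 4, 1 / 2, 3 / 4)


@dataclass(frozen=True)
class CenterlineKeypoints:
    """Five (x, y) control points, ordered along the length axis."""

    points: tuple[tuple[float, float], ...]
    length_axis: int  # 0 = x, 1 = y

    def __post_init__(self) -> None:
        if len(self.points) != 5:
            raise ValueError(f"exactly 5 keypoints required, got {len(self.points)}")
        u = [p[self.length_axis] for p in self.points]
        if not all(a < b for a, b in zip(u, u[1:])):
            raise ValueError("keypoints must strictly increase along the length axis")


def _fit_midline_curve(mT: np.ndarray, u_min: int, u_max: int):
    """Fit the mid-edge curve over the central 60% of the length axis.

    Returns ``None`` for a straight midline together with its slope, or a
    ((cu, cv), radius) circle from an algebraic (Kåsa) fit.  Sampling many
    columns keeps the extrapolation to the object ends stable, which a
    three-point fit would not.
    """
    span = u_max - u_min
    lo = u_min + int(0.2 * span)
    hi = u_max - int(0.2 * span)
    step = max(1, (hi - lo) // 80)
    us, vs = [], []
    for u in range(lo, hi + 1, step):
        col = np.nonzero(mT[:, u])[0]
        if len(col):
            us.append(float(u))
            vs.append(float(col.min() + col.max()) / 2.0)
    if len(us) < 3:
        return None, 0.0
    ua = np.asarray(us)
    va = np.asarray(vs)
    line_coef, *_ = np.linalg.lstsq(np.c_[ua, np.ones(len(ua))], va, rcond=None)
    slope = float(line_coef[0])
    line_resid = np.abs(va - (slope * ua + float(line_coef[1])))
    if line_resid.max() < 0.5:
        return None, slope  # midline is straight to within raster noise
    A = np.c_[2 * ua, 2 * va, np.ones(len(ua))]
    b = ua**2 + va**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cu, cv = float(sol[0]), float(sol[1])
    r2 = float(sol[2]) + cu * cu + cv * cv
    if not math.isfinite(r2) or r2 <= 0:
        return None, slope
    radius = math.sqrt(r2)
    if radius > 50.0 * max(span, 1):
        return None, slope  # effectively straight
    return ((cu, cv), radius), slope


def _march_to_boundary(
    mT: np.ndarray, start: tuple[float, float], circle, direction: int, slope: float = 0.0
) -> tuple[float, float]:
    """Last foreground pixel center walking along the midline curve.

    ``circle`` is a (center, radius) pair or ``None`` for a straight
    midline; ``direction`` is -1 (decreasing u) or +1.  The walk proceeds in
    0.25 px steps from ``start`` until it leaves the foreground; the
    endpoint keeps the curve's perpendicular coordinate and snaps the
    length-axis coordinate to the last foreground pixel — for a straight
    band this is exactly the extreme foreground pixel of the length axis,
    and for a curved band the midpoint of the end face.
    """
    h, w = mT.shape
    limit = 2.0 * math.hypot(h, w)

    def inside(u: float, v: float) -> bool:
        c = int(math.floor(u + 0.5))
        r = int(math.floor(v + 0.5))
        return 0 <= r < h and 0 <= c < w and mT[r, c]

    u0, v0 = start
    if circle is None:
        if abs(slope) < 1e-9:
            slope = 0.0
        du = 1.0 / math.hypot(1.0, slope)
        dv = slope / math.hypot(1.0, slope)
        last = start
        s = 0.0
        while s <= limit:
            u, v = u0 + direction * s * du, v0 + direction * s * dv
            if not inside(u, v):
                break
            last = (u, v)
            s += 0.25
    else:
        (cu, cv), radius = circle
        phi0 = math.atan2(v0 - cv, u0 - cu)
        last = start
        s = 0.0
        while s <= limit:
            phi = phi0 + direction * (s / radius) * _phi_sign(u0, cu, cv, v0)
            u = cu + radius * math.cos(phi)
            v = cv + radius * math.sin(phi)
            if not inside(u, v):
                break
            last = (u, v)
            s += 0.25
    return float(math.floor(last[0] + 0.5)), last[1]


def _phi_sign(u0: float, cu: float, cv: float, v0: float) -> float:
    # walking direction along the circle that increases u near the apex:
    # d(u)/d(phi) = -R sin(phi); pick the sign that moves u forward
    phi0 = math.atan2(v0 - cv, u0 - cu)
    return -1.0 if math.sin(phi0) > 0 else 1.0


def canonical_keypoints(mask: np.ndarray) -> CenterlineKeypoints:
    """Construct the canonical five-keypoint centerline of a mask.

    The three interior points at fractions {1/4, 1/2, 3/4} of the
    length-axis span sit at (min+max)/2 of the perpendicular coordinate of
    their cross-section.  The two endpoints are found by following the
    midline — a circle (or straight line) fitted to the mid-edge curve over
    the central span — outward in both directions until it leaves the
    foreground: for a straight object this is the extreme foreground pixel
    of the length axis, for a curved one the midpoint of the end cap.
    """
    from stipemorph.geometry import _require_nonempty

    m = _require_nonempty(mask)
    box = bounding_rect(m)
    if box.length < 5:
        raise ValueError(f"length axis must span >= 5 px, got {box.length}")
    mT, u_min, u_max = _axis_views(m, box)
    span = u_max - u_min

    interior: list[tuple[float, float]] = []
    for f in INTERIOR_FRACTIONS:
        u = u_min + round(f * span)
        vs = np.nonzero(mT[:, u])[0]
        if len(vs) == 0:
            raise ValueError(f"empty cross-section at length-axis position {u}")
        interior.append((float(u), float(vs.min() + vs.max()) / 2.0))

    circle, slope = _fit_midline_curve(mT, u_min, u_max)
    lo = _march_to_boundary(mT, interior[0], circle, -1, slope)
    hi = _march_to_boundary(mT, interior[-1], circle, +1, slope)
    pts_uv = [lo, *interior, hi]

    if box.length_axis == 0:
        pts = tuple((u, v) for u, v in pts_uv)
    else:
        pts = tuple((v, u) for u, v in pts_uv)
    return CenterlineKeypoints(points=pts, length_axis=box.length_axis)


def centerline_length(kps: CenterlineKeypoints) -> float:
    """Polyline length (px): the sum of the four segment lengths."""
    p = np.asarray(kps.points, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def keypoints_to_pose(
    kps: CenterlineKeypoints,
    box: BoundingBox,
    image_width: int,
    image_height: int,
    class_id: int = 0,
) -> PoseAnnotation:
    """Normalize the box and quintuplet by the image dimensions.

    Box center is ``(x_min + width/2) / W``; every keypoint gets visibility
    flag 2 (labeled, visible).  Keypoints outside the image are rejected.
    """
    for x, y in kps.points:
        if not (0 <= x <= image_width and 0 <= y <= image_height):
            raise ValueError(f"keypoint ({x}, {y}) outside the {image_width}×{image_height} image")
    return PoseAnnotation(
        class_id=class_id,
        box_center_x=(box.x_min + box.width / 2.0) / image_width,
        box_center_y=(box.y_min + box.height / 2.0) / image_height,
        box_w=box.width / image_width,
        box_h=box.height / image_height,
        keypoints=tuple(
            (x / image_width, y / image_height, 2) for x, y in kps.points
        ),
    )
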