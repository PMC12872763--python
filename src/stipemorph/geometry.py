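"""Shape measurements on single-object binary masks.

All operations work in pixel space with the shared convention: x rightward,
y downward, 0-based, coordinates refer to pixel centers.  The outer contour
is traced through boundary pixel centers (Moore neighbourhood, 8-connected);
area and perimeter come from the shoelace formula and the closed polygon
edge sum.  The "length axis" of an elongated mask is the longer side of its
axis-aligned bounding box; thickness is profiled at four interior stations
along that axis, and curvature is the inverse circumradius of the circle
through the two endpoints and the geodesic midpoint of the skeleton's main
branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

#: Fractional positions of the four thickness stations along the length axis.
THICKNESS_STATIONS = (1 / 5, 2 / 5, 3 / 5, 4 / 5)

# Moore neighbourhood in clockwise order starting from West, as (dr, dc).
_MOORE = (
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
)


@dataclass(frozen=True)
class Contour:
    """Ordered closed polygon through boundary pixel centers.

    ``points`` is an (N, 2) float array of (x, y) vertices; the polygon is
    implicitly closed (last vertex connects back to the first) and oriented
    with positive shoelace area.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
            raise ValueError("contour requires an (N, 2) array with N >= 1")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box over foreground pixels, inclusive pixel-count extents."""

    x_min: int
    y_min: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("bounding box extents must be >= 1 pixel")

    @property
    def length(self) -> int:
        """The longer side (the reported outer-rectangle length)."""
        return max(self.width, self.height)

    @property
    def width_short(self) -> int:
        """The shorter side (the reported outer-rectangle width)."""
        return min(self.width, self.height)

    @property
    def length_axis(self) -> int:
        """0 if the length axis is x (width >= height), else 1."""
        return 0 if self.width >= self.height else 1


@dataclass(frozen=True)
class ThicknessProfile:
    """Four cross-sectional thickness chords along the length axis (pixels)."""

    stations: tuple[float, float, float, float]
    chords: tuple[float, float, float, float]

    @property
    def max(self) -> float:
        return max(self.chords)

    @property
    def min(self) -> float:
        return min(self.chords)

    @property
    def mean(self) -> float:
        return sum(self.chords) / len(self.chords)


@dataclass(frozen=True)
class CircleFit:
    """Circle through three points; ``radius`` is ``inf`` for collinear input."""

    center: tuple[float, float] | None
    radius: float

    @property
    def curvature(self) -> float:
        return 0.0 if math.isinf(self.radius) else 1.0 / self.radius


@dataclass(frozen=True)
class SkeletonPath:
    """Main skeleton branch: ordered (x, y) pixel coordinates, 8-adjacent."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("skeleton path requires at least two points")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative Euclidean arc length at each path vertex."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def geodesic_length(self) -> float:
        return float(self.arc_lengths[-1])


def _require_nonempty(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got {m.ndim}-D")
    if not m.any():
        raise ValueError("operation requires a nonempty mask")
    return m


def extract_contour(mask: np.ndarray, simplify: bool = False) -> Contour:
    """Trace the outer boundary of the mask's foreground through pixel centers.

    Moore-neighbour border following over the 8-connected boundary; the
    starting pixel is the first foreground pixel in raster order and tracing
    stops by Jacob's criterion.  With ``simplify=True`` vertices collinear
    with their neighbours are removed (a filled rectangle reduces to its
    four corners).  A single-pixel mask yields a one-vertex contour.
    """
    m = _require_nonempty(mask)
    rows, cols = np.nonzero(m)
    start = (int(rows[0]), int(cols[0]))
    h, w = m.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and m[r, c]

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return Contour(np.array([[start[1], start[0]]], dtype=float))

    trace: list[tuple[int, int]] = [start]
    backtrack = (start[0], start[1] - 1)  # West of start is background by raster order
    first_backtrack = backtrack
    current = start
    max_steps = 4 * (len(rows) + 4)
    for _ in range(max_steps):
        # scan clockwise starting just after the backtrack neighbour
        br, bc = backtrack[0] - current[0], backtrack[1] - current[1]
        i0 = _MOORE.index((br, bc))
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(i0 + k) % 8]
            cand = (current[0] + dr, current[1] + dc)
            if fg(*cand):
                nxt = cand
                prev_dr, prev_dc = _MOORE[(i0 + k - 1) % 8]
                backtrack = (current[0] + prev_dr, current[1] + prev_dc)
                break
        assert nxt is not None
        if nxt == start and backtrack == first_backtrack:
            break
        trace.append(nxt)
        current = nxt
    pts = np.array([[c, r] for r, c in trace], dtype=float)
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    if simplify and len(pts) > 2:
        pts = _simplify_collinear(pts)
    return Contour(pts)


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _simplify_collinear(pts: np.ndarray) -> np.ndarray:
    keep = []
    n = len(pts)
    for i in range(n):
        a, b, c = pts[i - 1], pts[i], pts[(i + 1) % n]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) > 1e-12:
            keep.append(i)
    return pts[keep] if keep else pts[:1]


def contour_area_perimeter(contour: Contour) -> tuple[float, float]:
    """Shoelace area (px²) and closed-polygon perimeter (px) of a contour."""
    pts = contour.points
    if len(pts) < 2:
        return 0.0, 0.0
    area = abs(_signed_area(pts))
    closed = np.vstack([pts, pts[:1]])
    perimeter = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    return area, perimeter


def measure_region(mask: np.ndarray, tolerance: float = 1.2) -> tuple[float, float]:
    """Region area (px²) and boundary arc length (px) of the foreground.

    Unlike :func:`contour_area_perimeter`, which measures the raw
    pixel-center polygon, this measures the *region*: area is the foreground
    pixel count (unbiased for rasterized shapes) and the perimeter is the
    edge sum of the traced contour after Douglas–Peucker simplification,
    which compensates the staircase over-estimate of 8-connected border
    following on smooth curved boundaries (``tolerance`` in px), plus the
    half-pixel offset term 2π·(1/2): the pixel-center polygon runs half a
    pixel inside the region boundary, and offsetting a simple closed curve
    outward by r lengthens it by 2πr.
    """
    from skimage.measure import approximate_polygon

    m = _require_nonempty(mask)
    area = float(m.sum())
    contour = extract_contour(m)
    pts = contour.points
    if len(pts) < 3:
        return area, 0.0
    closed = np.vstack([pts, pts[:1]])
    approx = approximate_polygon(closed, tolerance=tolerance)
    perimeter = float(np.sum(np.linalg.norm(np.diff(approx, axis=0), axis=1))) + math.pi
    return area, perimeter


def bounding_rect(mask: np.ndarray) -> BoundingBox:
    """Axis-aligned bounding box of the foreground (inclusive pixel counts)."""
    m = _require_nonempty(mask)
    rows, cols = np.nonzero(m)
    return BoundingBox(
        x_min=int(cols.min()),
        y_min=int(rows.min()),
        width=int(cols.max() - cols.min() + 1),
        height=int(rows.max() - rows.min() + 1),
    )


def _axis_views(mask: np.ndarray, box: BoundingBox) -> tuple[np.ndarray, int, int]:
    """Return the mask with the length axis as columns, plus (u_min, u_max)."""
    m = np.asarray(mask, dtype=bool)
    if box.length_axis == 0:
        return m, box.x_min, box.x_min + box.width - 1
    return m.T, box.y_min, box.y_min + box.height - 1


def _column_center(mT: np.ndarray, u: int) -> float:
    vs = np.nonzero(mT[:, u])[0]
    if len(vs) == 0:
        raise ValueError(f"degenerate mask: no foreground pixels at length-axis position {u}")
    return float(vs.min() + vs.max()) / 2.0


def _local_tangent(mT: np.ndarray, u: int, u_min: int, u_max: int, window: int) -> float:
    """Slope dv/du of the mid-edge line near column u (least squares).

    Columns whose foreground extent is much smaller than the station
    column's are excluded: near a blunt object end such columns cross the
    end face instead of the two long edges and their midpoints would bias
    the fit.
    """
    ref_col = np.nonzero(mT[:, u])[0]
    ref_extent = float(ref_col.max() - ref_col.min()) if len(ref_col) else 0.0
    # window on the interior side of the station only: columns toward the
    # object ends may cross the end face and corrupt the fit
    mid = (u_min + u_max) / 2.0
    if u <= mid:
        lo, hi = u, min(u_max, u + 2 * window)
    else:
        lo, hi = max(u_min, u - 2 * window), u
    us, vs = [], []
    for uu in range(lo, hi + 1):
        col = np.nonzero(mT[:, uu])[0]
        if len(col) == 0:
            continue
        if ref_extent > 0 and (col.max() - col.min()) < 0.85 * ref_extent:
            continue
        us.append(uu)
        vs.append(float(col.min() + col.max()) / 2.0)
    if len(us) < 2:
        return 0.0
    A = np.vstack([np.asarray(us, float), np.ones(len(us))]).T
    coef, *_ = np.linalg.lstsq(A, np.asarray(vs, float), rcond=None)
    return float(coef[0])


def _chord_extent(
    m: np.ndarray, p: tuple[float, float], normal: tuple[float, float]
) -> tuple[float, float]:
    """Projections (s_min, s_max) of the contiguous run of foreground pixel
    centers along the line p + s*normal (pixel membership by nearest center).

    Marching stops at the first background pixel in each direction, so only
    the cross-section containing ``p`` is measured even when the line would
    re-enter another limb of a curved object.
    """
    h, w = m.shape
    nx, ny = normal
    px, py = p
    limit = float(math.hypot(h, w)) + 2.0

    def run(sign: float) -> float:
        best = None
        s = 0.0
        while s <= limit:
            x = px + sign * s * nx
            y = py + sign * s * ny
            c = int(math.floor(x + 0.5))
            r = int(math.floor(y + 0.5))
            if not (0 <= r < h and 0 <= c < w and m[r, c]):
                break
            # project the *pixel center* onto the normal axis
            proj = (c - px) * nx + (r - py) * ny
            if best is None or sign * proj > sign * best:
                best = proj
            s += 0.25
        if best is None:
            raise ValueError("cross-section anchor lies outside the mask")
        return best

    lo = run(-1.0)
    hi = run(+1.0)
    return min(lo, hi), max(lo, hi)


def thickness_profile(
    mask: np.ndarray,
    box: BoundingBox | None = None,
    method: str = "normal",
) -> ThicknessProfile:
    """Thickness chords at the four interior stations {1/5, 2/5, 3/5, 4/5}
    of the length axis.

    ``method="normal"`` (default) measures each chord perpendicular to the
    local mid-edge line, the physically meaningful thickness for curved
    objects; ``method="section"`` measures the raw extent of the foreground
    perpendicular coordinate within the station column (the bounding-box
    cross-section construction).  The two agree exactly for straight,
    axis-aligned objects.
    """
    m = _require_nonempty(mask)
    if box is None:
        box = bounding_rect(m)
    if method not in ("normal", "section"):
        raise ValueError(f"unknown thickness method {method!r}")
    mT, u_min, u_max = _axis_views(m, box)
    span = u_max - u_min
    window = max(3, round(0.04 * (span + 1)))
    chords = []
    for f in THICKNESS_STATIONS:
        u = u_min + round(f * span)
        vs = np.nonzero(mT[:, u])[0]
        if len(vs) == 0:
            raise ValueError(
                f"degenerate mask: station {f:.2f} (length-axis position {u}) is empty"
            )
        if method == "section":
            chords.append(float(vs.max() - vs.min()))
            continue
        v_c = float(vs.min() + vs.max()) / 2.0
        slope = _local_tangent(mT, u, u_min, u_max, window)
        norm = math.hypot(1.0, slope)
        normal = (-slope / norm, 1.0 / norm)
        s_min, s_max = _chord_extent(mT, (float(u), v_c), normal)
        chords.append(s_max - s_min)
    return ThicknessProfile(stations=THICKNESS_STATIONS, chords=tuple(chords))


def _skeleton_graph(coords: np.ndarray) -> sparse.csr_matrix:
    """8-adjacency graph over skeleton pixels, weights 1 and sqrt(2)."""
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    rows_i, cols_i, w = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr, dc in _MOORE:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None and j > i:
                rows_i.append(i)
                cols_i.append(j)
                w.append(math.sqrt(2.0) if dr and dc else 1.0)
    n = len(coords)
    g = sparse.coo_matrix((w, (rows_i, cols_i)), shape=(n, n))
    return (g + g.T).tocsr()


def skeleton_main_branch(mask: np.ndarray) -> SkeletonPath:
    """Thin the mask to a 1-px skeleton and keep the main branch.

    The skeleton comes from Zhang–Suen-style iterative thinning; the main
    branch is the maximum-geodesic-length path between two skeleton
    endpoints over the 8-adjacency graph (edge weights 1 and √2).  Geodesic
    ties are broken by the larger Euclidean endpoint separation, then by
    lexicographic (y, x) order of the endpoint pair.
    """
    m = _require_nonempty(mask)
    if m.sum() < 2:
        raise ValueError("skeleton of a single-pixel mask is a single point")
    skel = skeletonize(m, method="zhang")
    coords = np.argwhere(skel)  # (r, c)
    if len(coords) < 2:
        # thinning collapsed a tiny mask; fall back to the mask pixels when
        # the mask itself is already a thin 2-pixel object
        if m.sum() == 2:
            rc = np.argwhere(m)
            return SkeletonPath(rc[:, ::-1])
        raise ValueError("skeleton reduced to a single point")
    graph = _skeleton_graph(coords)
    degrees = np.asarray((graph > 0).sum(axis=1)).ravel()
    endpoints = np.nonzero(degrees == 1)[0]
    if len(endpoints) < 2:
        # a pure cycle or blob skeleton: use the two most distant pixels
        endpoints = np.arange(len(coords))
    dist, pred = dijkstra(graph, indices=endpoints, return_predecessors=True)
    best = None  # (geodesic, euclid, -lexkey) maximised
    best_pair = None
    for a_i, a in enumerate(endpoints):
        for b in endpoints:
            if b <= a:
                continue
            d = dist[a_i, b]
            if not np.isfinite(d):
                continue
            eu = float(np.linalg.norm(coords[a] - coords[b]))
            pa, pb = sorted([tuple(coords[a]), tuple(coords[b])])
            key = (d, eu, tuple(-x for x in pa + pb))
            if best is None or key > best:
                best = key
                best_pair = (a_i, b)
    if best_pair is None:
        raise ValueError("skeleton is disconnected; apply largest_component first")
    a_i, b = best_pair
    path_idx = [b]
    while path_idx[-1] != endpoints[a_i]:
        p = pred[a_i, path_idx[-1]]
        if p < 0:
            raise RuntimeError("path reconstruction failed")
        path_idx.append(int(p))
    path_idx.reverse()
    pts_rc = coords[path_idx]
    return SkeletonPath(pts_rc[:, ::-1])  # to (x, y)


def circumcircle(
    p1: Sequence[float], p2: Sequence[float], p3: Sequence[float]
) -> CircleFit:
    """Circle through three points via perpendicular-bisector intersection.

    Collinear points (triangle area below 1e-9) yield the infinite-radius
    flag (curvature 0); coincident points are rejected.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    c = np.asarray(p3, dtype=float)
    for u, v in ((a, b), (b, c), (a, c)):
        if np.allclose(u, v, atol=0.0):
            raise ValueError("circumcircle requires three distinct points")
    area2 = abs(
        (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    )  # twice the triangle area
    if area2 / 2.0 < 1e-9:
        return CircleFit(center=None, radius=math.inf)
    # perpendicular bisectors of (a, b) and (b, c)
    mid_ab = (a + b) / 2.0
    mid_bc = (b + c) / 2.0
    d_ab = b - a
    d_bc = c - b
    # solve [d_ab; d_bc] @ center = [d_ab . mid_ab; d_bc . mid_bc]
    A = np.vstack([d_ab, d_bc])
    rhs = np.array([d_ab @ mid_ab, d_bc @ mid_bc])
    center = np.linalg.solve(A, rhs)
    radius = float(np.linalg.norm(center - a))
    return CircleFit(center=(float(center[0]), float(center[1])), radius=radius)


def _refine_to_midline(
    m: np.ndarray, path: np.ndarray, idx: int, half_window: int
) -> tuple[tuple[float, float], float]:
    """Snap a path vertex to the midpoint of its perpendicular cross-section.

    The local tangent is estimated from the path over +/- ``half_window``
    vertices; the refined point is the midpoint of the contiguous foreground
    chord along the normal through the vertex.  Returns the refined point
    and the chord length (0 when the cross-section is degenerate).  This
    removes the half-pixel quantisation of the raster skeleton.
    """
    p = (float(path[idx][0]), float(path[idx][1]))
    lo = max(0, idx - half_window)
    hi = min(len(path) - 1, idx + half_window)
    t = path[hi].astype(float) - path[lo].astype(float)
    n_t = np.linalg.norm(t)
    if n_t == 0:
        return p, 0.0
    t /= n_t
    normal = (-t[1], t[0])
    try:
        s_min, s_max = _chord_extent(m, p, normal)
    except ValueError:
        return p, 0.0
    s_mid = (s_min + s_max) / 2.0
    return (p[0] + s_mid * normal[0], p[1] + s_mid * normal[1]), s_max - s_min


def _trim_spur_ends(m: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Drop path vertices at either end that run through thinning spurs.

    Thinning a blunt-ended band grows diagonal branches toward the end
    corners; along such a spur the distance-transform value drops from the
    local half-width toward 1 px, whereas medial vertices stay near the
    half-width.  The trimmed path is the longest contiguous run of vertices
    whose distance-transform value stays within ~1.5 px of the path's peak,
    never removing more than a third of the path per side.  Short paths are
    left untouched.
    """
    if len(pts) < 12:
        return pts
    from scipy import ndimage

    edt = ndimage.distance_transform_edt(m)
    vals = edt[pts[:, 1], pts[:, 0]]
    vmax = float(np.percentile(vals, 98))
    cut = vmax - max(1.5, 0.03 * vmax)
    good = vals >= cut
    best_lo, best_hi = 0, -1
    run_start = None
    for i, g in enumerate(good):
        if g and run_start is None:
            run_start = i
        if run_start is not None and (not g or i == len(good) - 1):
            run_end = i if g else i - 1
            if run_end - run_start > best_hi - best_lo:
                best_lo, best_hi = run_start, run_end
            run_start = None
    limit = len(pts) // 3  # never trim away more than a third per side
    lo = min(best_lo, limit)
    hi = max(best_hi, len(pts) - 1 - limit)
    return pts[lo : hi + 1]


def _anchor_point(m: np.ndarray, pts: np.ndarray, idx: int, w: int) -> tuple[float, float]:
    """Subpixel anchor: mean of refined cross-section midpoints near idx.

    Averaging over a window of path vertices suppresses the half-pixel
    raster noise of individual cross-sections.  Sections whose chord is
    noticeably shorter than the window's typical chord are excluded: near a
    blunt end the perpendicular chord clips the end face, which would bias
    the midpoint inward.  The small radially-inward bias of arc averaging is
    common to all anchors and cancels in the circumradius to first order.
    """
    lo = max(0, idx - w)
    hi = min(len(pts) - 1, idx + w)
    sections = []
    for j in range(lo, hi + 1):
        point, chord = _refine_to_midline(m, pts, j, max(3, w // 2))
        sections.append((point, chord))
    chords = np.array([c for _, c in sections])
    ref = float(np.percentile(chords, 90))
    keep = [p for p, c in sections if c >= 0.975 * ref]
    if len(keep) < 3:
        keep = [p for p, _ in sections]
    arrs = np.asarray(keep, dtype=float)
    return float(arrs[:, 0].mean()), float(arrs[:, 1].mean())


def curvature_of_mask(mask: np.ndarray, refine: bool = True) -> float:
    """Curvature (px⁻¹) of the mask's main skeleton branch.

    The circle is fitted through the two endpoints and the geodesic midpoint
    of the main branch; curvature is the inverse circumradius (0 for
    collinear points).  With ``refine=True`` (default) the branch is first
    trimmed of end spurs left by thinning and each of the three points is
    estimated subpixel as the windowed mean of perpendicular cross-section
    midpoints, which suppresses raster quantisation.
    """
    m = _require_nonempty(mask)
    path = skeleton_main_branch(m)
    pts = path.points
    if refine:
        pts = _trim_spur_ends(m, pts)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    mid_idx = int(np.searchsorted(arc, arc[-1] / 2.0))
    mid_idx = min(max(mid_idx, 1), len(pts) - 2)
    if refine:
        w = max(3, min(25, len(pts) // 4))
        inset = max(1, w // 2)
        # end anchors are inset by half a window so most cross-sections in
        # their windows lie in clean medial territory
        p1 = _anchor_point(m, pts, min(inset, len(pts) - 1), w)
        p2 = _anchor_point(m, pts, mid_idx, w)
        p3 = _anchor_point(m, pts, max(len(pts) - 1 - inset, 0), w)
    else:
        p1 = tuple(pts[0].astype(float))
        p2 = tuple(pts[mid_idx].astype(float))
        p3 = tuple(pts[-1].astype(float))
    try:
        fit = circumcircle(p1, p2, p3)
    except ValueError:
        return 0.0  # degenerate: refined points coincide -> straight
    return fit.curvature
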