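"""Cell-layer decomposition and per-segment intensity measurement.

The ribbon between the outer and inner boundary curves is tiled with
quadrilateral segments roughly perpendicular to the layer: the outer curve is
split at equal arc-length intervals starting from the aboral anchor, each
split point is matched to its nearest point on the inner curve, large gaps on
the inner curve are subdivided and matched back, and the boundary positions
are smoothed with a circular moving average so segments end up uniformly
spaced.  Per segment, the mean red/green/blue intensity of all enclosed
pixels gives one sample of the 1D expression profile along the layer.

Pixel membership uses the even-odd rule with pixel centers at
(col + 0.5, row + 0.5); segments are clipped at image borders.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import DecompositionError
from .geometry import Curve, EmbryoGeometry, Point2D, _segments_intersect, build_spline_curve

__all__ = [
    "RGBImage",
    "Segment",
    "SegmentDecomposition",
    "ExpressionProfile",
    "nearest_point_on_curve",
    "decompose_cell_layer",
    "measure_segments",
    "points_in_polygon",
]


@dataclass
class RGBImage:
    """An H x W x 3 raster, channel values in [0, 255] (8-bit convention).

    ``pixels`` may be integer or float; floats are accepted so synthetic
    expression fields can be measured without quantization loss.
    ``inverted`` records whether dark-stain inversion has been applied.
    """

    pixels: np.ndarray
    inverted: bool = False

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3 (or H x W greyscale)")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("empty image")
        self.pixels = arr

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class Segment:
    """One quadrilateral tile of the cell-layer ribbon.

    ``quad`` lists the corners (outer_i, outer_i+1, inner_i+1, inner_i);
    ``arc_position`` is the distance of the segment center along the
    mid-curve, measured from the aboral anchor.
    """

    quad: Tuple[Point2D, Point2D, Point2D, Point2D]
    center: Point2D
    arc_position: float

    @property
    def quad_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.quad], dtype=float)


@dataclass
class SegmentDecomposition:
    segments: List[Segment]
    total_arclength: float
    boundary_indices: Optional[Tuple[int, int]] = None
    boundary_arc_positions: Optional[Tuple[float, float]] = None

    def __len__(self):
        return len(self.segments)

    @property
    def arc_positions(self) -> np.ndarray:
        return np.array([s.arc_position for s in self.segments])


@dataclass
class ExpressionProfile:
    """Per-segment mean intensities versus arc position along the cell layer.

    Intensities are in [0, 1] expression units (inverted so higher means
    more stain, unless measured with ``invert=False``).
    """

    positions: np.ndarray
    mean_r: np.ndarray
    mean_g: np.ndarray
    mean_b: np.ndarray
    mean_grey: np.ndarray
    total_length: float
    boundary_positions: Optional[Tuple[float, float]] = None
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        for ch in ("mean_r", "mean_g", "mean_b", "mean_grey"):
            v = np.asarray(getattr(self, ch), dtype=float)
            if v.shape != self.positions.shape:
                raise ValueError("channel/position length mismatch")
            setattr(self, ch, v)

    def __len__(self):
        return len(self.positions)

    def channel(self, name: str) -> np.ndarray:
        return {"r": self.mean_r, "g": self.mean_g, "b": self.mean_b, "grey": self.mean_grey}[name]

    def with_values(self, **channels) -> "ExpressionProfile":
        """Copy with some channel arrays replaced (positions untouched)."""
        kwargs = dict(
            positions=self.positions.copy(),
            mean_r=self.mean_r.copy(),
            mean_g=self.mean_g.copy(),
            mean_b=self.mean_b.copy(),
            mean_grey=self.mean_grey.copy(),
            total_length=self.total_length,
            boundary_positions=self.boundary_positions,
            warnings=list(self.warnings),
        )
        for name, values in channels.items():
            kwargs[f"mean_{name}"] = np.asarray(values, dtype=float)
        return ExpressionProfile(**kwargs)


def nearest_point_on_curve(p, curve: Curve):
    """Sampled curve point closest to ``p``; ties broken by lowest index.

    Returns ``(index, Point2D, distance)``.
    """
    q = p.as_array() if isinstance(p, Point2D) else np.asarray(p, dtype=float)
    d2 = np.sum((curve.points - q) ** 2, axis=1)
    idx = int(np.argmin(d2))  # argmin returns the lowest index on ties
    pt = curve.points[idx]
    return idx, Point2D(pt[0], pt[1]), float(np.sqrt(d2[idx]))


def _circular_moving_average(values: np.ndarray, span: int, period: float) -> np.ndarray:
    """Moving average of monotone, unwrapped arc positions on a closed loop.

    ``values`` must increase over one full loop; windows crossing the seam
    use the periodic extension ``values[k + n] = values[k] + period``.
    """
    if span % 2 == 0 or span < 1:
        raise ValueError("span must be a positive odd integer")
    n = len(values)
    half = span // 2
    out = np.empty(n)
    for i in range(n):
        idx = np.arange(i - half, i + half + 1)
        window = values[idx % n] + period * (idx // n)
        out[i] = window.mean()
    return out


def decompose_cell_layer(
    geometry: EmbryoGeometry,
    segment_length: float,
    smoothing_span: int = 3,
    gap_factor: float = 1.5,
    n_curve_points: int = 100_000,
    smoothing_passes: int = 1,
) -> SegmentDecomposition:
    """Tile the cell-layer ribbon with parallel quadrilateral segments.

    The outer curve is divided into ``n = round(perimeter / segment_length)``
    equal arcs starting at the aboral anchor (the rounding residual is spread
    evenly so the closed curve is tiled exactly).  Each outer boundary is
    matched to the nearest inner-curve point; inner arcs between consecutive
    matches longer than ``gap_factor * segment_length`` are subdivided and
    matched back to the outer curve.  One (configurable) pass of a circular
    moving average then evens out the boundary spacing on both curves.

    Raises
    ------
    DecompositionError
        If matching produces crossing or non-monotone segment edges.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    outer = build_spline_curve(geometry.outer_array, n_points=n_curve_points, closed=True)
    inner = build_spline_curve(geometry.inner_array, n_points=n_curve_points, closed=True)
    L_out, L_in = outer.total_length, inner.total_length
    if segment_length >= L_out / 2:
        raise ValueError("segment_length must be smaller than half the outer perimeter")

    s0 = geometry.aboral_anchor * L_out
    n = int(round(L_out / segment_length))
    outer_s = s0 + np.arange(n) * (L_out / n)  # residual spread evenly

    # Match each outer boundary to the nearest inner-curve sample.
    outer_pts = outer.point_at(outer_s)
    _, idx_in = inner.kdtree.query(outer_pts)
    inner_s = inner.cumulative_arclength[idx_in]

    # Unwrap inner positions so they increase from the first match.
    inner_s = np.mod(inner_s - inner_s[0], L_in) + inner_s[0]

    # Subdivide large inner gaps and match the new points back to the outer curve.
    pairs = []  # (outer_s, inner_s)
    for k in range(n):
        pairs.append((outer_s[k], inner_s[k]))
        nxt_in = inner_s[(k + 1) % n] + (L_in if k + 1 == n else 0.0)
        gap = nxt_in - inner_s[k]
        if gap > gap_factor * segment_length:
            m = int(round(gap / segment_length))
            for j in range(1, m):
                s_new_in = inner_s[k] + gap * j / m
                p_new = inner.point_at(s_new_in)
                _, idx_out = outer.kdtree.query(p_new)
                s_new_out = outer.cumulative_arclength[idx_out]
                pairs.append((s_new_out, s_new_in))

    po = np.array([p[0] for p in pairs])
    pi = np.array([p[1] for p in pairs])
    # Unwrap both sequences to be monotone from the anchor.
    po = np.mod(po - s0, L_out) + s0
    order = np.argsort(po, kind="stable")
    po, pi = po[order], pi[order]
    pi = np.mod(pi - pi[0], L_in) + pi[0]
    if np.any(np.diff(pi) < 0):
        bad = int(np.argmin(np.diff(pi)))
        raise DecompositionError(f"inner boundary ordering reverses at segment {bad}")

    # Smooth boundary arc positions (circular moving average on each curve),
    # keeping the index pairing between outer and inner boundaries.
    for _ in range(max(0, smoothing_passes)):
        po = _circular_moving_average(po, smoothing_span, L_out)
        pi = _circular_moving_average(pi, smoothing_span, L_in)
    if np.any(np.diff(po) <= 0) or np.any(np.diff(pi) <= 0):
        bad = int(np.argmin(np.diff(po)))
        raise DecompositionError(f"boundary ordering lost after smoothing near segment {bad}")

    outer_b = outer.point_at(po)
    inner_b = inner.point_at(pi)
    m = len(po)

    # Crossing check on the radial edges of consecutive segments.
    for k in range(m):
        k2 = (k + 1) % m
        if _segments_intersect(outer_b[k], inner_b[k], outer_b[k2], inner_b[k2]):
            raise DecompositionError(f"segment edges cross at index {k}")

    # Mid-curve through the matched boundary pairs; arc positions along it.
    mid = 0.5 * (outer_b + inner_b)
    mid_seg = np.linalg.norm(np.diff(np.vstack([mid, mid[:1]]), axis=0), axis=1)
    mid_cum = np.concatenate([[0.0], np.cumsum(mid_seg)])  # length m+1
    total = float(mid_cum[-1])

    segments = []
    for k in range(m):
        k2 = (k + 1) % m
        quad = (
            Point2D(*outer_b[k]),
            Point2D(*outer_b[k2]),
            Point2D(*inner_b[k2]),
            Point2D(*inner_b[k]),
        )
        center = 0.5 * (mid[k] + mid[k2])
        arc = 0.5 * (mid_cum[k] + mid_cum[k + 1])
        segments.append(Segment(quad=quad, center=Point2D(*center), arc_position=float(arc)))

    boundary_indices = None
    boundary_arcs = None
    if geometry.boundary_markers is not None:
        arcs = np.array([s.arc_position for s in segments])
        f1, f2 = sorted(geometry.boundary_markers)
        b1, b2 = f1 * total, f2 * total
        boundary_arcs = (float(b1), float(b2))
        boundary_indices = (
            int(np.argmin(np.abs(arcs - b1))),
            int(np.argmin(np.abs(arcs - b2))),
        )

    return SegmentDecomposition(
        segments=segments,
        total_arclength=total,
        boundary_indices=boundary_indices,
        boundary_arc_positions=boundary_arcs,
    )


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) containment test, vectorized over points.

    A point on an edge counts as inside or outside according to the strict
    ``x < x_intersection`` comparison; the same predicate is applied
    everywhere so adjacent polygons sharing an edge claim boundary points
    consistently.
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    px, py = poly[:, 0], poly[:, 1]
    px2, py2 = np.roll(px, -1), np.roll(py, -1)
    for x1, y1, x2, y2 in zip(px, py, px2, py2):
        cond = (y1 > y) != (y2 > y)
        if not np.any(cond):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < xi)
    return inside


def measure_segments(
    image: RGBImage,
    decomposition: SegmentDecomposition,
    invert: bool = True,
    grey_weights: Optional[Sequence[float]] = None,
) -> ExpressionProfile:
    """Average the color intensities of the pixels enclosed in each segment.

    Pixel centers sit at (col + 0.5, row + 0.5); membership is the even-odd
    rule.  With ``invert`` (the default, for dark stain on light background)
    expression = (255 - value) / 255, otherwise value / 255.  The greyscale
    channel is the unweighted mean of the three channel means unless
    ``grey_weights`` (e.g. luma coefficients) is given.

    Segments that catch no pixel center get their means by linear
    interpolation from neighbouring segments and are listed in the returned
    profile's ``warnings``.
    """
    H, W = image.shape
    pix = np.asarray(image.pixels, dtype=float)
    warnings_list: List[str] = []

    n_seg = len(decomposition.segments)
    means = np.full((n_seg, 3), np.nan)
    clipped = False
    for k, seg in enumerate(decomposition.segments):
        quad = seg.quad_array
        xmin, ymin = quad.min(axis=0)
        xmax, ymax = quad.max(axis=0)
        if xmin < 0 or ymin < 0 or xmax > W or ymax > H:
            clipped = True
        c0 = max(int(np.floor(xmin - 0.5)), 0)
        c1 = min(int(np.ceil(xmax - 0.5)) + 1, W)
        r0 = max(int(np.floor(ymin - 0.5)), 0)
        r1 = min(int(np.ceil(ymax - 0.5)) + 1, H)
        if c0 >= c1 or r0 >= r1:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        centers = np.stack([cols.ravel() + 0.5, rows.ravel() + 0.5], axis=1)
        mask = points_in_polygon(centers, quad)
        if not np.any(mask):
            continue
        rr = rows.ravel()[mask]
        cc = cols.ravel()[mask]
        means[k] = pix[rr, cc].mean(axis=0)
    if clipped:
        msg = "decomposition extends beyond image bounds; segments clipped"
        warnings_list.append(msg)
        _warnings.warn(msg, stacklevel=2)

    # Fill empty segments by circular linear interpolation from neighbours.
    empty = np.isnan(means[:, 0])
    if np.all(empty):
        raise DecompositionError("no segment encloses any pixel center")
    if np.any(empty):
        good = ~empty
        idx = np.arange(n_seg)
        for ch in range(3):
            means[empty, ch] = np.interp(
                idx[empty], idx[good], means[good, ch], period=n_seg
            )
        for k in idx[empty]:
            warnings_list.append(f"segment {k} enclosed no pixel centers; interpolated")

    if invert:
        expr = (255.0 - means) / 255.0
    else:
        expr = means / 255.0
    if grey_weights is None:
        grey = expr.mean(axis=1)
    else:
        w = np.asarray(grey_weights, dtype=float)
        grey = expr @ (w / w.sum())

    return ExpressionProfile(
        positions=decomposition.arc_positions,
        mean_r=expr[:, 0],
        mean_g=expr[:, 1],
        mean_b=expr[:, 2],
        mean_grey=grey,
        total_length=decomposition.total_arclength,
        boundary_positions=decomposition.boundary_arc_positions,
        warnings=warnings_list,
    )
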