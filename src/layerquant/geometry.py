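"""Digital embryo geometries: paired closed spline curves for the cell layer.

An embryo cross-section is represented by two closed node rings, one on the
outer and one on the inner boundary of the body-wall cell layer.  Nodes are
connected by periodic cubic splines sampled densely (1e5 points by default),
which turns a handful of manually placed nodes into a smooth digital outline.
Geometries from several embryos of the same age can be averaged node-wise,
averages of successive stages can be interpolated to any intermediate
developmental time, and a geometry can be registered onto a micrograph with a
least-squares similarity transform.

Coordinate convention: image indexed (row, col); a point's ``x`` is the column
direction and ``y`` the row direction, origin at the top-left, units pixels
throughout.  Ring orientation is normalized so that the shoelace signed area
in (x, y) is positive ("counterclockwise" in the stored coordinates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .errors import IncompatibleGeometryError, InvalidGeometryError, RegistrationError

__all__ = [
    "Point2D",
    "EmbryoGeometry",
    "Curve",
    "build_spline_curve",
    "average_geometries",
    "interpolate_stages",
    "register_to_image",
    "similarity_transform",
    "load_geometry",
    "save_geometry",
]


@dataclass(frozen=True)
class Point2D:
    """A point in image pixel coordinates (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise InvalidGeometryError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_point_array(points: Sequence) -> np.ndarray:
    arr = np.asarray(
        [[p.x, p.y] if isinstance(p, Point2D) else [p[0], p[1]] for p in points],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidGeometryError("points must be a sequence of (x, y) pairs")
    if not np.all(np.isfinite(arr)):
        raise InvalidGeometryError("non-finite coordinates in point list")
    return arr


def _signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y2 - x2 * y))


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1p2 and p3p4."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _ring_self_intersects(ring: np.ndarray) -> bool:
    n = len(ring)
    for i in range(n):
        a1, a2 = ring[i], ring[(i + 1) % n]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(a1, a2, ring[j], ring[(j + 1) % n]):
                return True
    return False


def _points_in_ring(pts: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Even-odd containment of points in a closed polygonal ring."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    rx, ry = ring[:, 0], ring[:, 1]
    rx2, ry2 = np.roll(rx, -1), np.roll(ry, -1)
    for x1, y1, x2, y2 in zip(rx, ry, rx2, ry2):
        cond = (y1 > y) != (y2 > y)
        if not np.any(cond):
            continue
        xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < xi)
    return inside


@dataclass
class EmbryoGeometry:
    """Two closed node rings plus landmarks describing one embryo cross-section.

    Parameters
    ----------
    outer_nodes, inner_nodes
        Ordered closed rings of :class:`Point2D` (at least 4 nodes each); the
        inner ring must lie strictly inside the outer one.  Orientation is
        normalized to positive shoelace area on construction.
    boundary_markers
        Optional pair of arc-length fractions in [0, 1) along the ribbon,
        measured from the aboral anchor, marking the two endoderm-ectoderm
        boundaries.  Absent for blastula-stage embryos, which have no endoderm.
    aboral_anchor
        Arc-length fraction (of the outer curve, from its first node) of the
        aboral pole, where the decomposition starts.
    stage_hpf
        Hours past fertilization, or a symbolic stage label such as ``"bl"``.
    """

    outer_nodes: list
    inner_nodes: list
    boundary_markers: Optional[tuple] = None
    aboral_anchor: float = 0.0
    stage_hpf: object = None
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        outer = _as_point_array(self.outer_nodes)
        inner = _as_point_array(self.inner_nodes)
        if len(outer) < 4 or len(inner) < 4:
            raise InvalidGeometryError("each ring needs at least 4 nodes")
        if _signed_area(outer) < 0:
            outer = outer[::-1].copy()
        if _signed_area(inner) < 0:
            inner = inner[::-1].copy()
        if _ring_self_intersects(outer) or _ring_self_intersects(inner):
            raise InvalidGeometryError("ring is self-intersecting")
        if not np.all(_points_in_ring(inner, outer)):
            raise InvalidGeometryError("inner ring is not strictly inside outer ring")
        if self.boundary_markers is not None:
            a, b = self.boundary_markers
            if not (0 <= a < 1 and 0 <= b < 1):
                raise InvalidGeometryError("boundary markers must lie in [0, 1)")
            if a == b:
                raise InvalidGeometryError("boundary markers must be distinct")
            self.boundary_markers = (float(a), float(b))
        self.outer_nodes = [Point2D(*p) for p in outer]
        self.inner_nodes = [Point2D(*p) for p in inner]
        self.aboral_anchor = float(self.aboral_anchor) % 1.0
        self._validated = True

    @property
    def outer_array(self) -> np.ndarray:
        return _as_point_array(self.outer_nodes)

    @property
    def inner_array(self) -> np.ndarray:
        return _as_point_array(self.inner_nodes)

    def with_nodes(self, outer: np.ndarray, inner: np.ndarray) -> "EmbryoGeometry":
        return EmbryoGeometry(
            outer_nodes=[Point2D(*p) for p in np.asarray(outer, float)],
            inner_nodes=[Point2D(*p) for p in np.asarray(inner, float)],
            boundary_markers=self.boundary_markers,
            aboral_anchor=self.aboral_anchor,
            stage_hpf=self.stage_hpf,
        )

    def replace_node(self, ring: str, index: int, point: Point2D) -> "EmbryoGeometry":
        """Override a single node (programmatic analogue of dragging it)."""
        outer, inner = self.outer_array, self.inner_array
        if ring == "outer":
            outer[index] = point.as_array()
        elif ring == "inner":
            inner[index] = point.as_array()
        else:
            raise ValueError("ring must be 'outer' or 'inner'")
        return self.with_nodes(outer, inner)


class Curve:
    """A cubic-spline curve through nodes, densely sampled.

    Attributes
    ----------
    points : (n, 2) array
        Samples uniform in chord-length parameter.  For closed curves the
        first point is the spline at the first node and the duplicate
        endpoint is omitted (the parameterization wraps).
    cumulative_arclength : (n,) array
        Polyline arc length from the first sample to each sample.
    closed : bool
    total_length : float
        Full perimeter for closed curves (including the closing edge).
    """

    def __init__(self, points: np.ndarray, closed: bool, spline=None, node_params=None):
        self.points = np.asarray(points, dtype=float)
        self.closed = bool(closed)
        self._spline = spline
        self.node_params = node_params
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.cumulative_arclength = np.concatenate([[0.0], np.cumsum(seg)])
        if closed:
            closing = float(np.linalg.norm(self.points[0] - self.points[-1]))
            self.total_length = float(self.cumulative_arclength[-1] + closing)
        else:
            self.total_length = float(self.cumulative_arclength[-1])
        self._tree = None

    def __len__(self):
        return len(self.points)

    @property
    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def point_at(self, s):
        """Curve point(s) at arc length ``s`` (wraps for closed curves)."""
        s = np.asarray(s, dtype=float)
        if self.closed:
            s = np.mod(s, self.total_length)
            cum = np.concatenate([self.cumulative_arclength, [self.total_length]])
            xs = np.concatenate([self.points[:, 0], [self.points[0, 0]]])
            ys = np.concatenate([self.points[:, 1], [self.points[0, 1]]])
        else:
            s = np.clip(s, 0.0, self.total_length)
            cum, xs, ys = self.cumulative_arclength, self.points[:, 0], self.points[:, 1]
        return np.stack([np.interp(s, cum, xs), np.interp(s, cum, ys)], axis=-1)

    def arclength_at_index(self, i) -> np.ndarray:
        return self.cumulative_arclength[i]

    def evaluate_parameter(self, t):
        """Evaluate the underlying spline directly at parameter values ``t``."""
        if self._spline is None:
            raise ValueError("curve has no attached spline")
        return self._spline(t)


def build_spline_curve(nodes: Sequence, n_points: int = 100_000, closed: bool = True) -> Curve:
    """Connect nodes with a cubic spline sampled at ``n_points`` points.

    Chord-length parameterization; periodic end conditions for closed rings,
    natural end conditions for open curves.  The curve passes through every
    node.

    Raises
    ------
    InvalidGeometryError
        Fewer than 4 nodes, or two consecutive nodes coincide.
    """
    pts = _as_point_array(nodes)
    if len(pts) < 4:
        raise InvalidGeometryError("need at least 4 nodes for a cubic spline curve")
    if closed:
        knots = np.vstack([pts, pts[:1]])
    else:
        knots = pts
    chord = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    if np.any(chord == 0):
        raise InvalidGeometryError("duplicate consecutive nodes")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    bc = "periodic" if closed else "natural"
    spline = CubicSpline(t, knots, axis=0, bc_type=bc)
    if closed:
        # omit the duplicated endpoint so the parameterization wraps
        ts = np.linspace(0.0, t[-1], n_points, endpoint=False)
        node_params = t[:-1]
    else:
        ts = np.linspace(0.0, t[-1], n_points)
        node_params = t
    return Curve(spline(ts), closed=closed, spline=spline, node_params=node_params)


def _check_compatible(geoms: Sequence[EmbryoGeometry]):
    n_out = len(geoms[0].outer_nodes)
    n_in = len(geoms[0].inner_nodes)
    has_markers = geoms[0].boundary_markers is not None
    for g in geoms[1:]:
        if len(g.outer_nodes) != n_out or len(g.inner_nodes) != n_in:
            raise IncompatibleGeometryError("geometries have different node counts")
        if (g.boundary_markers is not None) != has_markers:
            raise IncompatibleGeometryError("boundary marker presence differs")


def average_geometries(geometries: Sequence[EmbryoGeometry]) -> EmbryoGeometry:
    """Node-wise arithmetic mean of 2-5 (or more) corresponding geometries.

    Node correspondence across embryos is assumed to be established manually
    (same number of strategically placed nodes per ring); markers and the
    anchor are averaged as arc fractions, the stage as a number when numeric.
    """
    geometries = list(geometries)
    if not geometries:
        raise IncompatibleGeometryError("no geometries to average")
    _check_compatible(geometries)
    outer = np.mean([g.outer_array for g in geometries], axis=0)
    inner = np.mean([g.inner_array for g in geometries], axis=0)
    markers = None
    if geometries[0].boundary_markers is not None:
        markers = tuple(np.mean([g.boundary_markers for g in geometries], axis=0))
    anchor = float(np.mean([g.aboral_anchor for g in geometries]))
    stages = [g.stage_hpf for g in geometries]
    try:
        stage = float(np.mean([float(s) for s in stages]))
    except (TypeError, ValueError):
        stage = stages[0]
    return EmbryoGeometry(
        outer_nodes=[Point2D(*p) for p in outer],
        inner_nodes=[Point2D(*p) for p in inner],
        boundary_markers=markers,
        aboral_anchor=anchor,
        stage_hpf=stage,
    )


def interpolate_stages(geom_a: EmbryoGeometry, geom_b: EmbryoGeometry, t: float) -> EmbryoGeometry:
    """Linear interpolation between two stage geometries, ``t`` in [0, 1]."""
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"interpolation fraction t={t} outside [0, 1]")
    _check_compatible([geom_a, geom_b])
    outer = (1 - t) * geom_a.outer_array + t * geom_b.outer_array
    inner = (1 - t) * geom_a.inner_array + t * geom_b.inner_array
    markers = None
    if geom_a.boundary_markers is not None:
        ma, mb = np.asarray(geom_a.boundary_markers), np.asarray(geom_b.boundary_markers)
        markers = tuple((1 - t) * ma + t * mb)
    anchor = (1 - t) * geom_a.aboral_anchor + t * geom_b.aboral_anchor
    try:
        stage = (1 - t) * float(geom_a.stage_hpf) + t * float(geom_b.stage_hpf)
    except (TypeError, ValueError):
        stage = geom_a.stage_hpf if t < 0.5 else geom_b.stage_hpf
    return EmbryoGeometry(
        outer_nodes=[Point2D(*p) for p in outer],
        inner_nodes=[Point2D(*p) for p in inner],
        boundary_markers=markers,
        aboral_anchor=anchor,
        stage_hpf=stage,
    )


def similarity_transform(source: np.ndarray, target: np.ndarray):
    """Least-squares similarity (uniform scale + rotation + translation).

    Returns ``(scale, rotation_matrix, translation)`` minimizing
    ``sum || s R x + t - y ||^2`` (Umeyama closed form, reflection excluded).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise RegistrationError("source and target must be equal-length (n, 2) arrays")
    if len(src) < 2:
        raise RegistrationError("at least 2 point pairs required")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    xs, ys = src - mu_s, tgt - mu_t
    var_s = float(np.sum(xs**2)) / len(src)
    if var_s == 0:
        raise RegistrationError("source points are coincident")
    cov = ys.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S)) / var_s
    t = mu_t - scale * R @ mu_s
    return scale, R, t


def register_to_image(
    geometry: EmbryoGeometry,
    source_points: Sequence,
    target_points: Sequence,
) -> EmbryoGeometry:
    """Map a library geometry onto a micrograph via corresponding landmarks.

    The best-fit similarity transform from ``source_points`` to
    ``target_points`` is applied to all nodes.  Individual nodes can
    afterwards be adjusted with :meth:`EmbryoGeometry.replace_node`.
    """
    src = _as_point_array(source_points)
    tgt = _as_point_array(target_points)
    scale, R, t = similarity_transform(src, tgt)
    outer = (scale * (R @ geometry.outer_array.T)).T + t
    inner = (scale * (R @ geometry.inner_array.T)).T + t
    return geometry.with_nodes(outer, inner)


# ---------------------------------------------------------------------------
# JSON persistence

def save_geometry(geometry: EmbryoGeometry, path):
    data = {
        "outer_nodes": [[p.x, p.y] for p in geometry.outer_nodes],
        "inner_nodes": [[p.x, p.y] for p in geometry.inner_nodes],
        "boundary_markers": list(geometry.boundary_markers)
        if geometry.boundary_markers is not None
        else None,
        "aboral_anchor": geometry.aboral_anchor,
        "stage_hpf": geometry.stage_hpf,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def load_geometry(path) -> EmbryoGeometry:
    with open(path) as fh:
        data = json.load(fh)
    markers = data.get("boundary_markers")
    return EmbryoGeometry(
        outer_nodes=[Point2D(*p) for p in data["outer_nodes"]],
        inner_nodes=[Point2D(*p) for p in data["inner_nodes"]],
        boundary_markers=tuple(markers) if markers else None,
        aboral_anchor=data.get("aboral_anchor", 0.0),
        stage_hpf=data.get("stage_hpf"),
    )
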