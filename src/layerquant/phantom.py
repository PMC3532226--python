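"""Synthetic phantom embryos with analytically known ground truth.

Real in situ hybridization micrographs come with no ground truth, so every
quantitative claim about the pipeline is validated on phantoms: two-layer
embryo cross-sections (concentric rings for the blastula, rings with an oral
invagination dimple for gastrula stages) with an expression function g(s)
painted along the cell layer, a light background with optional one-sided
lighting gradient, dark annotation-like glyphs, and seeded Gaussian noise.
Phantom view pairs and volumes play the same role for the 3D reconstruction:
views are maximum-expression projections of a known volume (the darkest
pixel along the ray, under the dark-stain convention).

All phantom outputs are deterministic given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .decomposition import RGBImage, points_in_polygon
from .errors import InvalidGeometryError
from .geometry import EmbryoGeometry, Point2D, build_spline_curve
from .volume3d import ExpressionVolume, ViewImage

__all__ = [
    "PhantomTruth",
    "make_phantom_geometry",
    "render_profile_image",
    "render_view_pair",
    "gaussian_bump",
    "make_box_volume",
    "make_blob_volume",
]


@dataclass
class PhantomTruth:
    """Everything needed to score a phantom run against its ground truth."""

    geometry: EmbryoGeometry
    truth_positions: np.ndarray  # 1000 arc positions along the mid-curve
    truth_values: np.ndarray  # g sampled at those positions
    total_length: float
    background_level: float
    noise_sd: float
    seed: Optional[int]
    description: str = ""
    volume: Optional[ExpressionVolume] = None

    def truth_at(self, positions) -> np.ndarray:
        """g interpolated at arbitrary arc positions (circular)."""
        s = np.mod(np.asarray(positions, dtype=float), self.total_length)
        xp = np.concatenate([self.truth_positions, [self.total_length]])
        fp = np.concatenate([self.truth_values, [self.truth_values[0]]])
        return np.interp(s, xp, fp)


def gaussian_bump(center_frac: float, width_frac: float, amplitude: float = 1.0) -> Callable:
    """g(s/L): a circular Gaussian bump at a fractional arc position."""

    def g(frac):
        frac = np.asarray(frac, dtype=float)
        d = np.abs(frac - center_frac)
        d = np.minimum(d, 1.0 - d)
        return amplitude * np.exp(-0.5 * (d / width_frac) ** 2)

    return g


def make_phantom_geometry(
    stage: str = "blastula",
    outer_radius: float = 100.0,
    thickness: float = 20.0,
    invagination_depth: float = 0.0,
    n_nodes: int = 16,
    center: Tuple[float, float] = (0.0, 0.0),
) -> EmbryoGeometry:
    """Parametric two-ring embryo geometry with known shape.

    ``blastula``: two concentric circles, no endoderm markers.  Gastrula
    stages: the outer radius is locally reduced by a Gaussian dimple of the
    given depth at the oral pole (opposite the aboral anchor, which is node
    0); the dimple's half-width sets the endoderm-ectoderm boundary markers.
    """
    if thickness >= outer_radius:
        raise InvalidGeometryError("thickness must be smaller than outer_radius")
    if stage == "blastula" and invagination_depth != 0:
        raise InvalidGeometryError("blastula has no invagination")
    if invagination_depth < 0 or invagination_depth >= outer_radius - thickness:
        if invagination_depth != 0:
            raise InvalidGeometryError("invagination_depth out of range")
    if n_nodes < 4:
        raise InvalidGeometryError("need at least 4 nodes per ring")

    cx, cy = center
    # node 0 at the aboral pole (angle pi); oral pole at angle 0
    phis = np.pi + 2 * np.pi * np.arange(n_nodes) / n_nodes
    sigma = {"blastula": 0.0, "early_gastrula": 0.45, "late_gastrula": 0.7}.get(stage)
    if sigma is None:
        raise InvalidGeometryError(f"unknown stage {stage!r}")

    def dimple(phi):
        if invagination_depth == 0:
            return np.zeros_like(phi)
        d = np.angle(np.exp(1j * phi))  # signed angular distance from oral pole
        return invagination_depth * np.exp(-0.5 * (d / sigma) ** 2)

    r_out = outer_radius - dimple(phis)
    r_in = r_out - thickness
    if np.any(r_in <= 0):
        raise InvalidGeometryError("invagination collapses the inner ring")
    outer = np.stack([cx + r_out * np.cos(phis), cy + r_out * np.sin(phis)], axis=1)
    inner = np.stack([cx + r_in * np.cos(phis), cy + r_in * np.sin(phis)], axis=1)

    markers = None
    if stage != "blastula" and invagination_depth > 0:
        w = sigma / (2 * np.pi)  # dimple half-width as an arc fraction
        markers = ((0.5 - w) % 1.0, (0.5 + w) % 1.0)

    return EmbryoGeometry(
        outer_nodes=[Point2D(*p) for p in outer],
        inner_nodes=[Point2D(*p) for p in inner],
        boundary_markers=markers,
        aboral_anchor=0.0,
        stage_hpf={"blastula": "bl", "early_gastrula": 24.0, "late_gastrula": 48.0}[stage],
    )


def _ribbon_masks(geometry: EmbryoGeometry, width: int, height: int, n_poly: int = 2000):
    """Pixel-center masks of the outer disc and the inner hole."""
    outer = build_spline_curve(geometry.outer_array, n_points=n_poly, closed=True)
    inner = build_spline_curve(geometry.inner_array, n_points=n_poly, closed=True)
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    centers = np.stack([cols.ravel() + 0.5, rows.ravel() + 0.5], axis=1)
    in_outer = points_in_polygon(centers, outer.points).reshape(height, width)
    in_inner = points_in_polygon(centers, inner.points).reshape(height, width)
    return in_outer, in_inner, centers, outer, inner


def render_profile_image(
    geometry: EmbryoGeometry,
    expression_fn: Callable,
    width: int,
    height: int,
    background_level: float = 0.95,
    lighting_gradient: float = 0.0,
    annotations: Optional[List[dict]] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    stain_strength: float = 0.85,
    n_truth: int = 1000,
) -> Tuple[RGBImage, PhantomTruth]:
    """Paint an expression function onto a phantom embryo micrograph.

    ``expression_fn`` maps the fractional arc position s/L along the
    mid-curve (0 at the aboral anchor, increasing with the ring orientation)
    to a relative stain level in [0, 1].  Ribbon pixels are darkened
    proportionally; the background is light (``background_level`` of full
    white) with an optional horizontal ``lighting_gradient`` (fractional
    brightness change across the canvas).  ``annotations`` are dark glyph
    stand-ins (dicts with shape 'rect' or 'disc', position, size, and an
    optional 'value' grey level in [0, 1]).  Gaussian noise of standard
    deviation ``noise_sd`` (in [0, 1] units) is seeded and the result is
    quantized to 8 bits, so identical parameters give bit-identical images.
    """
    in_outer, in_inner, centers, outer, inner = _ribbon_masks(geometry, width, height)
    ribbon = in_outer & ~in_inner
    H, W = height, width

    # mid-curve samples with arc positions, for nearest-arc lookup
    n_mid = 4000
    so = np.linspace(0, outer.total_length, n_mid, endpoint=False)
    anchor_out = geometry.aboral_anchor * outer.total_length
    outer_pts = outer.point_at(anchor_out + so)
    _, inner_idx = inner.kdtree.query(outer_pts)
    mid_pts = 0.5 * (outer_pts + inner.points[inner_idx])
    # arc position along the mid polyline
    seg = np.linalg.norm(np.diff(np.vstack([mid_pts, mid_pts[:1]]), axis=0), axis=1)
    mid_cum = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    L_mid = float(mid_cum[-1] + seg[-1])
    tree = cKDTree(mid_pts)

    cols, rows = np.meshgrid(np.arange(W), np.arange(H))
    base = background_level + lighting_gradient * (cols / max(W - 1, 1) - 0.5)
    img = np.clip(base, 0.0, 1.0)

    g_px = np.zeros(H * W)
    rib = ribbon.ravel()
    if np.any(rib):
        _, idx = tree.query(centers[rib])
        g_px[rib] = np.clip(expression_fn(mid_cum[idx] / L_mid), 0.0, 1.0)
    img = img * (1.0 - stain_strength * g_px.reshape(H, W))

    rgb = np.repeat(img[:, :, None], 3, axis=2)
    for ann in annotations or []:
        val = float(ann.get("value", 0.1))
        if ann.get("shape", "rect") == "rect":
            r0, c0 = int(ann["row"]), int(ann["col"])
            r1 = min(r0 + int(ann.get("h", 8)), H)
            c1 = min(c0 + int(ann.get("w", 12)), W)
            rgb[max(r0, 0):r1, max(c0, 0):c1, :] = val
        else:  # disc
            rr = (rows - ann["row"]) ** 2 + (cols - ann["col"]) ** 2
            rgb[rr <= ann.get("r", 5) ** 2, :] = val

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    pixels = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)

    truth_pos = np.linspace(0, L_mid, n_truth, endpoint=False)
    truth = PhantomTruth(
        geometry=geometry,
        truth_positions=truth_pos,
        truth_values=np.clip(expression_fn(truth_pos / L_mid), 0.0, 1.0),
        total_length=L_mid,
        background_level=background_level,
        noise_sd=noise_sd,
        seed=seed,
        description="painted cell-layer expression phantom",
    )
    return RGBImage(pixels=pixels), truth


def render_view_pair(truth_volume: ExpressionVolume) -> Tuple[ViewImage, ViewImage]:
    """Project a known volume into lateral and oral views.

    The optical model is the maximum expression along the viewing ray (the
    darkest raw pixel, for transparent embryos with dark stain): the lateral
    view collapses y, the oral view collapses x.  Reference points at two
    volume corners are emitted so the pair aligns to the identity map.
    """
    P = truth_volume.P
    n_x, n_y, n_z = P.shape
    lateral = P.max(axis=1).T  # [z, x]
    oral = P.max(axis=0).T  # [z, y]
    lat_refs = [Point2D(0, 0), Point2D(n_x - 1, n_z - 1)]
    oral_refs = [Point2D(0, 0), Point2D(n_y - 1, n_z - 1)]
    return (
        ViewImage(plane="lateral", expression=lateral, reference_points=lat_refs),
        ViewImage(plane="oral", expression=oral, reference_points=oral_refs),
    )


def make_box_volume(shape=(50, 50, 50), lo=(15, 20, 10), hi=(35, 32, 40), value=1.0) -> ExpressionVolume:
    """Axis-aligned box phantom (its support round-trips exactly)."""
    P = np.zeros(shape)
    P[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = value
    return ExpressionVolume(P=P)


def make_blob_volume(shape=(40, 40, 40), blobs=None) -> ExpressionVolume:
    """Smooth Gaussian-blob phantom volume."""
    if blobs is None:
        blobs = [((12, 20, 20), 5.0, 1.0), ((28, 20, 20), 6.0, 0.7)]
    x, y, z = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    P = np.zeros(shape)
    for (cx, cy, cz), sigma, amp in blobs:
        P += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) / (2 * sigma**2))
    return ExpressionVolume(P=np.clip(P, 0.0, 1.0))
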