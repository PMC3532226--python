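"""3D expression arrays from one or two embryo views, slicing, landscapes.

Axis convention: the primary (oral-aboral) body axis is x.  A lateral view
images the (x, z) plane and an oral view the (y, z) plane; view arrays are
stored image-like, rows = z and columns = x (or y), in inverted-intensity
expression units in [0, 1].  The reconstructed volume ``P`` is indexed
``P[x, y, z]``, voxel size equal to the source pixel size.

Two perpendicular views are mixed by taking, for every voxel, the minimum
expression of the associated pixel pair (equivalently the maximal raw
intensity, since the stain is dark on a light background): a voxel carries
signal only where both views see signal along their respective rays.  With a
single view, radial symmetry about a drawn in-plane axis is assumed and each
voxel takes a weighted average of the two base points where its circular arc
about the axis meets the image plane, with weights linear in azimuthal
angle.  Slices through the primary axis at equally incremented angles turn a
volume back into a stack of 2D images; decomposing, editing and
standardizing each angular slice yields the 2D expression landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .decomposition import RGBImage, decompose_cell_layer, measure_segments
from .errors import ReconstructionError
from .geometry import EmbryoGeometry, Point2D
from .profile_ops import apply_edit_script, standardize

__all__ = [
    "ViewImage",
    "ExpressionVolume",
    "ExpressionLandscape",
    "align_views",
    "reconstruct_two_views",
    "reconstruct_radial",
    "slice_volume",
    "build_landscape",
]


@dataclass
class ViewImage:
    """One embryo view in expression units.

    ``plane`` is ``"lateral"`` (x, z) or ``"oral"`` (y, z); ``expression``
    is stored rows = z, columns = x or y, values in [0, 1].  Reference
    points, if present, are (column, z) pairs used for z alignment.
    """

    plane: str
    expression: np.ndarray
    reference_points: Optional[List[Point2D]] = None

    def __post_init__(self):
        if self.plane not in ("lateral", "oral"):
            raise ValueError("plane must be 'lateral' or 'oral'")
        arr = np.asarray(self.expression, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expression must be a 2D array")
        if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
            raise ValueError("expression values must lie in [0, 1]")
        self.expression = np.clip(arr, 0.0, 1.0)

    @property
    def n_z(self) -> int:
        return self.expression.shape[0]


@dataclass
class ExpressionVolume:
    """3D expression array P[x, y, z], values in [0, 1]."""

    P: np.ndarray
    voxel_size: float = 1.0
    axis: str = "x"

    def __post_init__(self):
        arr = np.asarray(self.P, dtype=float)
        if arr.ndim != 3:
            raise ValueError("P must be a 3D array")
        self.P = arr

    @property
    def shape(self):
        return self.P.shape


@dataclass
class ExpressionLandscape:
    """Standardized profiles of angular slices stacked into a 2D array."""

    slice_angles: np.ndarray
    profiles: np.ndarray  # (n_slices, n_positions)
    grid: np.ndarray

    def __post_init__(self):
        self.slice_angles = np.asarray(self.slice_angles, dtype=float)
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if self.profiles.shape[0] != len(self.slice_angles):
            raise ValueError("row count must equal slice count")


def _fit_z_affine(z_src: np.ndarray, z_tgt: np.ndarray) -> Tuple[float, float]:
    """Closed-form 1D least squares for z_tgt ~ scale * z_src + shift."""
    z_src = np.asarray(z_src, dtype=float)
    z_tgt = np.asarray(z_tgt, dtype=float)
    if len(z_src) < 2:
        raise ReconstructionError("at least 2 reference points per view required")
    if np.ptp(z_src) == 0:
        raise ReconstructionError("reference points have zero z-spread")
    A = np.stack([z_src, np.ones_like(z_src)], axis=1)
    (scale, shift), *_ = np.linalg.lstsq(A, z_tgt, rcond=None)
    return float(scale), float(shift)


def align_views(lateral: ViewImage, oral: ViewImage) -> ViewImage:
    """Shift and scale the oral image's height to match the lateral view.

    Matched reference points on both views (in corresponding order) define a
    1D affine map on z; the oral image is resampled bilinearly onto the
    lateral z grid.
    """
    if not lateral.reference_points or not oral.reference_points:
        raise ReconstructionError("both views need reference points")
    if len(lateral.reference_points) != len(oral.reference_points):
        raise ReconstructionError("reference point counts differ")
    z_lat = np.array([p.y for p in lateral.reference_points])
    z_oral = np.array([p.y for p in oral.reference_points])
    scale, shift = _fit_z_affine(z_oral, z_lat)
    if scale == 0:
        raise ReconstructionError("degenerate z scale")
    n_z = lateral.n_z
    n_u = oral.expression.shape[1]
    # target z row k samples the oral image at (k - shift) / scale
    z_coords = (np.arange(n_z) - shift) / scale
    # snap float-noise offsets so an (almost) identity map resamples exactly
    near = np.abs(z_coords - np.round(z_coords)) < 1e-9
    z_coords[near] = np.round(z_coords[near])
    rows = np.repeat(z_coords[:, None], n_u, axis=1)
    cols = np.repeat(np.arange(n_u)[None, :], n_z, axis=0)
    resampled = map_coordinates(oral.expression, [rows, cols], order=1, mode="constant", cval=0.0)
    new_refs = [Point2D(p.x, scale * p.y + shift) for p in oral.reference_points]
    return ViewImage(plane="oral", expression=resampled, reference_points=new_refs)


def reconstruct_two_views(lateral: ViewImage, oral_aligned: ViewImage) -> ExpressionVolume:
    """Mix two aligned perpendicular views into a volume by the min rule.

    P[x, y, z] = min(S1[x, z], S2[y, z]) where S1 is the lateral and S2 the
    aligned oral view, both in expression units.
    """
    if lateral.n_z != oral_aligned.n_z:
        raise ReconstructionError(
            f"z extents differ: {lateral.n_z} vs {oral_aligned.n_z}; align views first"
        )
    S1 = lateral.expression.T  # [x, z]
    S2 = oral_aligned.expression.T  # [y, z]
    P = np.minimum(S1[:, None, :], S2[None, :, :])
    return ExpressionVolume(P=P)


def reconstruct_radial(
    image: ViewImage,
    axis_line: Tuple[Point2D, Point2D],
    out_depth: Optional[int] = None,
) -> ExpressionVolume:
    """Volume from a single view assuming radial symmetry about a drawn axis.

    The axis line lies in the image plane (y = 0 through the volume's
    central y index).  For each voxel, the circle about the axis through it
    meets the image plane at base points S1 (the half-plane the voxel leans
    toward at angle 0) and S2; the voxel value is the average of the two
    bilinearly sampled base intensities weighted linearly in the azimuthal
    angle theta in [0, pi]:  (1 - theta/pi) * I(S1) + (theta/pi) * I(S2).
    Base points outside the image give 0.
    """
    (a, b) = axis_line
    A = np.array([a.x, a.y], dtype=float)
    B = np.array([b.x, b.y], dtype=float)
    u = B - A
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ReconstructionError("axis line has zero length")
    u = u / norm
    nvec = np.array([-u[1], u[0]])  # in-plane unit normal; S1 side is +n

    img = image.expression  # [z, x]; in-plane coordinates are (x, z)
    n_z, n_x = img.shape
    if out_depth is None:
        out_depth = n_z
    y_c = (out_depth - 1) / 2.0

    xs = np.arange(n_x, dtype=float)
    zs = np.arange(n_z, dtype=float)
    X, Z = np.meshgrid(xs, zs, indexing="ij")  # in-plane voxel coordinates
    # Signed in-plane coordinates relative to the axis: t along, p across.
    dx = X - A[0]
    dz = Z - A[1]
    t = dx * u[0] + dz * u[1]
    p_plane = dx * nvec[0] + dz * nvec[1]

    P = np.empty((n_x, out_depth, n_z), dtype=float)
    foot_x = A[0] + t * u[0]
    foot_z = A[1] + t * u[1]
    for j in range(out_depth):
        y = j - y_c
        r = np.hypot(p_plane, y)
        theta = np.arctan2(np.abs(y), p_plane)  # in [0, pi]
        w2 = theta / np.pi
        s1x, s1z = foot_x + r * nvec[0], foot_z + r * nvec[1]
        s2x, s2z = foot_x - r * nvec[0], foot_z - r * nvec[1]
        i1 = map_coordinates(img, [s1z, s1x], order=1, mode="constant", cval=0.0)
        i2 = map_coordinates(img, [s2z, s2x], order=1, mode="constant", cval=0.0)
        P[:, j, :] = (1.0 - w2) * i1 + w2 * i2
    return ExpressionVolume(P=P)


def slice_volume(volume: ExpressionVolume, n_slices: int = 9) -> List[np.ndarray]:
    """Planes through the primary axis at equally incremented angles.

    Slice k lies at angle k * 180 / n_slices degrees about the line through
    the volume center parallel to the x axis; slice 0 is the original
    central (x, z) plane.  Each slice is returned image-like (rows = the
    rotated in-plane coordinate w, columns = x), sampled trilinearly; points
    outside the volume read 0.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    P = volume.P
    n_x, n_y, n_z = P.shape
    y_c = (n_y - 1) / 2.0
    z_c = (n_z - 1) / 2.0
    xs = np.arange(n_x, dtype=float)
    ws = np.arange(n_z, dtype=float)
    Wg, Xg = np.meshgrid(ws, xs, indexing="ij")  # slice rows = w, cols = x
    slices = []
    for k in range(n_slices):
        alpha = np.pi * k / n_slices
        y = y_c + (Wg - z_c) * np.sin(alpha)
        z = z_c + (Wg - z_c) * np.cos(alpha)
        sl = map_coordinates(P, [Xg, y, z], order=1, mode="constant", cval=0.0)
        slices.append(sl)
    return slices


def build_landscape(
    volume: ExpressionVolume,
    geometry: EmbryoGeometry,
    segment_length: float,
    n_slices: int = 9,
    edit_script: Optional[dict] = None,
    pin: float = 25.0,
    allow_zero: bool = True,
    **decompose_kwargs,
) -> ExpressionLandscape:
    """Decompose, edit and standardize every angular slice of a volume.

    The shared ``geometry`` must be registered to the central slice (slice
    pixel coordinates: x = column, w = row).  Each slice is measured with
    the common decomposition, passed through the shared ``edit_script`` (if
    any), resampled to the standard coordinate, and the rows stacked in
    slice order.  All rows share one intensity scale (the landscape's global
    maximum becomes 100), so amplitude differences between angular slices
    are preserved.
    """
    decomposition = decompose_cell_layer(geometry, segment_length, **decompose_kwargs)
    slices = slice_volume(volume, n_slices=n_slices)
    rows = []
    grid = None
    for sl in slices:
        img = RGBImage(pixels=np.repeat(sl[:, :, None] * 255.0, 3, axis=2))
        profile = measure_segments(img, decomposition, invert=False)
        if edit_script is not None:
            edited = apply_edit_script(profile, edit_script)
        else:
            edited = profile
        if isinstance(edited, type(profile)):
            std = standardize(edited, pin=pin, allow_zero=allow_zero, rescale=False)
        else:
            std = edited
        grid = std.grid
        rows.append(std.values)
    profiles = np.vstack(rows)
    if profiles.max() > 0:
        profiles = profiles * (100.0 / profiles.max())
    angles = 180.0 * np.arange(n_slices) / n_slices
    return ExpressionLandscape(slice_angles=angles, profiles=profiles, grid=grid)
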