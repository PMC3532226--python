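"""Editing and standardization of 1D expression profiles.

Raw profiles measured along the cell layer carry artefacts that do not
reflect transcript concentration: troughs and ridges from figure annotations,
decomposition noise, an uneven baseline from non-uniform background and
lighting, and small left/right asymmetries.  The operations here mirror a
manual profile editor: interval repair by interpolation, circular moving
average smoothing, constant baseline subtraction (clamped at zero), zeroing
of regions without observed expression, and symmetrization by averaging the
two halves of the loop about the aboral anchor.

Standardization maps every edited profile to a common coordinate: the
endoderm center at position 0, the two endoderm-ectoderm boundaries pinned
at -pin/+pin (default 25), and the aboral pole at -50 and +50 (the same
physical point, since the cell layer is a closed loop); the maximum
intensity is rescaled to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .decomposition import ExpressionProfile, RGBImage
from .errors import EditError, NoExpressionError

__all__ = [
    "StandardProfile",
    "invert_image",
    "repair_interval",
    "moving_average",
    "subtract_baseline",
    "zero_regions",
    "symmetrize",
    "standardize",
    "apply_edit_script",
]

_CHANNELS = ("r", "g", "b", "grey")


@dataclass
class StandardProfile:
    """A profile on the normalized -50..+50 grid with maximum value 100."""

    grid: np.ndarray
    values: np.ndarray
    gene: Optional[str] = None
    stage: Optional[str] = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid/values length mismatch")

    @property
    def label(self) -> str:
        return f"{self.gene or 'gene'}:{self.stage if self.stage is not None else '?'}"

    def __len__(self):
        return len(self.grid)


def invert_image(image: RGBImage) -> RGBImage:
    """Color inversion v -> 255 - v, so darker stain means larger value."""
    return RGBImage(pixels=255.0 - np.asarray(image.pixels, dtype=float),
                    inverted=not image.inverted)


def _resolve_channels(channel) -> Tuple[str, ...]:
    if channel in (None, "all"):
        return _CHANNELS
    if channel not in _CHANNELS:
        raise EditError(f"unknown channel {channel!r}")
    return (channel,)


def repair_interval(
    profile: ExpressionProfile,
    interval: Tuple[int, int],
    method: str = "linear",
    channel: str = "all",
    constant_value: Optional[float] = None,
) -> ExpressionProfile:
    """Replace an artefact interval by an interpolant fitted to its flanks.

    ``interval`` is a half-open index range ``(start, stop)``.  Methods:
    ``linear`` (2 context points per side), ``cubic_spline`` and ``pchip``
    (4 per side), and ``constant`` (requires ``constant_value``).
    """
    start, stop = interval
    n = len(profile)
    if not (0 <= start < stop <= n):
        raise EditError(f"invalid interval {interval}")
    context = {"linear": 2, "cubic_spline": 4, "pchip": 4, "constant": 0}.get(method)
    if context is None:
        raise EditError(f"unknown repair method {method!r}")
    if method == "constant":
        if constant_value is None:
            raise EditError("constant method requires constant_value")
    elif start < context or stop > n - context:
        raise EditError(
            f"interval {interval} too close to profile ends for {method} "
            f"(needs {context} context points each side)"
        )

    x = profile.positions
    out = {}
    for ch in _resolve_channels(channel):
        v = profile.channel(ch).copy()
        if method == "constant":
            v[start:stop] = constant_value
        else:
            xi = np.concatenate([x[start - context:start], x[stop:stop + context]])
            yi = np.concatenate([v[start - context:start], v[stop:stop + context]])
            if method == "linear":
                v[start:stop] = np.interp(x[start:stop], xi, yi)
            elif method == "cubic_spline":
                v[start:stop] = CubicSpline(xi, yi)(x[start:stop])
            else:  # pchip: shape-preserving, monotone on monotone context
                v[start:stop] = PchipInterpolator(xi, yi)(x[start:stop])
        out[ch] = v
    return profile.with_values(**out)


def moving_average(profile: ExpressionProfile, span: int) -> ExpressionProfile:
    """Circular moving average with coefficients 1/span (span odd).

    The profile is a closed loop, so the window wraps around the ends;
    the circular mean of the profile is preserved exactly.
    """
    if span % 2 == 0 or span < 1:
        raise EditError("span must be a positive odd integer")
    n = len(profile)
    if span > n:
        raise EditError("span exceeds profile length")
    kernel = np.ones(span) / span
    half = span // 2
    out = {}
    for ch in _CHANNELS:
        v = profile.channel(ch)
        padded = np.concatenate([v[-half:], v, v[:half]]) if half else v
        out[ch] = np.convolve(padded, kernel, mode="valid")
    return profile.with_values(**out)


def subtract_baseline(profile: ExpressionProfile, baseline: float) -> ExpressionProfile:
    """Lower the profile by a constant background level, clamping at zero."""
    if baseline < 0:
        raise EditError("baseline must be non-negative")
    return profile.with_values(
        **{ch: np.maximum(profile.channel(ch) - baseline, 0.0) for ch in _CHANNELS}
    )


def zero_regions(profile: ExpressionProfile, intervals: Sequence[Tuple[int, int]]) -> ExpressionProfile:
    """Set regions without observed expression to exactly zero.

    ``intervals`` are half-open index ranges; overlaps are fine (idempotent).
    """
    n = len(profile)
    out = {ch: profile.channel(ch).copy() for ch in _CHANNELS}
    for start, stop in intervals:
        if not (0 <= start <= stop <= n):
            raise EditError(f"interval ({start}, {stop}) outside profile")
        for v in out.values():
            v[start:stop] = 0.0
    return profile.with_values(**out)


def _circular_interp(s, positions, values, period):
    """Linear interpolation on a closed loop of period ``period``."""
    s = np.mod(np.asarray(s, dtype=float), period)
    xp = np.concatenate([[positions[-1] - period], positions, [positions[0] + period]])
    fp = np.concatenate([[values[-1]], values, [values[0]]])
    return np.interp(s, xp, fp)


def symmetrize(profile: ExpressionProfile) -> ExpressionProfile:
    """Average the two halves of the loop about the aboral anchor.

    v'(s) = (v(s) + v(L - s)) / 2, with v(L - s) read off by circular linear
    interpolation between segment centers; cancels nonsymmetric influences
    such as one-sided lighting.  Idempotent up to interpolation error and a
    fixed point for mirror-symmetric profiles.
    """
    L = profile.total_length
    s = profile.positions
    out = {}
    for ch in _CHANNELS:
        v = profile.channel(ch)
        mirrored = _circular_interp(L - s, s, v, L)
        out[ch] = 0.5 * (v + mirrored)
    return profile.with_values(**out)


def _coordinate_map(total_length, boundary_positions, pin):
    """Return (normalized_knots, arc_knots) for the piecewise-linear map.

    With endoderm boundaries b1 < b2: aboral anchor (s=0) -> -50, b1 -> -pin,
    the endoderm arc-center (b1+b2)/2 -> 0, b2 -> +pin, s=L -> +50.  Without
    boundaries (blastula): the oral pole s=L/2 -> 0, aboral -> +/-50.
    """
    L = total_length
    if boundary_positions is None:
        return np.array([-50.0, 0.0, 50.0]), np.array([0.0, L / 2, L])
    b1, b2 = sorted(boundary_positions)
    if not (0 < b1 < b2 < L):
        raise EditError(f"boundary positions {boundary_positions} outside (0, {L})")
    if not (0 < pin < 50):
        raise EditError("pin must lie strictly between 0 and 50")
    mid = 0.5 * (b1 + b2)
    return (
        np.array([-50.0, -float(pin), 0.0, float(pin), 50.0]),
        np.array([0.0, b1, mid, b2, L]),
    )


def standardize(
    profile: ExpressionProfile,
    boundary_positions: Optional[Tuple[float, float]] = None,
    pin: float = 25.0,
    n_out: int = 101,
    channel: str = "grey",
    allow_zero: bool = False,
    rescale: bool = True,
    gene: Optional[str] = None,
    stage: Optional[str] = None,
) -> StandardProfile:
    """Resample a profile onto the normalized -50..+50 grid, maximum 100.

    ``boundary_positions`` defaults to the positions recorded on the profile
    by the decomposition; pass None with a profile lacking them for the
    blastula mapping (no pins, oral pole at 0).  ``rescale=False`` keeps the
    original intensity units (used when several profiles share one scale,
    as in an expression landscape).

    Raises
    ------
    NoExpressionError
        If the profile is identically zero and ``allow_zero`` is False.
    """
    if boundary_positions is None:
        boundary_positions = profile.boundary_positions
    v = profile.channel(channel)
    vmax = float(np.max(v))
    if vmax <= 0 and not allow_zero:
        raise NoExpressionError("profile has no expression (max <= 0)")
    knots_u, knots_s = _coordinate_map(profile.total_length, boundary_positions, pin)
    grid = np.linspace(-50.0, 50.0, n_out)
    s_of_u = np.interp(grid, knots_u, knots_s)
    values = _circular_interp(s_of_u, profile.positions, v, profile.total_length)
    if rescale and np.max(values) > 0:
        values = values * (100.0 / np.max(values))
    return StandardProfile(grid=grid, values=values, gene=gene, stage=stage)


def apply_edit_script(profile: ExpressionProfile, script: dict):
    """Apply an ordered edit script (as parsed from YAML) to a profile.

    The script is ``{"ops": [...]}`` where each op is a mapping with an
    ``op`` key naming one of repair / moving_average / subtract_baseline /
    zero / symmetrize / standardize plus that operation's keyword arguments.
    Returns the edited :class:`ExpressionProfile`, or a
    :class:`StandardProfile` if the chain ends with a standardize step.
    """
    current = profile
    for op in script.get("ops", []):
        op = dict(op)
        name = op.pop("op")
        if name == "repair":
            current = repair_interval(current, tuple(op.pop("interval")), **op)
        elif name == "moving_average":
            current = moving_average(current, **op)
        elif name == "subtract_baseline":
            current = subtract_baseline(current, **op)
        elif name == "zero":
            current = zero_regions(current, [tuple(iv) for iv in op.pop("intervals")], **op)
        elif name == "symmetrize":
            current = symmetrize(current)
        elif name == "standardize":
            if "boundary_positions" in op and op["boundary_positions"] is not None:
                op["boundary_positions"] = tuple(op["boundary_positions"])
            current = standardize(current, **op)
        else:
            raise EditError(f"unknown edit operation {name!r}")
    return current
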