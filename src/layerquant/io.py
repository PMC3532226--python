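"""File formats: images, profile CSVs, edit-script YAML, volume files.

Profiles travel as plain CSV with a few ``#`` header comment lines carrying
the ribbon length, boundary positions and metadata.  Volumes are written as
raw little-endian float32 with a JSON sidecar recording dimensions, voxel
size and the axis convention.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .decomposition import ExpressionProfile, RGBImage
from .profile_ops import StandardProfile
from .volume3d import ExpressionVolume

__all__ = [
    "load_image", "save_image",
    "save_profile", "load_profile",
    "save_standard_profile", "load_standard_profile",
    "load_edit_script",
    "save_volume", "load_volume",
]


def load_image(path) -> RGBImage:
    """Read a PNG/TIFF as 8-bit RGB (greyscale promoted, alpha dropped)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr.astype(float) / arr.max() * 255.0, 0, 255).astype(np.uint8)
    return RGBImage(pixels=arr)


def save_image(image: RGBImage, path):
    iio.imwrite(path, np.clip(np.round(image.pixels), 0, 255).astype(np.uint8))


def save_profile(profile: ExpressionProfile, path):
    with open(path, "w") as fh:
        fh.write(f"# total_length={float(profile.total_length)!r}\n")
        if profile.boundary_positions is not None:
            b1, b2 = profile.boundary_positions
            fh.write(f"# boundary_positions={float(b1)!r},{float(b2)!r}\n")
        fh.write("position_px,mean_r,mean_g,mean_b,mean_grey\n")
        for i in range(len(profile)):
            fh.write(
                f"{float(profile.positions[i])!r},{float(profile.mean_r[i])!r},"
                f"{float(profile.mean_g[i])!r},{float(profile.mean_b[i])!r},"
                f"{float(profile.mean_grey[i])!r}\n"
            )


def _read_header_comments(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, val = line[1:].strip().split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def load_profile(path) -> ExpressionProfile:
    meta = _read_header_comments(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    boundary = None
    if "boundary_positions" in meta:
        b1, b2 = meta["boundary_positions"].split(",")
        boundary = (float(b1), float(b2))
    return ExpressionProfile(
        positions=df["position_px"].to_numpy(),
        mean_r=df["mean_r"].to_numpy(),
        mean_g=df["mean_g"].to_numpy(),
        mean_b=df["mean_b"].to_numpy(),
        mean_grey=df["mean_grey"].to_numpy(),
        total_length=float(meta["total_length"]),
        boundary_positions=boundary,
    )


def save_standard_profile(profile: StandardProfile, path):
    with open(path, "w") as fh:
        if profile.gene is not None:
            fh.write(f"# gene={profile.gene}\n")
        if profile.stage is not None:
            fh.write(f"# stage={profile.stage}\n")
        fh.write("position_norm,value\n")
        for g, v in zip(profile.grid, profile.values):
            fh.write(f"{float(g)!r},{float(v)!r}\n")


def load_standard_profile(path) -> StandardProfile:
    meta = _read_header_comments(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    gene, stage = meta.get("gene"), meta.get("stage")
    if gene is None:
        # fall back to the {gene}_{hpf}.csv filename convention
        stem = os.path.splitext(os.path.basename(path))[0]
        if "_" in stem:
            gene, stage = stem.rsplit("_", 1)
        else:
            gene = stem
    return StandardProfile(
        grid=df["position_norm"].to_numpy(),
        values=df["value"].to_numpy(),
        gene=gene,
        stage=stage,
    )


def load_edit_script(path) -> dict:
    with open(path) as fh:
        script = yaml.safe_load(fh)
    if not isinstance(script, dict) or "ops" not in script:
        raise ValueError("edit script must be a mapping with an 'ops' list")
    return script


def save_volume(volume: ExpressionVolume, path):
    """Raw little-endian float32 voxels + a ``<path>.json`` sidecar."""
    P = np.ascontiguousarray(volume.P, dtype="<f4")
    P.tofile(path)
    sidecar = {
        "dims": list(volume.P.shape),
        "dtype": "<f4",
        "order": "C",
        "index_order": ["x", "y", "z"],
        "voxel_size": volume.voxel_size,
        "primary_axis": volume.axis,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_volume(path) -> ExpressionVolume:
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    P = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["dims"])
    return ExpressionVolume(
        P=P.astype(float),
        voxel_size=sidecar.get("voxel_size", 1.0),
        axis=sidecar.get("primary_axis", "x"),
    )
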