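"""Calibrated 3D stack I/O and tile stitching.

The package-wide conventions are fixed here once: arrays are indexed
``(z, y, x)`` with 0-based indices and half-open bounding boxes, and all
physical calibration is in micrometres. Stacks are stored as OME-TIFF with
the voxel size and channel name embedded; free-form experiment metadata
(condition, culture day, replicate) travels in a JSON sidecar next to the
image file so that plain multi-page TIFF remains usable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile

from .errors import CalibrationError, ConfigurationError, GridMismatchError

__all__ = [
    "ImageStack",
    "TileLayout",
    "read_stack",
    "write_stack",
    "write_multichannel",
    "stitch_tiles",
    "split_tiles",
]

#: Full-scale intensity of the linear 16-bit-like range used throughout.
MAX_SCALE = 65535.0


@dataclass
class ImageStack:
    """A single-channel calibrated 3D intensity grid.

    Attributes
    ----------
    intensities:
        ``(z, y, x)`` array of nonnegative intensities.
    voxel_size:
        ``(dz, dy, dx)`` voxel edge lengths in µm, all strictly positive.
    channel:
        Channel name; the pipeline uses ``"TNBC"`` and ``"LEC"``.
    meta:
        Experiment metadata (``condition``, ``day``, ``replicate``, ...).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "other"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ConfigurationError(
                f"stack must be 3D (z, y, x); got ndim={self.intensities.ndim}"
            )
        if min(self.intensities.shape) < 1:
            raise ConfigurationError(f"empty stack dimension: shape={self.intensities.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise CalibrationError(f"voxel_size must be 3 strictly positive values, got {vs}")
        self.voxel_size = vs
        if np.issubdtype(self.intensities.dtype, np.number) and self.intensities.size:
            if float(self.intensities.min()) < 0:
                raise ConfigurationError("stack intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def with_intensities(self, intensities: np.ndarray) -> "ImageStack":
        """Copy of this stack carrying new intensities on the same grid."""
        return ImageStack(intensities, self.voxel_size, self.channel, dict(self.meta))


@dataclass
class TileLayout:
    """Row-major mosaic layout of contiguous fields (e.g. 4x4 = 16 tiles)."""

    rows: int
    cols: int

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("TileLayout rows and cols must be >= 1")


def _sidecar_path(path: str) -> str:
    return str(path) + ".meta.json"


def write_stack(stack: ImageStack, path: str) -> None:
    """Write a stack as OME-TIFF with calibration and channel embedded.

    Experiment metadata is written to a ``<path>.meta.json`` sidecar.
    """
    dz, dy, dx = stack.voxel_size
    data = np.asarray(stack.intensities)
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": [stack.channel]},
        },
    )
    if stack.meta:
        with open(_sidecar_path(path), "w") as fh:
            json.dump(stack.meta, fh, indent=1, sort_keys=True)


def write_multichannel(stacks: Sequence[ImageStack], path: str) -> None:
    """Write several same-grid channels into one multi-channel OME-TIFF."""
    if not stacks:
        raise ConfigurationError("no stacks given")
    ref = stacks[0]
    for s in stacks[1:]:
        if s.shape != ref.shape or s.voxel_size != ref.voxel_size:
            raise GridMismatchError("all channels must share grid shape and voxel size")
    dz, dy, dx = ref.voxel_size
    data = np.stack([np.asarray(s.intensities) for s in stacks])
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "Channel": {"Name": [s.channel for s in stacks]},
        },
    )
    merged = {}
    for s in stacks:
        merged.update(s.meta)
    if merged:
        with open(_sidecar_path(path), "w") as fh:
            json.dump(merged, fh, indent=1, sort_keys=True)


def read_stack(
    path: str,
    channel: str | None = None,
    voxel_size_override: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a calibrated stack from (OME-)TIFF.

    Parameters
    ----------
    path:
        Multi-page TIFF or OME-TIFF file.
    channel:
        For multi-channel files, the name of the channel to extract
        (required); for single-channel files, overrides the stored name.
    voxel_size_override:
        ``(dz, dy, dx)`` in µm; required when the file carries no
        calibration. Missing calibration is an error, never a silent
        default.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        voxel_size = None
        channel_names: list[str] = []
        if tf.ome_metadata:
            px = tifffile.xml2dict(tf.ome_metadata)["OME"]["Image"]
            if isinstance(px, list):
                px = px[0]
            px = px["Pixels"]
            sizes = (px.get("PhysicalSizeZ"), px.get("PhysicalSizeY"), px.get("PhysicalSizeX"))
            if all(s is not None for s in sizes):
                voxel_size = tuple(float(s) for s in sizes)
            chans = px.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            channel_names = [c.get("Name") or f"channel{i}" for i, c in enumerate(chans)]

    if voxel_size_override is not None:
        voxel_size = tuple(float(v) for v in voxel_size_override)
    if voxel_size is None:
        raise CalibrationError(
            f"{path}: no voxel calibration in metadata and no voxel_size_override given"
        )

    if "C" in axes:
        c_axis = axes.index("C")
        if channel is None:
            raise ConfigurationError(
                f"{path} has {data.shape[c_axis]} channels {channel_names}; specify one"
            )
        if channel not in channel_names:
            raise ConfigurationError(f"channel '{channel}' not in {channel_names} of {path}")
        data = np.take(data, channel_names.index(channel), axis=c_axis)
        name = channel
    else:
        if data.ndim != 3:
            raise ConfigurationError(f"{path}: expected 3D content, got shape {data.shape}")
        name = channel or (channel_names[0] if channel_names else "other")
    if data.ndim != 3:
        raise ConfigurationError(f"{path}: expected 3D content, got shape {data.shape}")

    meta = {}
    if os.path.exists(_sidecar_path(path)):
        with open(_sidecar_path(path)) as fh:
            meta = json.load(fh)
    return ImageStack(data, voxel_size, channel=name, meta=meta)


def stitch_tiles(tiles: Sequence[ImageStack], layout: TileLayout) -> ImageStack:
    """Assemble contiguous fields into one volume by exact abutment in x–y.

    Tiles are placed row-major with no registration and no blending,
    mirroring mosaics already registered by the acquisition software.
    """
    if layout.rows * layout.cols != len(tiles):
        raise ConfigurationError(
            f"layout {layout.rows}x{layout.cols} expects {layout.rows * layout.cols} tiles, "
            f"got {len(tiles)}"
        )
    ref = tiles[0]
    for i, t in enumerate(tiles[1:], start=1):
        if t.shape != ref.shape:
            raise GridMismatchError(f"tile {i} shape {t.shape} != tile 0 shape {ref.shape}")
        if t.voxel_size != ref.voxel_size:
            raise CalibrationError(f"tile {i} voxel_size {t.voxel_size} != {ref.voxel_size}")
        if t.channel != ref.channel:
            raise ConfigurationError(f"tile {i} channel '{t.channel}' != '{ref.channel}'")
    rows = [
        np.concatenate([tiles[r * layout.cols + c].intensities for c in range(layout.cols)], axis=2)
        for r in range(layout.rows)
    ]
    mosaic = np.concatenate(rows, axis=1)
    return ImageStack(mosaic, ref.voxel_size, ref.channel, dict(ref.meta))


def split_tiles(stack: ImageStack, layout: TileLayout) -> list[ImageStack]:
    """Split a stack into a row-major grid of tiles (inverse of stitching).

    The y and x extents must divide evenly by the layout.
    """
    nz, ny, nx = stack.shape
    if ny % layout.rows or nx % layout.cols:
        raise ConfigurationError(
            f"shape {(ny, nx)} not divisible by layout {layout.rows}x{layout.cols}"
        )
    ty, tx = ny // layout.rows, nx // layout.cols
    out = []
    for r in range(layout.rows):
        for c in range(layout.cols):
            sub = stack.intensities[:, r * ty : (r + 1) * ty, c * tx : (c + 1) * tx]
            out.append(ImageStack(sub.copy(), stack.voxel_size, stack.channel, dict(stack.meta)))
    return out
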