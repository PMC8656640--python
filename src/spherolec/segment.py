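"""Binary segmentation of channel stacks and object labeling.

A channel is segmented by a global threshold (Otsu by default, a fixed
intensity optionally), followed by morphological closing with a
physical-radius ball, optional 3D hole filling, and removal of connected
components below a minimum physical volume — an object-level noise
filter. Labeled tumor objects are extracted with 26-connectivity and
ordered deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, GridMismatchError
from .image_io import ImageStack
from .morphology import physical_ball

__all__ = [
    "BinaryMask",
    "LabelMap",
    "ObjectRecord",
    "SegmentParams",
    "segment_channel",
    "label_objects",
    "dice",
]

logger = logging.getLogger(__name__)

#: 26-connectivity structuring element for 3D connected components.
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """A boolean foreground mask on a calibrated grid."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "other"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ConfigurationError(f"mask must be 3D, got ndim={self.voxels.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ConfigurationError(f"voxel_size must be strictly positive, got {vs}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def volume(self) -> float:
        """Mask volume in µm³ (voxel count × voxel volume)."""
        return int(self.voxels.sum()) * self.voxel_volume


@dataclass
class ObjectRecord:
    """Morphometry of one labeled connected component."""

    label: int
    voxel_count: int
    volume: float  # µm³, exactly voxel_count × voxel volume
    centroid: tuple[float, float, float]  # (z, y, x) in µm
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open voxel ranges


@dataclass
class LabelMap:
    """Dense 1..N labeling of connected foreground objects."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    objects: list[ObjectRecord] = field(default_factory=list)
    channel: str = "other"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def object_mask(self, label: int) -> BinaryMask:
        return BinaryMask(self.labels == label, self.voxel_size, self.channel)

    def foreground(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.voxel_size, self.channel)


@dataclass
class SegmentParams:
    """Segmentation parameters.

    threshold_method:
        ``"otsu"`` (default, parameter-free) or ``"fixed"``.
    fixed_threshold:
        Intensity used when ``threshold_method == "fixed"``.
    min_object_volume:
        Components smaller than this (µm³) are discarded; object-level
        noise removal. Default 500 µm³ (well below a single-cell volume).
    closing_radius:
        Radius (µm) of the ball used for morphological closing; 0 skips.
    fill_holes:
        Fill enclosed 3D background cavities after closing.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    min_object_volume: float = 500.0
    closing_radius: float = 1.0
    fill_holes: bool = True

    def __post_init__(self):
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigurationError(f"unknown threshold_method '{self.threshold_method}'")
        if self.min_object_volume < 0:
            raise ConfigurationError("min_object_volume must be >= 0")
        if self.closing_radius < 0:
            raise ConfigurationError("closing_radius must be >= 0")


def segment_channel(stack: ImageStack, params: SegmentParams) -> BinaryMask:
    """Threshold → close → fill holes → drop small components.

    A constant image leaves Otsu's threshold undefined; an empty mask is
    returned with a logged warning rather than raising.
    """
    data = np.asarray(stack.intensities, dtype=np.float64)
    if params.threshold_method == "otsu":
        if np.all(data == data.flat[0]):
            logger.warning(
                "constant image in channel '%s': Otsu threshold undefined, returning empty mask",
                stack.channel,
            )
            return BinaryMask(np.zeros(data.shape, dtype=bool), stack.voxel_size, stack.channel)
        thr = float(threshold_otsu(data))
    else:
        thr = float(params.fixed_threshold)
    mask = data > thr

    if params.closing_radius > 0:
        footprint = physical_ball(params.closing_radius, stack.voxel_size)
        if footprint.size > 1:
            mask = ndimage.binary_closing(mask, structure=footprint)
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)

    if params.min_object_volume > 0 and mask.any():
        voxel_volume = float(np.prod(stack.voxel_size))
        min_voxels = params.min_object_volume / voxel_volume
        labels, n = ndimage.label(mask, structure=STRUCTURE_26)
        if n:
            counts = np.bincount(labels.ravel())
            keep = counts >= min_voxels
            keep[0] = False
            mask = keep[labels]
    return BinaryMask(mask, stack.voxel_size, stack.channel)


def label_objects(mask: BinaryMask) -> LabelMap:
    """26-connected components with deterministic label ordering.

    Labels are dense 1..N, sorted by descending voxel count; ties broken
    by the (z, y, x) scan position of each component's first voxel.
    """
    raw, n = ndimage.label(mask.voxels, structure=STRUCTURE_26)
    if n == 0:
        return LabelMap(raw.astype(np.int32), mask.voxel_size, [], mask.channel)
    counts = np.bincount(raw.ravel())[1:]  # per raw label 1..n
    flat = raw.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier scan positions win
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(1, n + 1), key=lambda l: (-counts[l - 1], first_idx[l]))
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    labels = remap[raw]

    voxel_volume = mask.voxel_volume
    slices = ndimage.find_objects(labels)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, list(range(1, n + 1)))
    records = []
    for new, old in enumerate(order, start=1):
        sl = slices[new - 1]
        cz, cy, cx = centroids[new - 1]
        records.append(
            ObjectRecord(
                label=new,
                voxel_count=int(counts[old - 1]),
                volume=int(counts[old - 1]) * voxel_volume,
                centroid=(
                    cz * mask.voxel_size[0],
                    cy * mask.voxel_size[1],
                    cx * mask.voxel_size[2],
                ),
                bbox=tuple((s.start, s.stop) for s in sl),
            )
        )
    return LabelMap(labels, mask.voxel_size, records, mask.channel)


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    av = a.voxels if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    bv = b.voxels if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if av.shape != bv.shape:
        raise GridMismatchError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((av & bv).sum()) / denom
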