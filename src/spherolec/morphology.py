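"""Structuring elements in physical units.

All morphological operations in the package use footprints defined by a
radius in micrometres and rasterized per axis with the voxel calibration,
so behaviour is invariant to voxel size and correct for anisotropic stacks
(dz != dx).
"""

from __future__ import annotations

import numpy as np

__all__ = ["physical_ball"]


def physical_ball(radius_um: float, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Boolean ellipsoidal footprint covering a ball of ``radius_um`` µm.

    Parameters
    ----------
    radius_um:
        Ball radius in micrometres. ``0`` yields a single-voxel footprint
        (the identity element for dilation/erosion).
    voxel_size:
        ``(dz, dy, dx)`` voxel edge lengths in micrometres.

    Returns
    -------
    numpy.ndarray
        Odd-shaped boolean array; a voxel is inside when its centre lies
        within ``radius_um`` of the footprint centre in physical space.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    half = [int(np.floor(radius_um / v)) for v in voxel_size]
    grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    dist2 = sum((g * v) ** 2 for g, v in zip(grids, voxel_size))
    # tiny tolerance so voxels exactly on the shell are included
    return dist2 <= radius_um**2 * (1 + 1e-9) + 1e-12
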