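"""Detector-style CT preprocessing: intensity normalization and cubic resize.

The two operations mirror what 3D detection networks expect as input: voxel
values mapped by ``(v + 1024) / 2048`` from Hounsfield units onto [0, 1]
(air at -1024 HU -> 0, dense contrast/bone at +1024 HU -> 1), and the grid
resampled to an isotropic cube (default edge 350).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ContractViolationError
from .io_formats import Volume

__all__ = ["normalize_intensity", "resize_cubic"]

DEFAULT_EDGE = 350
HU_OFFSET = 1024.0
HU_RANGE = 2048.0


def normalize_intensity(vol: Volume, clip: bool = True) -> Volume:
    """Map Hounsfield units to [0, 1] via ``(v + 1024) / 2048``.

    Values above 1024 HU (dense calcium, metal) would exceed 1, so the result
    is clipped to [0, 1] by default; pass ``clip=False`` to keep the raw
    affine intensity map. Raises on an already-normalized volume to prevent
    silent double normalization.
    """
    if vol.intensity_space != "hu":
        raise ContractViolationError(
            "volume is already normalized; refusing to normalize twice"
        )
    data = (np.asarray(vol.data, dtype=float) + HU_OFFSET) / HU_RANGE
    if clip:
        data = np.clip(data, 0.0, 1.0)
    return Volume(data=data, affine=vol.affine.copy(), intensity_space="normalized")


def resize_cubic(vol: Volume, edge: int = DEFAULT_EDGE, order: str = "linear") -> Volume:
    """Resample a volume onto an ``edge`` x ``edge`` x ``edge`` grid.

    Sampling is corner-aligned: output sample ``i`` on an axis of source
    length ``n`` lands at source index ``i * (n - 1) / (edge - 1)``, so the
    hull of voxel centers (hence the world-space bounding box of the sampled
    field) is preserved exactly and resizing to the source shape is an exact
    no-op. The affine's spatial columns are rescaled by ``(n - 1)/(edge - 1)``
    per axis so every output voxel keeps its world position.

    ``order`` is ``"linear"`` (trilinear, for images) or ``"nearest"``
    (for label masks).
    """
    if edge < 2:
        raise ContractViolationError(f"edge must be >= 2, got {edge}")
    if order not in ("linear", "nearest"):
        raise ContractViolationError(f"unknown interpolation order {order!r}")

    src = np.asarray(vol.data, dtype=float)
    shape = np.asarray(src.shape, dtype=float)
    # scale 1.0 on degenerate single-slice axes keeps the affine invertible
    scale = np.where(shape > 1, (shape - 1) / (edge - 1), 1.0)

    idx = [np.arange(edge) * scale[a] for a in range(3)]
    grid = np.meshgrid(*idx, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndimage.map_coordinates(
        src, coords, order=1 if order == "linear" else 0, mode="nearest"
    ).reshape((edge, edge, edge))

    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] * scale[np.newaxis, :]
    return Volume(data=out, affine=new_affine, intensity_space=vol.intensity_space)
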