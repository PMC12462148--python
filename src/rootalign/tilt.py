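"""Aortic-root tilt alignment.

The alignment procedure isolates the contrast-enhanced lumen inside a
region of interest and reports the orientation of its central axis:

1. **Threshold** the ROI at an intensity separating iodinated lumen
   (typically 300-500 HU) from myocardium and fat (default 200 HU).
2. Keep the **largest connected component**, discarding bone fragments,
   calcifications and other bright structures clipped by the ROI.
3. Fit the component's **principal axis** by PCA of the voxel-center point
   cloud mapped to world millimetres (so anisotropic voxels are handled
   physically, not in index units).
4. Report the **tilt angle**: the acute elevation of that axis above the
   horizontal (axial) plane, ``arcsin(|axis_z|)`` in degrees.

The axis sign is normalized so its superior (world z) component is >= 0;
when that component is zero, the first nonzero component is made positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    AmbiguousAxisError,
    ContractViolationError,
    DegenerateComponentError,
    EmptySelectionError,
    GeometryError,
)
from .io_formats import Box3D, Volume, world_to_voxel

__all__ = [
    "Mask",
    "TiltResult",
    "TiltConfig",
    "threshold_mask",
    "largest_component",
    "principal_axis",
    "tilt_angle",
    "align_tilt",
]

_EIGENVALUE_TIE_TOL = 1e-9


@dataclass
class Mask:
    """Boolean subgrid anchored at ``offset`` inside its parent volume."""

    data: np.ndarray
    offset: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.offset = np.asarray(self.offset, dtype=int)
        self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class TiltResult:
    """Outcome of the alignment pipeline with full provenance.

    ``axis`` is a unit vector in world-mm orientation; ``angle_deg`` the
    acute tilt in [0, 90] degrees; ``threshold_used`` is recorded in the
    intensity space of the input volume.
    """

    axis: np.ndarray
    angle_deg: float
    component_voxels: int
    threshold_used: float
    centroid_mm: np.ndarray

    def to_dict(self) -> dict:
        return {
            "axis": [float(v) for v in self.axis],
            "angle_deg": float(self.angle_deg),
            "component_voxels": int(self.component_voxels),
            "threshold_used": float(self.threshold_used),
            "centroid_mm": [float(v) for v in self.centroid_mm],
        }


@dataclass
class TiltConfig:
    """Tunables of the alignment pipeline.

    threshold_hu
        Lumen/background separation in HU (default 200; ~0.598 after
        normalization, applied automatically for normalized volumes).
    connectivity
        Voxel neighborhood for component labeling: 6, 18 or 26.
    convention
        ``"elevation"``: angle = arcsin(|z|), rotation-invariant in the
        axial plane. ``"coronal_projection"``: arctan(|z| / |x|) on the
        (x, z) components, as measured on a coronal view.
    min_component_voxels
        Smallest component accepted as the lumen; suppresses specks.
    intensity_weighted
        Weight the PCA point cloud by voxel intensity instead of uniformly.
    """

    threshold_hu: float = 200.0
    connectivity: int = 26
    convention: str = "elevation"
    min_component_voxels: int = 50
    intensity_weighted: bool = False


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def threshold_mask(vol: Volume, roi: Box3D, threshold: float) -> Mask:
    """Binary mask of voxels >= ``threshold`` inside the rasterized ROI.

    The ROI (voxel space) is rasterized as ``floor(lo) .. ceil(hi)`` and
    clipped to the grid. An all-false mask is returned, not raised; only an
    ROI entirely outside the grid is a geometry error.
    """
    if roi.space != "voxel":
        raise ContractViolationError("threshold_mask expects a voxel-space ROI")
    shape = np.asarray(vol.shape)
    lo = np.maximum(np.floor(roi.lo).astype(int), 0)
    hi = np.minimum(np.ceil(roi.hi).astype(int), shape)
    if np.any(lo >= hi):
        raise GeometryError(
            f"ROI [{roi.lo}, {roi.hi}) does not intersect the {vol.shape} grid"
        )
    sub = vol.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return Mask(data=sub >= threshold, offset=lo, spacing=vol.spacing)


def largest_component(mask: Mask, connectivity: int = 26) -> Mask:
    """Keep only the largest connected component of a mask.

    Ties in voxel count are broken by the component containing the
    lexicographically smallest voxel index, which is deterministic.
    Raises :class:`EmptySelectionError` on an empty mask (the signal that
    the threshold was too high).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ContractViolationError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    if mask.voxel_count == 0:
        raise EmptySelectionError("mask is empty; threshold selected no voxels")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask.data, structure=structure)
    counts = np.bincount(labels.ravel())[1:]  # skip background label 0
    # ndimage assigns label ids in raster-scan order of first encounter, so the
    # smallest id among tied counts is the lexicographically-first component
    best = int(np.flatnonzero(counts == counts.max())[0]) + 1
    return Mask(data=labels == best, offset=mask.offset, spacing=mask.spacing)


def _component_points_mm(mask: Mask, affine: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask.data).astype(float)
    centers = idx + mask.offset + 0.5  # voxel centers in parent index space
    return centers @ np.asarray(affine, dtype=float)[:3, :3].T + affine[:3, 3]


def _sign_normalize(axis: np.ndarray) -> np.ndarray:
    if axis[2] != 0.0:
        return axis if axis[2] > 0 else -axis
    for v in axis:
        if v != 0.0:
            return axis if v > 0 else -axis
    return axis


def principal_axis(
    mask: Mask,
    affine: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Leading PCA eigenvector of the component's world-mm point cloud.

    Each true voxel contributes its center (index + 0.5) mapped through the
    affine. The returned unit vector has a non-negative superior (world z)
    component. Raises :class:`DegenerateComponentError` for < 3 voxels or a
    rank-0 cloud, and :class:`AmbiguousAxisError` when the two leading
    eigenvalues tie within 1e-9 — the axis is then not unique and is
    reported rather than guessed.
    """
    pts = _component_points_mm(mask, affine)
    if pts.shape[0] < 3:
        raise DegenerateComponentError(
            f"component has {pts.shape[0]} voxels; need >= 3 for axis estimation"
        )
    if weights is None:
        w = np.ones(pts.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != pts.shape[0] or np.any(w < 0) or w.sum() <= 0:
            raise ContractViolationError("weights must be nonnegative, one per voxel")
    mean = np.average(pts, axis=0, weights=w)
    centered = pts - mean
    cov = (centered * w[:, None]).T @ centered / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= _EIGENVALUE_TIE_TOL:
        raise DegenerateComponentError("point cloud has rank 0; no principal axis")
    if evals[-1] - evals[-2] <= _EIGENVALUE_TIE_TOL:
        raise AmbiguousAxisError(
            f"leading eigenvalues tie ({evals[-1]:.6g} vs {evals[-2]:.6g}); "
            "principal axis is not unique"
        )
    axis = evecs[:, -1]
    axis = axis / np.linalg.norm(axis)
    return _sign_normalize(axis)


def tilt_angle(axis: np.ndarray, convention: str = "elevation") -> float:
    """Acute angle (degrees, [0, 90]) between an axis and the horizontal plane.

    ``"elevation"`` is ``arcsin(|z|)``; ``"coronal_projection"`` is
    ``arctan(|z| / |x|)``, the angle seen after projecting onto the coronal
    (x-z) plane.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-6:
        if norm == 0:
            raise ContractViolationError("axis must be a nonzero unit vector")
        raise ContractViolationError(f"axis must be a unit vector, |axis| = {norm}")
    if convention == "elevation":
        return math.degrees(math.asin(min(abs(float(axis[2])), 1.0)))
    if convention == "coronal_projection":
        return math.degrees(math.atan2(abs(float(axis[2])), abs(float(axis[0]))))
    raise ContractViolationError(f"unknown angle convention {convention!r}")


def align_tilt(vol: Volume, roi: Box3D, config: TiltConfig | None = None) -> TiltResult:
    """Run the full alignment pipeline on one ROI.

    The configured HU threshold is mapped to the normalized scale when the
    volume has been normalized. Stage failures propagate with a ``stage``
    attribute naming the failing step (``"threshold"``, ``"component"``,
    ``"pca"``).
    """
    config = config or TiltConfig()
    if vol.intensity_space == "normalized":
        threshold = (config.threshold_hu + 1024.0) / 2048.0
    else:
        threshold = config.threshold_hu
    if roi.space == "world":
        roi = world_to_voxel(roi, vol.affine)

    mask = threshold_mask(vol, roi, threshold)
    try:
        component = largest_component(mask, connectivity=config.connectivity)
    except EmptySelectionError as exc:
        exc.threshold = threshold
        exc.stage = "threshold"
        raise
    if component.voxel_count < config.min_component_voxels:
        err = DegenerateComponentError(
            f"largest component has {component.voxel_count} voxels, below "
            f"min_component_voxels={config.min_component_voxels}",
            stage="component",
        )
        raise err

    weights = None
    if config.intensity_weighted:
        lo = component.offset
        hi = lo + np.asarray(component.data.shape)
        sub = vol.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        weights = np.asarray(sub[component.data], dtype=float)
        weights = np.clip(weights, 0.0, None)

    try:
        axis = principal_axis(component, vol.affine, weights=weights)
    except DegenerateComponentError as exc:
        exc.stage = "pca"
        raise

    pts = _component_points_mm(component, vol.affine)
    return TiltResult(
        axis=axis,
        angle_deg=tilt_angle(axis, convention=config.convention),
        component_voxels=component.voxel_count,
        threshold_used=float(threshold),
        centroid_mm=pts.mean(axis=0),
    )
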