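"""Volumes, 3D boxes and annotation files.

Conventions
-----------
* Voxel coordinates are 0-based; a :class:`Box3D` is half-open ``[lo, hi)``
  so adjacent boxes never share voxels and voxel-count arithmetic is exact.
* World space follows the NIfTI affine convention: the 4x4 ``affine`` maps a
  voxel index (column vector, homogeneous) to millimetres. Annotation tools
  differ on LPS vs RAS, so every serialized box carries an explicit ``space``
  tag and coordinate conversion re-sorts corners per axis, which keeps
  ``lo < hi`` valid even under axis-flipping (negative-determinant) affines.
* The ``center_size_txt`` dialect stores one box per line as
  ``label cz cx cy sz sx sy [confidence]`` with the six geometry numbers as
  fractions of the axis length, depth (grid z) first — the layout used by
  3D YOLO-style detectors. Note the (z, x, y) column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import ContractViolationError, FormatError

__all__ = [
    "Volume",
    "Box3D",
    "Detection",
    "AnnotationSet",
    "read_volume",
    "write_volume",
    "world_to_voxel",
    "voxel_to_world",
    "read_annotations",
    "write_annotations",
]

# the txt dialect stores geometry columns depth-first: file column -> array axis
_TXT_AXIS_ORDER = (2, 0, 1)


@dataclass
class Volume:
    """A 3D scalar grid plus the affine that places it in world millimetres.

    ``intensity_space`` is ``"hu"`` for raw Hounsfield units and
    ``"normalized"`` after the detector-style ``(v + 1024) / 2048`` map.
    """

    data: np.ndarray
    affine: np.ndarray
    intensity_space: str = "hu"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ContractViolationError(
                f"volume data must be 3D with positive extents, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ContractViolationError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ContractViolationError("affine must be invertible")
        if self.intensity_space not in ("hu", "normalized"):
            raise ContractViolationError(
                f"unknown intensity space {self.intensity_space!r}"
            )

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (norms of the affine's spatial columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class Box3D:
    """Axis-aligned half-open box ``[lo, hi)`` with an explicit coordinate-space tag."""

    lo: np.ndarray
    hi: np.ndarray
    space: str = "voxel"
    label: str = "aortic_root"

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.lo.shape != (3,) or self.hi.shape != (3,):
            raise ContractViolationError("box corners must be 3-vectors")
        if self.space not in ("voxel", "world"):
            raise ContractViolationError(f"unknown box space {self.space!r}")
        if not np.all(self.lo < self.hi):
            raise ContractViolationError(
                f"box must have strictly positive extent: lo={self.lo}, hi={self.hi}"
            )

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    @property
    def center(self) -> np.ndarray:
        return (self.lo + self.hi) / 2.0

    @property
    def size(self) -> np.ndarray:
        return self.hi - self.lo


@dataclass
class Detection:
    """A detector output: a box plus a confidence score in [0, 1]."""

    box: Box3D
    confidence: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ContractViolationError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )
        if self.label is None:
            self.label = self.box.label


@dataclass
class AnnotationSet:
    """Boxes (ground truth) or detections keyed by image id, with per-image affines."""

    boxes: dict[str, list] = field(default_factory=dict)
    affines: dict[str, np.ndarray] = field(default_factory=dict)

    def image_ids(self) -> list[str]:
        return list(self.boxes)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file (optionally gzipped) into a :class:`Volume`.

    The stored scaling (``scl_slope``/``scl_inter``) is applied, so the
    returned data are in the acquisition scale (Hounsfield units for CT).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ContractViolationError(
            f"{path} has {len(img.shape)} dimensions; expected a 3D volume"
        )
    data = np.asarray(img.get_fdata())  # get_fdata applies scl_slope/scl_inter
    return Volume(data=data, affine=np.asarray(img.affine), intensity_space="hu")


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as NIfTI-1 (gzipped when the suffix is .nii.gz)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory {path.parent} does not exist")
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def _apply_affine(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    out = pts @ affine[:3, :3].T + affine[:3, 3]
    return out


def _transform_box(box: Box3D, matrix: np.ndarray, new_space: str) -> Box3D:
    corners = _apply_affine(matrix, np.stack([box.lo, box.hi]))
    lo = np.minimum(corners[0], corners[1])  # re-sort per axis: flips allowed
    hi = np.maximum(corners[0], corners[1])
    return Box3D(lo=lo, hi=hi, space=new_space, label=box.label)


def world_to_voxel(point_or_box, affine: np.ndarray):
    """Map a world-mm point (3-vector) or ``Box3D`` to voxel indices.

    Box corners are transformed and re-sorted per axis so ``lo < hi`` holds
    even under axis-flipping affines. Raises
    :class:`~rootalign.errors.ContractViolationError` if a box is already in
    voxel space, and ``numpy.linalg.LinAlgError`` for a singular affine.
    """
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    if isinstance(point_or_box, Box3D):
        if point_or_box.space != "world":
            raise ContractViolationError("box is not in world space")
        return _transform_box(point_or_box, inv, "voxel")
    return _apply_affine(inv, point_or_box)[0]


def voxel_to_world(point_or_box, affine: np.ndarray):
    """Exact inverse of :func:`world_to_voxel`."""
    affine = np.asarray(affine, dtype=float)
    if isinstance(point_or_box, Box3D):
        if point_or_box.space != "voxel":
            raise ContractViolationError("box is not in voxel space")
        return _transform_box(point_or_box, affine, "world")
    return _apply_affine(affine, point_or_box)[0]


# ---------------------------------------------------------------------------
# Annotation files
# ---------------------------------------------------------------------------

def _box_to_json(obj) -> dict:
    det = obj if isinstance(obj, Detection) else None
    box = det.box if det is not None else obj
    rec = {
        "label": box.label,
        "lo": [float(v) for v in box.lo],
        "hi": [float(v) for v in box.hi],
        "space": box.space,
    }
    if det is not None:
        rec["confidence"] = float(det.confidence)
    return rec


def _box_from_json(rec: dict):
    box = Box3D(
        lo=np.asarray(rec["lo"], dtype=float),
        hi=np.asarray(rec["hi"], dtype=float),
        space=rec.get("space", "voxel"),
        label=rec.get("label", "aortic_root"),
    )
    if "confidence" in rec:
        return Detection(box=box, confidence=float(rec["confidence"]))
    return box


def read_annotations(
    path: str | Path,
    dialect: str = "json",
    image_shape: Sequence[int] | None = None,
) -> AnnotationSet:
    """Read box annotations.

    ``dialect="json"`` reads the corner-pair schema
    ``{"images": [{"id", "affine", "boxes": [...]}]}``; boxes with a
    ``confidence`` field come back as :class:`Detection`.

    ``dialect="center_size_txt"`` reads one box per line as
    ``label cz cx cy sz sx sy [confidence]`` where centers and sizes are
    fractions of the axis length in (z, x, y) column order; ``image_shape``
    (in voxels) is required to scale them. The voxel-space corners are
    ``lo = (c - s/2)·shape`` and ``hi = (c + s/2)·shape``.
    """
    path = Path(path)
    if dialect == "json":
        payload = json.loads(path.read_text())
        out = AnnotationSet()
        for image in payload["images"]:
            image_id = str(image["id"])
            out.boxes[image_id] = [_box_from_json(r) for r in image.get("boxes", [])]
            if image.get("affine") is not None:
                out.affines[image_id] = np.asarray(image["affine"], dtype=float)
        return out

    if dialect == "center_size_txt":
        if image_shape is None:
            raise ContractViolationError(
                "image_shape is required for the center_size_txt dialect"
            )
        shape = np.asarray(image_shape, dtype=float)
        boxes: list = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (7, 8):
                raise FormatError(
                    f"expected 7 or 8 whitespace-separated fields, got {len(parts)}",
                    line=lineno,
                )
            label = parts[0]
            vals = [float(v) for v in parts[1:7]]
            centers_txt, sizes_txt = vals[:3], vals[3:]
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise FormatError("fractions must lie in [0, 1]", line=lineno)
            if any(s <= 0 for s in sizes_txt):
                raise FormatError("box sizes must be strictly positive", line=lineno)
            center = np.empty(3)
            size = np.empty(3)
            for col, axis in enumerate(_TXT_AXIS_ORDER):
                center[axis] = centers_txt[col]
                size[axis] = sizes_txt[col]
            box = Box3D(
                lo=(center - size / 2) * shape,
                hi=(center + size / 2) * shape,
                space="voxel",
                label=label,
            )
            if len(parts) == 8:
                boxes.append(Detection(box=box, confidence=float(parts[7])))
            else:
                boxes.append(box)
        out = AnnotationSet()
        out.boxes["0"] = boxes
        return out

    raise ContractViolationError(f"unknown annotation dialect {dialect!r}")


def write_annotations(
    annotations: AnnotationSet,
    path: str | Path,
    dialect: str = "json",
    image_shape: Sequence[int] | None = None,
) -> None:
    """Write annotations in the JSON or center-size text dialect.

    The text dialect holds a single image's boxes and requires
    ``image_shape`` to express corners as axis fractions.
    """
    path = Path(path)
    if dialect == "json":
        images = []
        for image_id, boxes in annotations.boxes.items():
            rec: dict = {"id": image_id, "boxes": [_box_to_json(b) for b in boxes]}
            if image_id in annotations.affines:
                rec["affine"] = [
                    [float(v) for v in row] for row in annotations.affines[image_id]
                ]
            else:
                rec["affine"] = None
            images.append(rec)
        path.write_text(json.dumps({"images": images}, indent=2))
        return

    if dialect == "center_size_txt":
        if image_shape is None:
            raise ContractViolationError(
                "image_shape is required for the center_size_txt dialect"
            )
        if len(annotations.boxes) != 1:
            raise ContractViolationError(
                "center_size_txt holds a single image's boxes"
            )
        shape = np.asarray(image_shape, dtype=float)
        lines = []
        (boxes,) = annotations.boxes.values()
        for obj in boxes:
            det = obj if isinstance(obj, Detection) else None
            box = det.box if det is not None else obj
            center = box.center / shape
            size = box.size / shape
            fields = [box.label]
            fields += [f"{center[a]:.9f}" for a in _TXT_AXIS_ORDER]
            fields += [f"{size[a]:.9f}" for a in _TXT_AXIS_ORDER]
            if det is not None:
                fields.append(f"{det.confidence:.9f}")
            lines.append(" ".join(fields))
        path.write_text("\n".join(lines) + "\n")
        return

    raise ContractViolationError(f"unknown annotation dialect {dialect!r}")
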