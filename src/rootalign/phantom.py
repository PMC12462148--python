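"""Synthetic contrast-enhanced cardiac-CT phantoms with known ground truth.

Each phantom is a capsule-capped tube of contrast-attenuating "lumen"
(default 400 HU) with a thin wall shell (default 80 HU) inside a background
volume, tilted at a prescribed angle to the axial plane. The generating
angle, axis and a tight world-space box around the tube are returned as
ground truth, so the detection and tilt-alignment stages can be validated
end to end without patient data or trained weights.

The tube is deliberately a straight capsule, not anatomy: it tests the
algorithmic contract (threshold -> largest component -> PCA -> angle), and a
hemispherical cap avoids the PCA edge artifacts a flat-cut cylinder would
introduce. A mild ``curvature_radius_mm`` option bends the centerline into a
circular arc to probe the systematic bias that a curved vessel induces in an
axis fitted to the whole lumen.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ContractViolationError, GeometryError
from .io_formats import AnnotationSet, Box3D, Volume, write_annotations, write_volume
from .tilt import tilt_angle

__all__ = ["Distractor", "PhantomSpec", "PhantomTruth", "make_phantom", "make_cohort"]


@dataclass
class Distractor:
    """A bright confounder stamped after the tube.

    ``sphere``: ball of radius ``size_mm``. ``rod``: grid-z-aligned cylinder
    of radius ``size_mm / 2`` and length ``4 * size_mm``.
    """

    kind: str
    center_mm: tuple[float, float, float]
    size_mm: float
    hu: float


@dataclass
class PhantomSpec:
    """Generating parameters of one phantom.

    The tube axis points at ``tube_angle_deg`` elevation above the axial
    plane, rotated ``tube_azimuth_deg`` within it; ``tube_length_mm`` is the
    end-to-end length including the hemispherical caps. ``noise_sd_hu`` adds
    seeded Gaussian noise after geometry; ``partial_volume`` smooths the
    tube boundary over one voxel, emulating CT partial-volume averaging.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tube_angle_deg: float = 50.0
    tube_azimuth_deg: float = 0.0
    tube_radius_mm: float = 10.0
    tube_length_mm: float = 80.0
    wall_thickness_mm: float = 2.0
    lumen_hu: float = 400.0
    wall_hu: float = 80.0
    background_hu: float = 0.0
    noise_sd_hu: float = 0.0
    partial_volume: bool = True
    curvature_radius_mm: float | None = None
    distractors: list[Distractor] = field(default_factory=list)
    seed: int = 0


@dataclass
class PhantomTruth:
    """Analytic ground truth: tight world-mm ROI box, unit axis, tilt angle."""

    roi_box: Box3D
    axis: np.ndarray
    angle_deg: float
    lumen_voxels: int


def _axis_from_angles(angle_deg: float, azimuth_deg: float) -> np.ndarray:
    theta = math.radians(angle_deg)
    phi = math.radians(azimuth_deg)
    return np.array(
        [math.cos(theta) * math.cos(phi), math.cos(theta) * math.sin(phi), math.sin(theta)]
    )


def _centered_affine(shape, spacing) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    # voxel-center grid centered on world origin
    affine[:3, 3] = -(np.asarray(shape, dtype=float) / 2.0 - 0.5) * np.asarray(spacing)
    return affine


def _segment_distance(pts: np.ndarray, center: np.ndarray, direction: np.ndarray, half: float) -> np.ndarray:
    rel = pts - center
    t = np.clip(rel @ direction, -half, half)
    return np.linalg.norm(rel - t[:, None] * direction, axis=1)


def _arc_distance(pts: np.ndarray, center: np.ndarray, direction: np.ndarray, half: float, radius: float) -> np.ndarray:
    """Distance to a circular-arc centerline approximated by a fine polyline."""
    # the arc lies in the plane spanned by `direction` and a perpendicular
    # chosen to bend within the vertical plane containing the axis
    perp = np.array([0.0, 0.0, 1.0]) - direction * direction[2]
    if np.linalg.norm(perp) < 1e-9:  # vertical tube: bend toward +x
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    arc_half = half / radius  # radians subtended by each half
    ts = np.linspace(-arc_half, arc_half, 65)
    arc_center = center + radius * perp
    nodes = arc_center + radius * (
        -np.cos(ts)[:, None] * perp + np.sin(ts)[:, None] * direction
    )
    best = np.full(pts.shape[0], np.inf)
    for a, b in zip(nodes[:-1], nodes[1:]):
        mid, d = (a + b) / 2.0, b - a
        length = np.linalg.norm(d)
        np.minimum(best, _segment_distance(pts, mid, d / length, length / 2.0), out=best)
    return best


def make_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Render a phantom volume and its analytic ground truth.

    The capsule is centered in the grid. Intensity is composed as
    background, overridden by wall inside ``radius + wall_thickness`` of the
    centerline and by lumen inside ``radius``; with ``partial_volume`` the
    two boundaries fade linearly over one voxel. Gaussian noise (seeded) and
    distractors are added afterwards, so the same spec and seed reproduce
    the volume bit for bit.
    """
    if not (0.0 < spec.tube_angle_deg <= 90.0):
        raise ContractViolationError("tube_angle_deg must lie in (0, 90]")
    shape = np.asarray(spec.shape, dtype=int)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    affine = _centered_affine(shape, spacing)
    direction = _axis_from_angles(spec.tube_angle_deg, spec.tube_azimuth_deg)

    r_out = spec.tube_radius_mm + spec.wall_thickness_mm
    half = spec.tube_length_mm / 2.0 - r_out  # centerline half-length of the capsule
    if half <= 0:
        raise ContractViolationError("tube_length_mm must exceed its diameter with wall")
    extent = np.abs(direction) * half + r_out
    if np.any(2 * extent > shape * spacing):
        raise GeometryError(
            f"tube bounding box {2 * extent} mm exceeds volume {shape * spacing} mm"
        )

    ii = [np.arange(n, dtype=float) for n in shape]
    grid = np.meshgrid(*ii, indexing="ij")
    pts = np.stack([g.ravel() for g in grid], axis=1) @ affine[:3, :3].T + affine[:3, 3]

    center = np.zeros(3)
    if spec.curvature_radius_mm is not None:
        dist = _arc_distance(pts, center, direction, half, spec.curvature_radius_mm)
    else:
        dist = _segment_distance(pts, center, direction, half)

    voxel = float(spacing.min())
    if spec.partial_volume:
        f_outer = np.clip((r_out + voxel / 2.0 - dist) / voxel, 0.0, 1.0)
        f_inner = np.clip((spec.tube_radius_mm + voxel / 2.0 - dist) / voxel, 0.0, 1.0)
    else:
        f_outer = (dist <= r_out).astype(float)
        f_inner = (dist <= spec.tube_radius_mm).astype(float)
    data = (
        spec.background_hu
        + (spec.wall_hu - spec.background_hu) * f_outer
        + (spec.lumen_hu - spec.wall_hu) * f_inner
    )
    lumen_voxels = int(np.sum(f_inner >= 0.5))

    for d in spec.distractors:
        c = np.asarray(d.center_mm, dtype=float)
        if d.kind == "sphere":
            inside = np.linalg.norm(pts - c, axis=1) <= d.size_mm
        elif d.kind == "rod":
            inside = _segment_distance(pts, c, np.array([0.0, 0.0, 1.0]), 2.0 * d.size_mm) <= d.size_mm / 2.0
        else:
            raise ContractViolationError(f"unknown distractor kind {d.kind!r}")
        data[inside] = d.hu

    data = data.reshape(tuple(shape))
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd_hu, size=data.shape)

    axis = direction if direction[2] >= 0 else -direction
    truth = PhantomTruth(
        roi_box=Box3D(lo=center - extent, hi=center + extent, space="world"),
        axis=axis,
        angle_deg=spec.tube_angle_deg,
        lumen_voxels=lumen_voxels,
    )
    assert abs(tilt_angle(axis) - spec.tube_angle_deg) < 1e-9
    return Volume(data=data, affine=affine, intensity_space="hu"), truth


def make_cohort(
    n: int,
    angle_range: tuple[float, float],
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[tuple[str, Volume, PhantomTruth]]:
    """Generate ``n`` phantoms with angles evenly spaced over ``angle_range``.

    Per-phantom seeds are derived deterministically from the master seed, so
    regenerating a cohort with the same seed reproduces identical volumes.
    When ``out_dir`` is given, each volume is written as
    ``phantom_XXX.nii.gz`` together with ``annotations.json`` (truth boxes in
    world mm) and ``truth.csv`` (id, angle, axis, lumen voxel count).
    Returns ``(image_id, volume, truth)`` triples either way.
    """
    lo, hi = angle_range
    if n < 1 or not (0.0 < lo <= hi <= 90.0):
        raise ContractViolationError("need n >= 1 and 0 < lo <= hi <= 90 degrees")
    base_spec = base_spec or PhantomSpec()
    angles = np.linspace(lo, hi, n)
    children = np.random.SeedSequence(seed).spawn(n)

    cohort = []
    truth_ann = AnnotationSet()
    for i, angle in enumerate(angles):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        spec = replace(base_spec, tube_angle_deg=float(angle), seed=child_seed)
        vol, truth = make_phantom(spec)
        image_id = f"phantom_{i:03d}"
        cohort.append((image_id, vol, truth))
        truth_ann.boxes[image_id] = [truth.roi_box]
        truth_ann.affines[image_id] = vol.affine

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for image_id, vol, _ in cohort:
            write_volume(vol, out_dir / f"{image_id}.nii.gz")
        write_annotations(truth_ann, out_dir / "annotations.json", dialect="json")
        with open(out_dir / "truth.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["image_id", "angle_deg", "axis_x", "axis_y", "axis_z", "lumen_voxels"]
            )
            for image_id, _, truth in cohort:
                writer.writerow(
                    [image_id, f"{truth.angle_deg:.6f}"]
                    + [f"{v:.9f}" for v in truth.axis]
                    + [truth.lumen_voxels]
                )
    return cohort
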