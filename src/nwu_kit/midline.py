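"""Midline-plane estimation, hemisphere splitting, mask mirroring, and
rigid CT-to-CT registration.

The midline is modeled as a single plane estimated by reflective symmetry:
the plane for which the brain image best matches its own mirror image
(normalized cross-correlation inside the brain mask), searched over axial
rotation, in-plane rotation, and lateral offset from the mid-sagittal grid
plane. An atlas with a delineated midline can be substituted by any caller
that already has one — every downstream operation takes a ``MidlinePlane``,
not an estimation method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, optimize

from .ct_io import CTVolume, VoxelMask, HU_MIN
from .errors import InputError, PipelineError

__all__ = [
    "MidlinePlane",
    "RigidTransform",
    "estimate_midline",
    "split_hemispheres",
    "mirror_mask",
    "register_rigid",
    "resample_volume",
    "resample_mask",
    "extract_brain_mask",
]


@dataclass
class MidlinePlane:
    """A plane in physical (mm) space: a point on it and a unit normal."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    warning: str | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise InputError("midline normal must be nonzero")
        self.normal = tuple(n / norm)
        self.point = tuple(float(p) for p in self.point)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.point)) @ np.asarray(self.normal)

    def reflect(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = self.signed_distance(pts)
        return pts - 2.0 * d[:, None] * np.asarray(self.normal)


@dataclass
class RigidTransform:
    """Rigid map of physical points from the fixed to the moving frame.

    ``p_moving = rotation @ p_fixed + translation`` — the resampling
    convention: to fill a fixed-grid voxel, look up the moving image there.
    """

    rotation: np.ndarray
    translation: np.ndarray
    warning: str | None = None

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-5):
            raise InputError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-5):
            raise InputError("rotation must be proper (det +1)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "convention": "p_moving = R @ p_fixed + t (mm, fixed-grid resampling)",
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["rotation"]), np.asarray(payload["translation"]))


def _normal_from_angles(theta_z_deg: float, theta_y_deg: float) -> np.ndarray:
    tz, ty = np.deg2rad(theta_z_deg), np.deg2rad(theta_y_deg)
    rz = np.array([[np.cos(tz), -np.sin(tz), 0], [np.sin(tz), np.cos(tz), 0], [0, 0, 1]])
    ry = np.array([[np.cos(ty), 0, np.sin(ty)], [0, 1, 0], [-np.sin(ty), 0, np.cos(ty)]])
    return rz @ ry @ np.array([1.0, 0.0, 0.0])


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_midline(
    volume: CTVolume,
    brain_mask: VoxelMask,
    max_offset_mm: float = 10.0,
    max_angle_deg: float = 12.0,
    n_samples: int = 12000,
    seed: int = 0,
) -> MidlinePlane:
    """Estimate the mid-sagittal plane by reflective symmetry.

    A coarse grid over axial rotation and lateral offset initializes a
    Powell refinement over (offset, axial rotation, in-plane rotation). The
    objective is the normalized cross-correlation between brain-voxel
    intensities and the trilinearly sampled intensities at their mirror
    points. If optimization cannot improve on the mid-sagittal grid plane,
    that initialization is returned with ``warning`` set.
    """
    if brain_mask.count() == 0:
        raise InputError("brain_mask is empty")
    rng = np.random.default_rng(seed)
    idxs = np.argwhere(brain_mask.voxels)
    if idxs.shape[0] > n_samples:
        idxs = idxs[rng.choice(idxs.shape[0], n_samples, replace=False)]
    pts = volume.index_to_physical(idxs)
    vals = volume.voxels[tuple(idxs.T)].astype(np.float64)
    center = volume.index_to_physical(np.argwhere(brain_mask.voxels)).mean(axis=0)
    spacing = np.asarray(volume.spacing)

    def cost(params: np.ndarray) -> float:
        off, tz, ty = params
        normal = _normal_from_angles(tz, ty)
        plane = MidlinePlane(tuple(center + off * normal), tuple(normal))
        refl = plane.reflect(pts)
        frac = (refl - np.asarray(volume.origin)) / spacing
        sampled = ndimage.map_coordinates(
            volume.voxels, frac.T, order=1, mode="constant", cval=HU_MIN
        )
        return -_ncc(vals, sampled)

    best_p = np.zeros(3)
    best_c = cost(best_p)
    init_c = best_c
    for tz in np.arange(-max_angle_deg, max_angle_deg + 0.1, 2.0):
        for off in np.arange(-max_offset_mm, max_offset_mm + 0.1, 2.0):
            c = cost(np.array([off, tz, 0.0]))
            if c < best_c:
                best_c, best_p = c, np.array([off, tz, 0.0])
    res = optimize.minimize(
        cost, best_p, method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": 400},
    )
    if res.fun < best_c:
        best_c, best_p = res.fun, res.x
    warning = None
    if best_c >= init_c - 1e-12 and not np.allclose(best_p, 0.0):
        best_p, warning = np.zeros(3), "optimizer failed to improve on initialization"
    off, tz, ty = best_p
    normal = _normal_from_angles(tz, ty)
    return MidlinePlane(tuple(center + off * normal), tuple(normal), warning=warning)


def split_hemispheres(
    brain_mask: VoxelMask, plane: MidlinePlane
) -> tuple[VoxelMask, VoxelMask]:
    """Partition a brain mask into (left, right) by signed plane distance.

    Voxels within half a voxel of the plane belong to neither hemisphere.
    "Left" is the negative side of the plane normal (which points toward
    the patient's right in canonical orientation).
    """
    idxs = np.argwhere(brain_mask.voxels)
    left = np.zeros(brain_mask.shape, dtype=np.uint8)
    right = np.zeros(brain_mask.shape, dtype=np.uint8)
    if idxs.size:
        pts = brain_mask.index_to_physical(idxs)
        d = plane.signed_distance(pts)
        half = 0.5 * float(
            np.abs(np.asarray(plane.normal)) @ np.asarray(brain_mask.spacing)
        )
        left[tuple(idxs[d < -half].T)] = 1
        right[tuple(idxs[d > half].T)] = 1
    return (
        VoxelMask(left, brain_mask.spacing, brain_mask.origin),
        VoxelMask(right, brain_mask.spacing, brain_mask.origin),
    )


def mirror_mask(mask: VoxelMask, plane: MidlinePlane) -> VoxelMask:
    """Reflect a mask across the midline plane (nearest-neighbor).

    Each inside-voxel's physical center is reflected and snapped to the
    nearest voxel. Reflected points outside the grid are dropped; clipping
    to the brain is deliberately left to the caller so mirroring stays a
    pure geometric operation.
    """
    idxs = np.argwhere(mask.voxels)
    out = np.zeros(mask.shape, dtype=np.uint8)
    if idxs.size == 0:
        return VoxelMask(out, mask.spacing, mask.origin)
    refl = plane.reflect(mask.index_to_physical(idxs))
    tgt = np.rint(mask.physical_to_index(refl)).astype(int)
    inside = np.all((tgt >= 0) & (tgt < np.asarray(mask.shape)), axis=1)
    if not inside.any():
        raise PipelineError("reflected region falls entirely outside the grid")
    out[tuple(tgt[inside].T)] = 1
    return VoxelMask(out, mask.spacing, mask.origin)


def _to_sitk(volume: CTVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.T))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    return img


def register_rigid(
    moving: CTVolume,
    fixed: CTVolume,
    seed: int = 0,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Mattes mutual information with a multi-resolution gradient-descent
    search over the 6 rigid parameters — robust for CT-to-CT even with
    contrast differences between CTP source frames and NCCT. If the final
    similarity is no better than the centered initialization, that
    initialization is returned with a warning.
    """
    f_img = sitk.Cast(_to_sitk(fixed), sitk.sitkFloat32)
    m_img = sitk.Cast(_to_sitk(moving), sitk.sitkFloat32)
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    # explicit seed: REGULAR sampling jitters sample positions randomly,
    # and an unseeded jitter makes registration runs non-reproducible
    reg.SetMetricSamplingPercentage(0.25, seed + 1)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(sitk.Euler3DTransform(initial), inPlace=False)

    final = reg.Execute(f_img, m_img)
    warning = None
    init_metric = sitk.ImageRegistrationMethod()
    init_metric.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    init_metric.SetInterpolator(sitk.sitkLinear)
    init_metric.SetInitialTransform(initial, inPlace=False)
    try:
        before = init_metric.MetricEvaluate(f_img, m_img)
        after = reg.GetMetricValue()
        if after >= before:
            final, warning = initial, "registration did not improve on initialization"
    except RuntimeError:  # pragma: no cover - metric evaluation edge cases
        pass

    euler = sitk.Euler3DTransform()
    euler.SetFixedParameters(final.GetFixedParameters())
    euler.SetParameters(final.GetParameters())
    rot = np.asarray(euler.GetMatrix()).reshape(3, 3)
    c = np.asarray(euler.GetCenter())
    t = np.asarray(euler.GetTranslation())
    # sitk: p_m = R (p_f - c) + c + t  ->  translation_eff = c + t - R c
    return RigidTransform(rot, c + t - rot @ c, warning=warning)


def _resample(
    data: np.ndarray,
    source: CTVolume | VoxelMask,
    fixed: CTVolume,
    transform: RigidTransform,
    order: int,
    cval: float,
) -> np.ndarray:
    idx = np.indices(fixed.shape, dtype=np.float64).reshape(3, -1).T
    pts_f = fixed.index_to_physical(idx)
    pts_m = pts_f @ transform.rotation.T + transform.translation
    frac = (pts_m - np.asarray(source.origin)) / np.asarray(source.spacing)
    out = ndimage.map_coordinates(
        data.astype(np.float64), frac.T, order=order, mode="constant", cval=cval
    )
    return out.reshape(fixed.shape)


def resample_volume(
    moving: CTVolume, fixed: CTVolume, transform: RigidTransform
) -> CTVolume:
    """Resample a volume onto the fixed grid (trilinear, preserves densitometry)."""
    out = _resample(moving.voxels, moving, fixed, transform, order=1, cval=HU_MIN)
    return CTVolume(out.astype(np.float32), fixed.spacing, fixed.origin)


def resample_mask(
    mask: VoxelMask, fixed: CTVolume, transform: RigidTransform
) -> VoxelMask:
    """Resample a mask onto the fixed grid (nearest-neighbor, preserves binarity)."""
    out = _resample(mask.voxels, mask, fixed, transform, order=0, cval=0.0)
    return VoxelMask((out > 0.5).astype(np.uint8), fixed.spacing, fixed.origin)


def extract_brain_mask(
    volume: CTVolume,
    hu_low: float = 0.0,
    hu_high: float = 80.0,
    min_volume_ml: float = 100.0,
) -> VoxelMask:
    """Simple HU/morphology brain extraction inside the skull shell.

    Soft tissue and CSF fall in [0, 80] HU while air and bone do not, so the
    brain is the largest connected component of that window, hole-filled.
    Not a substitute for dedicated skull stripping on real scans with neck
    coverage, but adequate for head-centered volumes.
    """
    cand = (volume.voxels >= hu_low) & (volume.voxels <= hu_high)
    cand = ndimage.binary_opening(cand, structure=np.ones((3, 3, 3)))
    labels, n = ndimage.label(cand)
    if n == 0:
        raise PipelineError("no brain-range tissue found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] * volume.voxel_volume_mm3 / 1000.0 < min_volume_ml:
        raise PipelineError("largest soft-tissue component is too small to be a brain")
    brain = ndimage.binary_fill_holes(labels == largest)
    return VoxelMask.on_grid(brain, volume)
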