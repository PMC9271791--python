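"""Synthetic head-CT phantom with known water uptake.

The phantom is the test oracle for the whole pipeline: an ellipsoidal brain
inside a hyperdense skull shell on an air background, with ventricular and
sulcal CSF compartments, and a unilateral ellipsoidal infarct whose voxel
densities are the contralateral tissue draws scaled by ``(1 - w)``, where
``w`` is the true water-uptake fraction. Because the uptake is imposed by
construction, the pipeline's NWU estimate can be compared against
``100 * w`` exactly. Optional ingredients emulate the confounders the
measurement must survive: hyperdense hemorrhagic-transformation foci, head
tilt, and scanner noise. A companion generator produces a 4D CT-perfusion
series by convolving a gamma-variate arterial input function with
exponential residue functions, with reduced flow and added delay inside the
infarct core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, VoxelMask, HU_MIN, HU_MAX
from .ctp import CTPSeries
from .errors import InputError
from .midline import MidlinePlane

__all__ = ["PhantomSpec", "PhantomBundle", "CTPBundle", "make_phantom", "make_ctp_series"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head.

    Defaults describe a plausible subacute stroke head CT: grey/white
    parenchyma around 38 HU with 2 HU tissue heterogeneity, CSF around 8 HU,
    a 50 ml left-hemisphere infarct, and 2 HU scanner noise.
    """

    shape: tuple[int, int, int] = (72, 88, 32)
    spacing: tuple[float, float, float] = (2.5, 2.5, 5.0)
    tissue_hu_mean: float = 38.0
    tissue_hu_sd: float = 2.0
    csf_hu_mean: float = 8.0
    csf_hu_sd: float = 3.0
    uptake_fraction: float = 0.25
    infarct_volume_ml: float = 50.0
    ht_fraction: float = 0.0
    ht_hu_range: tuple[float, float] = (50.0, 80.0)
    tilt_deg: float = 0.0
    noise_sd: float = 2.0
    infarct_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.uptake_fraction < 1.0):
            raise InputError("uptake_fraction must lie in [0, 1)")
        if not (0.0 <= self.ht_fraction < 1.0):
            raise InputError("ht_fraction must lie in [0, 1)")
        if self.tissue_hu_sd < 0 or self.csf_hu_sd < 0 or self.noise_sd < 0:
            raise InputError("standard deviations must be >= 0")
        if self.infarct_side not in ("left", "right"):
            raise InputError("infarct_side must be 'left' or 'right'")


@dataclass
class PhantomBundle:
    """A generated phantom with every ground-truth object the tests need."""

    ncct: CTVolume
    brain_mask: VoxelMask
    csf_mask: VoxelMask
    infarct_mask: VoxelMask
    ht_mask: VoxelMask
    true_nwu_percent: float
    midline_truth: MidlinePlane
    spec: PhantomSpec


def _ellipsoid_r2(coords, center, semi):
    """Normalized squared ellipsoid radius field (<= 1 is inside)."""
    r2 = np.zeros(coords[0].shape, dtype=np.float64)
    for c, c0, a in zip(coords, center, semi):
        r2 += ((c - c0) / a) ** 2
    return r2


def _rotate_z(arr: np.ndarray, deg: float, order: int, cval: float) -> np.ndarray:
    # rotation about the inferior-superior (z) axis = in the (x, y) plane
    return ndimage.rotate(
        arr, deg, axes=(0, 1), reshape=False, order=order, cval=cval, prefilter=False
    )


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the phantom described by ``spec``.

    The density image is assembled as label-wise anatomical means (air
    -1024, skull 700, tissue, CSF), blurred with a 1.5 mm Gaussian to emulate
    partial-volume averaging, after which the infarct's density deficit
    factor ``(1 - w)`` is applied, and per-voxel tissue/CSF heterogeneity,
    HT replacement draws, and scanner noise are added. Masks and image are
    finally rotated together by ``tilt_deg`` about the image-center
    inferior-superior axis.

    Raises
    ------
    InputError
        If the requested infarct does not fit inside one hemisphere.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    w = float(spec.uptake_fraction)

    # physical coordinate fields (mm, voxel centers, origin at voxel 0)
    idx = np.indices(shape, dtype=np.float64)
    coords = [idx[i] * spacing[i] for i in range(3)]
    fov = np.array(shape) * spacing
    center = fov / 2.0 - spacing / 2.0

    brain_semi = 0.36 * fov  # leaves room for the skull shell inside the FOV
    r2_brain = _ellipsoid_r2(coords, center, brain_semi)
    brain = r2_brain <= 1.0
    skull = (r2_brain > 1.0) & (_ellipsoid_r2(coords, center, brain_semi + 6.0) <= 1.0)

    # lateral ventricles: paired paramedian ellipsoids (generous, as in the
    # atrophic brains of a stroke-age cohort)
    vent_semi = (10.0, 26.0, 22.0)
    vent = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        c = (center[0] + side * 13.0, center[1] + 4.0, center[2])
        vent |= _ellipsoid_r2(coords, c, vent_semi) <= 1.0
    # sulcal CSF: the superior interhemispheric fissure
    sulcal = (
        (np.abs(coords[0] - center[0]) <= 2.6)
        & brain
        & (r2_brain < 0.97)
        & (coords[2] > center[2])
    )
    csf = (vent | sulcal) & brain

    # infarct: ellipsoid in the requested hemisphere, clear of the ventricles
    sgn = -1.0 if spec.infarct_side == "left" else 1.0
    s = (3.0 * spec.infarct_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    inf_semi = (0.85 * s, 1.2 * s, 0.98 * s)
    inf_center = (
        center[0] + sgn * 0.54 * brain_semi[0],
        center[1] - 8.0,
        center[2] - 5.0,
    )
    inf_ideal = _ellipsoid_r2(coords, inf_center, inf_semi) <= 1.0
    infarct = inf_ideal & brain & ~csf
    if sgn < 0:
        infarct &= coords[0] < center[0] - 0.51 * spacing[0]
    else:
        infarct &= coords[0] > center[0] + 0.51 * spacing[0]
    if inf_ideal.sum() == 0 or infarct.sum() < 0.9 * inf_ideal.sum():
        raise InputError(
            f"infarct_volume_ml={spec.infarct_volume_ml} does not fit inside the "
            f"{spec.infarct_side} hemisphere of this phantom"
        )

    # label-wise anatomical means, then partial-volume blur (2 mm physical
    # sigma, about one in-plane voxel); the uptake itself is applied after
    # the blur as a multiplicative density deficit with a sharp lesion edge
    # so that the mean density over the ground-truth mask is exactly
    # (1 - w) x the homologous tissue mean — the construction oracle.
    mean_img = np.full(shape, HU_MIN, dtype=np.float64)
    mean_img[skull] = 700.0
    mean_img[brain] = spec.tissue_hu_mean
    mean_img[csf] = spec.csf_hu_mean
    # 1.5 mm sigma approximates a soft CT reconstruction kernel; a PSF
    # expressed in voxels would be anisotropic (5 mm axially) and unphysical
    mean_img = ndimage.gaussian_filter(mean_img, sigma=1.5 / spacing)
    mean_img[infarct] *= 1.0 - w

    # per-voxel heterogeneity: infarct draws are tissue draws scaled by (1 - w)
    img = mean_img.copy()
    tissue_only = brain & ~csf & ~infarct
    img[tissue_only] += rng.normal(0.0, spec.tissue_hu_sd, int(tissue_only.sum()))
    img[infarct] += (1.0 - w) * rng.normal(0.0, spec.tissue_hu_sd, int(infarct.sum()))
    img[csf] += rng.normal(0.0, spec.csf_hu_sd, int(csf.sum()))

    # hemorrhagic transformation: replace a random subset of infarct voxels
    ht = np.zeros(shape, dtype=bool)
    if spec.ht_fraction > 0:
        inf_idx = np.flatnonzero(infarct.ravel())
        n_ht = int(round(spec.ht_fraction * inf_idx.size))
        chosen = rng.choice(inf_idx, size=n_ht, replace=False)
        ht.ravel()[chosen] = True
        img.ravel()[chosen] = rng.uniform(*spec.ht_hu_range, n_ht)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, shape)

    normal = np.array([1.0, 0.0, 0.0])
    if spec.tilt_deg != 0.0:
        img = _rotate_z(img, spec.tilt_deg, order=1, cval=HU_MIN)
        brain = _rotate_z(brain.astype(np.uint8), spec.tilt_deg, 0, 0).astype(bool)
        csf = _rotate_z(csf.astype(np.uint8), spec.tilt_deg, 0, 0).astype(bool)
        infarct = _rotate_z(infarct.astype(np.uint8), spec.tilt_deg, 0, 0).astype(bool)
        ht = _rotate_z(ht.astype(np.uint8), spec.tilt_deg, 0, 0).astype(bool)
        # ndimage.rotate(angle, axes=(0, 1)) rotates content such that the
        # midline normal turns by +tilt about the z axis in world space
        t = np.deg2rad(spec.tilt_deg)
        normal = np.array([np.cos(t), np.sin(t), 0.0])

    img = np.clip(img, HU_MIN, HU_MAX)
    ncct = CTVolume(img.astype(np.float32), tuple(spacing))
    plane = MidlinePlane(point=tuple(center), normal=tuple(normal))
    return PhantomBundle(
        ncct=ncct,
        brain_mask=VoxelMask.on_grid(brain, ncct),
        csf_mask=VoxelMask.on_grid(csf, ncct),
        infarct_mask=VoxelMask.on_grid(infarct, ncct),
        ht_mask=VoxelMask.on_grid(ht, ncct),
        true_nwu_percent=100.0 * w,
        midline_truth=plane,
        spec=spec,
    )


# Gamma-variate AIF shape (bolus arrival 8 s, 4 s rise, shape 3); the exact
# shape is a free modeling choice — only its convolution structure matters.
AIF_T0_S = 8.0
AIF_TPEAK_S = 4.0
AIF_ALPHA = 3.0
AIF_PEAK_HU = 200.0


def gamma_variate_aif(times: np.ndarray, peak_hu: float = AIF_PEAK_HU) -> np.ndarray:
    dt = np.maximum(np.asarray(times, dtype=float) - AIF_T0_S, 0.0) / AIF_TPEAK_S
    return peak_hu * (dt**AIF_ALPHA) * np.exp(AIF_ALPHA * (1.0 - dt))


@dataclass
class CTPBundle:
    """Forward-modeled CTP series with its construction ground truth."""

    series: CTPSeries
    cbf_truth: np.ndarray
    tmax_truth: np.ndarray
    vessel_mask: VoxelMask
    aif_truth: np.ndarray


def make_ctp_series(
    bundle: PhantomBundle,
    cbf_normal: float = 60.0,
    cbf_core_ratio: float = 0.2,
    mtt_s: float = 4.0,
    delay_core_s: float = 6.0,
    time_step_s: float = 1.0,
    duration_s: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CTPBundle:
    """Forward-model a 4D CTP acquisition on the phantom grid.

    Each tissue voxel's time-attenuation curve is
    ``CBF * (AIF (*) R)(t - delay)`` with residue ``R(t) = exp(-t / MTT)``,
    superimposed on the voxel's NCCT baseline density. Infarct-core voxels
    receive ``cbf_normal * cbf_core_ratio`` and ``delay_core_s``; the rest of
    the brain receives ``cbf_normal`` with zero delay. A small anterior
    midline vessel carries the undiluted AIF so that AIF search has a true
    arterial target. Amplitudes are scaled so normal tissue peaks near 25 HU
    of enhancement.
    """
    if time_step_s <= 0:
        raise InputError("time_step_s must be > 0")
    if not (0.0 < cbf_core_ratio < 1.0):
        raise InputError("cbf_core_ratio must lie in (0, 1)")
    times = np.arange(0.0, duration_s, time_step_s)
    if times.size < 10:
        raise InputError("duration_s too short: need at least 10 time points")
    aif = gamma_variate_aif(times)
    if aif.max() <= 0:
        raise InputError("duration_s does not cover the AIF bolus")

    rng = np.random.default_rng(seed)
    brain = bundle.brain_mask.voxels.astype(bool)
    core = bundle.infarct_mask.voxels.astype(bool)
    normal_tissue = brain & ~core

    def tissue_curve(flow_scale: float, delay: float) -> np.ndarray:
        shifted = np.interp(times - delay, times, aif, left=0.0, right=0.0)
        residue = np.exp(-times / mtt_s)
        conv = np.convolve(shifted, residue)[: times.size] * time_step_s
        return flow_scale * conv

    base = tissue_curve(1.0, 0.0)
    amp = 25.0 / base.max()  # HU of peak enhancement for normal tissue
    curve_normal = amp * base
    curve_core = amp * cbf_core_ratio * tissue_curve(1.0, delay_core_s)

    # vessel: a small anterior midline region inside the brain
    shape = bundle.ncct.shape
    spacing = np.asarray(bundle.ncct.spacing)
    idxs = np.argwhere(brain)
    y_hi = np.quantile(idxs[:, 1], 0.97)
    cx = (shape[0] - 1) / 2.0
    cz = (shape[2] - 1) / 2.0
    vessel = np.zeros(shape, dtype=bool)
    sel = (
        (idxs[:, 1] >= y_hi)
        & (np.abs(idxs[:, 0] - cx) * spacing[0] <= 6.0)
        & (np.abs(idxs[:, 2] - cz) * spacing[2] <= 8.0)
    )
    vessel[tuple(idxs[sel].T)] = True
    if not vessel.any():  # pragma: no cover - degenerate tiny grids only
        raise InputError("could not place an AIF vessel inside the brain mask")

    series = np.broadcast_to(
        bundle.ncct.voxels[..., None], shape + (times.size,)
    ).astype(np.float32).copy()
    series[normal_tissue & ~vessel] += curve_normal.astype(np.float32)
    series[core & ~vessel] += curve_core.astype(np.float32)
    series[vessel] = bundle.ncct.voxels[vessel][:, None] + aif.astype(np.float32)
    if noise_sd > 0:
        series += rng.normal(0.0, noise_sd, series.shape).astype(np.float32)

    cbf_truth = np.zeros(shape, dtype=np.float32)
    cbf_truth[normal_tissue] = cbf_normal
    cbf_truth[core] = cbf_normal * cbf_core_ratio
    tmax_truth = np.zeros(shape, dtype=np.float32)
    tmax_truth[core] = delay_core_s

    ctp = CTPSeries(series, times, tuple(bundle.ncct.spacing), bundle.ncct.origin)
    return CTPBundle(
        series=ctp,
        cbf_truth=cbf_truth,
        tmax_truth=tmax_truth,
        vessel_mask=VoxelMask.on_grid(vessel, bundle.ncct),
        aif_truth=aif,
    )
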