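"""CT-perfusion processing: AIF selection, SVD deconvolution, core mask.

The indicator-dilution model treats each voxel's contrast time-attenuation
curve as the convolution of an arterial input function (AIF) with a scaled
residue function: ``C(t) = CBF * (AIF (*) R)(t)``. Deconvolving with a
truncated-SVD inverse of the AIF convolution matrix recovers ``k(t) =
CBF * R(t - delay)``; its maximum is (relative) CBF and its argmax is Tmax.
The ischemic core is tissue with CBF below 30% of normal, where "normal" is
the median CBF of tissue with Tmax under 4 s. Only CBF ratios enter the
core rule, so no absolute ml/100g/min calibration is attempted.

The inversion uses the block-circulant (delay-insensitive) convolution
matrix: tracer arrival in ischemic tissue lags the arterial input by
seconds, and the non-circulant formulation systematically underestimates
CBF in exactly the delayed tissue the core rule needs to classify.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .ct_io import CTVolume, VoxelMask
from .errors import InputError, PipelineError

__all__ = [
    "CTPSeries",
    "PerfusionMaps",
    "CoreMaskConfig",
    "read_ctp_series",
    "select_aif",
    "deconvolve",
    "core_mask",
]


@dataclass
class CTPSeries:
    """A 4D CTP acquisition: 3 spatial axes + time, in HU."""

    voxels: np.ndarray
    times: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 4:
            raise InputError("CTPSeries requires a 4D array (x, y, z, t)")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != self.voxels.shape[3]:
            raise InputError("times length must match the temporal axis")
        if self.times.size < 10:
            raise InputError("CTP series needs at least 10 time points")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def mean_volume(self) -> CTVolume:
        """Temporal mean as a 3D volume (used for registration to NCCT)."""
        return CTVolume(self.voxels.mean(axis=3), self.spacing, self.origin)


@dataclass
class PerfusionMaps:
    """Per-voxel relative CBF (arbitrary units) and Tmax (s)."""

    cbf: np.ndarray
    tmax: np.ndarray
    brain_mask: VoxelMask

    def __post_init__(self) -> None:
        self.cbf = np.asarray(self.cbf, dtype=np.float32)
        self.tmax = np.asarray(self.tmax, dtype=np.float32)
        if self.cbf.shape != self.tmax.shape:
            raise InputError("cbf and tmax maps must share a shape")


@dataclass
class CoreMaskConfig:
    """The core rule: CBF < cbf_core_fraction x median CBF of Tmax-normal tissue."""

    cbf_core_fraction: float = 0.30
    tmax_normal_s: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.cbf_core_fraction < 1.0):
            raise InputError("cbf_core_fraction must lie in (0, 1)")
        if self.tmax_normal_s <= 0:
            raise InputError("tmax_normal_s must be > 0")


def read_ctp_series(path: str | Path, time_step_s: float | None = None) -> CTPSeries:
    """Load a 4D NIfTI CTP series; frame times from pixdim[4] unless given."""
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise InputError(f"expected a 4D image, got shape {img.shape} in {path}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if any((not np.isfinite(z)) or z <= 0 for z in spacing):
        raise InputError(f"invalid voxel spacing {spacing} in NIfTI header of {path}")
    dt = time_step_s if time_step_s is not None else float(zooms[3]) if len(zooms) > 3 else 0.0
    if dt <= 0:
        raise InputError(
            "frame interval missing: header pixdim[4] is unset; pass time_step_s"
        )
    times = np.arange(data.shape[3]) * dt
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTPSeries(data, times, spacing, origin)


def _bolus_start_index(curve: np.ndarray, fraction: float = 0.10) -> int:
    """First index where a baseline-subtracted curve reaches ``fraction`` of peak."""
    enh = curve - curve[0]
    peak = enh.max()
    if peak <= 0:
        return 1
    above = np.flatnonzero(enh >= fraction * peak)
    return max(int(above[0]), 1)


def select_aif(
    series: CTPSeries,
    brain_mask: VoxelMask,
    k: int = 20,
    min_enhancement_hu: float = 5.0,
) -> np.ndarray:
    """Pick an arterial input curve from the best candidate voxels.

    Candidates are ranked by a score favoring high peak enhancement, early
    peak time, and narrow width — the canonical arterial signature. The
    returned curve is the mean baseline-subtracted curve of the top ``k``
    voxels. The score is invariant to a positive global rescaling of the
    data, so the same voxels are selected regardless of contrast dose.

    Raises
    ------
    PipelineError
        "no bolus detected" when no voxel enhances by ``min_enhancement_hu``.
    """
    mask = brain_mask.voxels.astype(bool)
    tacs = series.voxels[mask]  # (n, t)
    times = series.times
    mean_curve = tacs.mean(axis=0)
    n0 = _bolus_start_index(mean_curve)
    baseline = tacs[:, :n0].mean(axis=1, keepdims=True)
    enh = tacs - baseline
    peaks = enh.max(axis=1)
    if peaks.max() < min_enhancement_hu:
        raise PipelineError("no bolus detected")
    t_peak = times[np.argmax(enh, axis=1)]
    dt = float(np.median(np.diff(times)))
    # full width above half maximum, in seconds
    width = (enh >= 0.5 * peaks[:, None]).sum(axis=1) * dt
    score = peaks / ((t_peak - times[0] + dt) * (width + dt))
    score[peaks < min_enhancement_hu] = -np.inf
    top = np.argsort(score)[::-1][: min(k, int(np.isfinite(score).sum()))]
    return enh[top].mean(axis=0)


def deconvolve(
    series: CTPSeries,
    aif: np.ndarray,
    brain_mask: VoxelMask | None = None,
    svd_threshold_fraction: float = 0.1,
) -> PerfusionMaps:
    """Truncated-SVD deconvolution of every voxel curve against the AIF.

    Non-uniform acquisitions are first resampled to a uniform time grid by
    linear interpolation. Baseline frames (before the AIF reaches 10% of
    its peak) are averaged and subtracted per voxel. Singular values of the
    AIF convolution matrix below ``svd_threshold_fraction`` of the maximum
    are zeroed — the standard regularization against oscillatory residue
    estimates. CBF is clamped at 0.
    """
    aif = np.asarray(aif, dtype=float)
    if aif.size != series.times.size:
        raise InputError("aif and series must share the time axis")
    times = series.times
    data = series.voxels
    dts = np.diff(times)
    dt = float(dts.min())
    if not np.allclose(dts, dts[0], rtol=1e-6):
        grid = np.arange(times[0], times[-1] + 0.5 * dt, dt)
        data = np.ascontiguousarray(
            np.stack(
                [np.interp(grid, times, data.reshape(-1, times.size)[i])
                 for i in range(int(np.prod(series.shape)))],
                axis=0,
            ).reshape(series.shape + (grid.size,))
        )
        aif = np.interp(grid, times, aif)
        times = grid
    else:
        dt = float(dts[0])

    n_t = times.size
    n0 = _bolus_start_index(aif)
    aif0 = aif - aif[:n0].mean()

    # block-circulant (delay-insensitive) formulation: zero-pad to 2T so the
    # convolution matrix is circulant, whose SVD is the DFT — truncating
    # singular values below the threshold is exactly truncating small
    # Fourier coefficients of the AIF
    n_pad = 2 * n_t
    a_fft = np.fft.rfft(aif0, n_pad) * dt
    mag = np.abs(a_fft)
    keep = mag >= svd_threshold_fraction * mag.max()
    if not keep.any():
        raise PipelineError("AIF convolution matrix singular after truncation")
    inv_fft = np.where(keep, 1.0, 0.0) / np.where(keep, a_fft, 1.0)

    flat = data.reshape(-1, n_t).astype(np.float64)
    flat = flat - flat[:, :n0].mean(axis=1, keepdims=True)
    tac_fft = np.fft.rfft(flat, n_pad, axis=1)
    residue = np.fft.irfft(tac_fft * inv_fft, n_pad, axis=1)[:, :n_t]
    cbf = residue.max(axis=1)
    tmax = times[np.argmax(residue, axis=1)] - times[0]
    np.maximum(cbf, 0.0, out=cbf)

    shape = series.shape
    if brain_mask is None:
        brain_mask = VoxelMask(np.ones(shape, dtype=np.uint8), series.spacing, series.origin)
    return PerfusionMaps(
        cbf.reshape(shape).astype(np.float32),
        tmax.reshape(shape).astype(np.float32),
        brain_mask,
    )


def core_mask(maps: PerfusionMaps, cfg: CoreMaskConfig | None = None) -> VoxelMask:
    """Threshold perfusion maps into the ischemic-core mask.

    Normal reference = median CBF over brain voxels with Tmax strictly
    below ``tmax_normal_s`` (median rather than mean: robust to residual
    lesion voxels). Core = brain voxels with CBF strictly below
    ``cbf_core_fraction`` x reference. An empty core is a valid outcome.

    Raises
    ------
    PipelineError
        "no normal tissue reference" if no voxel has Tmax below the cutoff.
    """
    cfg = cfg or CoreMaskConfig()
    brain = maps.brain_mask.voxels.astype(bool)
    normal_sel = brain & (maps.tmax < cfg.tmax_normal_s)
    if not normal_sel.any():
        raise PipelineError("no normal tissue reference")
    reference = float(np.median(maps.cbf[normal_sel]))
    core = brain & (maps.cbf < cfg.cbf_core_fraction * reference)
    return VoxelMask(core.astype(np.uint8), maps.brain_mask.spacing, maps.brain_mask.origin)
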