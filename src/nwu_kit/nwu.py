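"""Net water uptake (NWU) from an ischemic region and its mirror.

NWU is the percent density deficit of ischemic tissue relative to the
homologous contralateral region:

    NWU = 100 * (1 - D_ischemic / D_normal)

where each D is the mean HU over the region's voxels after removing CSF and
applying HU windows. The windows are asymmetric on follow-up scans: the
visible infarct keeps [0, 40] HU — the lower bound extended to 0 to retain
severely edematous voxels, the upper bound cut to 40 to reject hemorrhagic
transformation and contrast staining — while the normal side (and the
baseline CTP core) keeps the standard [20, 80] HU window.

Besides the full-region estimator, the module provides the patch-based
estimator (standard square patches over the MCA territory of four axial
slices, mirrored contralaterally) and the manual-protocol ROI estimator
(up to 13 small discs inside the infarct, mirrored, no HU windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .config import PipelineConfig
from .csf_seg import segment_csf
from .ct_io import CTVolume, VoxelMask
from .ctp import CTPSeries, CoreMaskConfig, core_mask, deconvolve, select_aif
from .errors import InputError, PipelineError
from .infarct_seg import infarct_volume_ml, segment_infarct
from .midline import (
    MidlinePlane,
    estimate_midline,
    extract_brain_mask,
    mirror_mask,
    register_rigid,
    resample_mask,
)

__all__ = [
    "ThresholdConfig",
    "NWUResult",
    "PatchSpec",
    "ROISpec",
    "compute_nwu",
    "patch_nwu",
    "roi_nwu",
    "run_baseline_pipeline",
    "run_followup_pipeline",
]


@dataclass
class ThresholdConfig:
    """HU windows (inclusive) for each region class."""

    infarct_hu: tuple[float, float] = (0.0, 40.0)
    baseline_core_hu: tuple[float, float] = (20.0, 80.0)
    normal_hu: tuple[float, float] = (20.0, 80.0)

    def __post_init__(self) -> None:
        for name in ("infarct_hu", "baseline_core_hu", "normal_hu"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InputError(f"{name} must satisfy low < high")
            setattr(self, name, (float(lo), float(hi)))

    @classmethod
    def from_pipeline_config(cls, cfg: PipelineConfig) -> "ThresholdConfig":
        return cls(cfg.infarct_hu, cfg.baseline_core_hu, cfg.normal_hu)


@dataclass
class NWUResult:
    """An NWU measurement with full voxel-exclusion accounting."""

    nwu_percent: float
    d_ischemic: float
    d_normal: float
    n_ischemic_used: int
    n_normal_used: int
    n_removed_csf: dict[str, int]
    n_removed_threshold: dict[str, int]
    thresholds: ThresholdConfig
    mode: str
    warnings: list[str] = field(default_factory=list)
    infarct_volume_ml: float | None = None

    @property
    def total_edema_volume_ml(self) -> float | None:
        """Infarct volume x NWU fraction — a derived volumetric measure."""
        if self.infarct_volume_ml is None:
            return None
        return self.infarct_volume_ml * self.nwu_percent / 100.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = {
            k: list(v) for k, v in asdict(self.thresholds).items()
        }
        d["total_edema_volume_ml"] = self.total_edema_volume_ml
        return d


def _interval_filter(values: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    return (values >= interval[0]) & (values <= interval[1])


def _measure(
    volume: CTVolume,
    ischemic: np.ndarray,
    normal: np.ndarray,
    csf: np.ndarray | None,
    ischemic_interval: tuple[float, float] | None,
    normal_interval: tuple[float, float] | None,
    thresholds: ThresholdConfig,
    mode: str,
    min_voxels: int,
    warnings: list[str],
) -> NWUResult:
    """Shared exclusion bookkeeping + Eq. NWU = 100*(1 - D_isch/D_normal)."""
    n_removed_csf: dict[str, int] = {}
    n_removed_threshold: dict[str, int] = {}
    regions = {}
    for name, sel, interval in (
        ("ischemic", ischemic, ischemic_interval),
        ("normal", normal, normal_interval),
    ):
        sel = sel.copy()
        if csf is not None:
            n_before = int(sel.sum())
            sel &= ~csf
            n_removed_csf[name] = n_before - int(sel.sum())
        else:
            n_removed_csf[name] = 0
        vals = volume.voxels[sel]
        if interval is not None:
            keep = _interval_filter(vals, interval)
            n_removed_threshold[name] = int((~keep).sum())
            vals = vals[keep]
        else:
            n_removed_threshold[name] = 0
        if vals.size < min_voxels:
            raise PipelineError(
                f"region vanished after exclusions: {name} region has "
                f"{vals.size} voxels (< {min_voxels})"
            )
        regions[name] = vals
    d_isch = float(regions["ischemic"].mean())
    d_norm = float(regions["normal"].mean())
    if d_norm == 0:
        raise PipelineError("normal-region mean density is zero; NWU undefined")
    return NWUResult(
        nwu_percent=100.0 * (1.0 - d_isch / d_norm),
        d_ischemic=d_isch,
        d_normal=d_norm,
        n_ischemic_used=int(regions["ischemic"].size),
        n_normal_used=int(regions["normal"].size),
        n_removed_csf=n_removed_csf,
        n_removed_threshold=n_removed_threshold,
        thresholds=thresholds,
        mode=mode,
        warnings=warnings,
    )


def compute_nwu(
    volume: CTVolume,
    infarct: VoxelMask,
    csf: VoxelMask,
    plane: MidlinePlane,
    thresholds: ThresholdConfig | None = None,
    mode: str = "followup-infarct",
    brain_mask: VoxelMask | None = None,
    min_voxels: int = 50,
) -> NWUResult:
    """Compute NWU for an infarct (or core) mask against its mirror region.

    The mirror region is the infarct mask reflected across the midline
    plane, minus any overlap with the infarct itself (midline-crossing
    lesions) and, when ``brain_mask`` is given, minus voxels outside the
    brain. CSF is removed from both regions first; then the ischemic region
    is filtered to its mode's HU window (``followup-infarct`` -> [0, 40],
    ``baseline-core`` -> [20, 80]) and the mirror region to the normal
    window [20, 80]. Exclusion counts for every step are recorded on the
    result.
    """
    thresholds = thresholds or ThresholdConfig()
    if infarct.count() == 0:
        raise InputError("infarct mask is empty")
    if mode == "followup-infarct":
        isch_interval = thresholds.infarct_hu
    elif mode == "baseline-core":
        isch_interval = thresholds.baseline_core_hu
    else:
        raise InputError(f"unknown mode {mode!r}")

    warnings: list[str] = []
    isch = infarct.voxels.astype(bool)
    mirror = mirror_mask(infarct, plane).voxels.astype(bool)
    n_overlap = int((mirror & isch).sum())
    if n_overlap:
        warnings.append(
            f"{n_overlap} mirrored voxels overlap the infarct mask "
            "(midline-crossing lesion?); excluded from the normal region"
        )
        mirror &= ~isch
    if brain_mask is not None:
        outside = mirror & ~brain_mask.voxels.astype(bool)
        frac = outside.sum() / max(mirror.sum(), 1)
        if frac > 0.20:
            warnings.append(
                f"mirror region falls {100 * frac:.0f}% outside the brain mask"
            )
        mirror &= brain_mask.voxels.astype(bool)
    return _measure(
        volume, isch, mirror, csf.voxels.astype(bool),
        isch_interval, thresholds.normal_hu, thresholds, mode, min_voxels, warnings,
    )


@dataclass
class PatchSpec:
    """Standard square patches over the MCA territory of four axial slices."""

    patch_edge_mm: float = 20.0
    slice_positions: tuple[float, float, float, float] | None = None  # z in mm
    side: str = "left"
    centers_mm: Sequence[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.patch_edge_mm <= 0:
            raise InputError("patch_edge_mm must be > 0")
        if self.slice_positions is not None and len(self.slice_positions) != 4:
            raise InputError("exactly 4 axial slice positions are required")
        if self.side not in ("left", "right"):
            raise InputError("side must be 'left' or 'right'")
        if self.centers_mm is not None and len(self.centers_mm) != 4:
            raise InputError("exactly 4 patch centers are required")


def _auto_patch_centers(
    brain_mask: VoxelMask, plane: MidlinePlane, spec: PatchSpec
) -> list[tuple[float, float, float]]:
    """Mid-hemisphere centroids on four axial levels through the brain."""
    idxs = np.argwhere(brain_mask.voxels)
    if idxs.size == 0:
        raise InputError("brain mask is empty")
    pts = brain_mask.index_to_physical(idxs)
    d = plane.signed_distance(pts)
    sign = -1.0 if spec.side == "left" else 1.0
    side_pts = pts[np.sign(d) == sign]
    if side_pts.size == 0:
        raise PipelineError(f"no brain voxels on the {spec.side} side of the midline")
    if spec.slice_positions is not None:
        z_levels = list(spec.slice_positions)
    else:
        z_lo, z_hi = np.quantile(side_pts[:, 2], [0.30, 0.75])
        z_levels = list(np.linspace(z_lo, z_hi, 4))
    dz = brain_mask.spacing[2]
    centers = []
    for z in z_levels:
        at = side_pts[np.abs(side_pts[:, 2] - z) <= 0.6 * dz]
        if at.shape[0] == 0:
            raise InputError(f"axial slice at z={z:.1f} mm contains no brain")
        cx, cy = at[:, 0].mean(), at[:, 1].mean()
        # push the center laterally toward mid-hemisphere (MCA-territory analog)
        cx = 0.5 * (cx + at[:, 0].min() if sign < 0 else cx + at[:, 0].max())
        centers.append((float(cx), float(cy), float(z)))
    return centers


def _square_patch_region(
    grid: CTVolume, centers: Sequence[tuple[float, float, float]], edge_mm: float
) -> np.ndarray:
    out = np.zeros(grid.shape, dtype=bool)
    half = edge_mm / 2.0
    sx, sy, sz = grid.spacing
    ox, oy, oz = grid.origin
    xs = ox + np.arange(grid.shape[0]) * sx
    ys = oy + np.arange(grid.shape[1]) * sy
    for cx, cy, cz in centers:
        k = int(round((cz - oz) / sz))
        if not (0 <= k < grid.shape[2]):
            raise InputError(f"patch slice z={cz:.1f} mm is outside the volume")
        sel_x = np.abs(xs - cx) <= half
        sel_y = np.abs(ys - cy) <= half
        out[np.ix_(sel_x, sel_y, [k])] = True
    return out


def patch_nwu(
    volume: CTVolume,
    spec: PatchSpec,
    plane: MidlinePlane,
    csf: VoxelMask,
    thresholds: ThresholdConfig | None = None,
    brain_mask: VoxelMask | None = None,
    min_voxels: int = 50,
) -> NWUResult:
    """Patch-based NWU estimate (no infarct segmentation required).

    Square patches on four axial slices of the affected MCA territory form
    the ischemic region; their mirror across the midline forms the normal
    region. Both regions are CSF-cleaned and filtered to the standard
    normal-brain window [20, 80] — the patch protocol predates the
    asymmetric windows and samples territory, not segmented infarct.
    """
    thresholds = thresholds or ThresholdConfig()
    if spec.centers_mm is not None:
        centers = list(spec.centers_mm)
    else:
        if brain_mask is None:
            brain_mask = extract_brain_mask(volume)
        centers = _auto_patch_centers(brain_mask, plane, spec)
    isch = _square_patch_region(volume, centers, spec.patch_edge_mm)
    if brain_mask is not None:
        isch &= brain_mask.voxels.astype(bool)
    isch_mask = VoxelMask.on_grid(isch, volume)
    if isch_mask.count() == 0:
        raise PipelineError("patch region contains no brain voxels")
    mirror = mirror_mask(isch_mask, plane).voxels.astype(bool)
    mirror &= ~isch
    if brain_mask is not None:
        mirror &= brain_mask.voxels.astype(bool)
    return _measure(
        volume, isch, mirror, csf.voxels.astype(bool),
        thresholds.normal_hu, thresholds.normal_hu, thresholds, "patch",
        min_voxels, [],
    )


@dataclass
class ROISpec:
    """Manual-protocol sampling: up to 13 discs inside the infarct."""

    centers: Sequence[tuple[float, float, float]]
    diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        if not (1 <= len(self.centers) <= 13):
            raise InputError("ROISpec requires between 1 and 13 centers")
        if self.diameter_mm <= 0:
            raise InputError("diameter_mm must be > 0")


def roi_nwu(
    volume: CTVolume,
    spec: ROISpec,
    plane: MidlinePlane,
    min_voxels: int = 5,
) -> NWUResult:
    """ROI-sampling NWU: mean density over small discs vs. their mirrors.

    Each ROI is a 2D disc confined to its center's axial slice, matching
    the slice-based manual protocol. No CSF removal and no HU windows are
    applied: the protocol avoids hemorrhage and CSF by placement. The
    voxel floor is lower than for full-region estimators because the
    protocol's regions are deliberately small.
    """
    d = plane.signed_distance(np.asarray(spec.centers, dtype=float))
    if np.any(d == 0) or (np.any(d > 0) and np.any(d < 0)):
        raise InputError(
            "all ROI centers must lie on the affected side of the midline"
        )
    r = spec.diameter_mm / 2.0
    sx, sy, sz = volume.spacing
    ox, oy, oz = volume.origin
    xs = ox + np.arange(volume.shape[0]) * sx
    ys = oy + np.arange(volume.shape[1]) * sy
    isch = np.zeros(volume.shape, dtype=bool)
    for cx, cy, cz in spec.centers:
        k = int(round((cz - oz) / sz))
        if not (0 <= k < volume.shape[2]):
            raise InputError(f"ROI slice z={cz:.1f} mm is outside the volume")
        dist2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
        isch[:, :, k] |= dist2 <= r * r
    isch_mask = VoxelMask.on_grid(isch, volume)
    mirror = mirror_mask(isch_mask, plane).voxels.astype(bool)
    mirror &= ~isch
    return _measure(
        volume, isch, mirror, None, None, None,
        ThresholdConfig(), "roi", min_voxels, [],
    )


def run_followup_pipeline(
    ncct: CTVolume,
    config: PipelineConfig | None = None,
    csf_segmenter: Callable | None = None,
    infarct_segmenter: Callable | None = None,
) -> NWUResult:
    """Fully automated follow-up NWU: brain mask, midline, CSF, infarct, NWU.

    Raises ``PipelineError("no visible infarct")`` when segmentation finds
    nothing — mirroring the exclusion of such scans from manual reads.
    """
    cfg = config or PipelineConfig()
    brain = extract_brain_mask(ncct, cfg.brain_hu_low, cfg.brain_hu_high)
    plane = estimate_midline(ncct, brain, seed=cfg.seed)
    csf_fn = csf_segmenter or (
        lambda v, b: segment_csf(v, b, cfg.csf_hu_low, cfg.csf_hu_high,
                                 cfg.csf_min_component_ml)
    )
    csf = csf_fn(ncct, brain)
    if infarct_segmenter is not None:
        infarct = infarct_segmenter(ncct, brain, csf, plane)
    else:
        infarct = segment_infarct(
            ncct, brain, csf, plane,
            delta_hu=cfg.delta_hu, smoothing_mm=cfg.smoothing_mm,
            min_component_ml=cfg.min_component_ml,
            hu_low=cfg.infarct_hu[0], hu_high=cfg.infarct_hu[1],
        )
    if infarct.count() == 0:
        raise PipelineError("no visible infarct")
    result = compute_nwu(
        ncct, infarct, csf, plane,
        thresholds=ThresholdConfig.from_pipeline_config(cfg),
        mode="followup-infarct", brain_mask=brain,
        min_voxels=cfg.min_region_voxels,
    )
    result.infarct_volume_ml = infarct_volume_ml(infarct)
    return result


def run_baseline_pipeline(
    ncct: CTVolume,
    ctp_series: CTPSeries,
    config: PipelineConfig | None = None,
    visible_infarct_mask: VoxelMask | None = None,
    csf_segmenter: Callable | None = None,
) -> NWUResult:
    """Fully automated baseline NWU via the CTP-derived core.

    The core (CBF < 30% of Tmax-normal tissue) is deconvolved from the CTP
    series, rigidly registered onto the NCCT, and measured with the
    [20, 80] window on both sides. If an infarct is already clearly visible
    on the baseline NCCT, its mask can be supplied and is used in place of
    the core — then measured like a follow-up infarct ([0, 40] window).
    """
    cfg = config or PipelineConfig()
    brain = extract_brain_mask(ncct, cfg.brain_hu_low, cfg.brain_hu_high)
    plane = estimate_midline(ncct, brain, seed=cfg.seed)
    csf_fn = csf_segmenter or (
        lambda v, b: segment_csf(v, b, cfg.csf_hu_low, cfg.csf_hu_high,
                                 cfg.csf_min_component_ml)
    )
    csf = csf_fn(ncct, brain)
    thresholds = ThresholdConfig.from_pipeline_config(cfg)

    if visible_infarct_mask is not None:
        result = compute_nwu(
            ncct, visible_infarct_mask, csf, plane, thresholds=thresholds,
            mode="followup-infarct", brain_mask=brain,
            min_voxels=cfg.min_region_voxels,
        )
        result.infarct_volume_ml = infarct_volume_ml(visible_infarct_mask)
        return result

    ctp_mean = ctp_series.mean_volume()
    brain_ctp = extract_brain_mask(ctp_mean, cfg.brain_hu_low, cfg.brain_hu_high + 40)
    aif = select_aif(ctp_series, brain_ctp, k=cfg.aif_k)
    maps = deconvolve(ctp_series, aif, brain_ctp, cfg.svd_threshold_fraction)
    core = core_mask(maps, CoreMaskConfig(cfg.cbf_core_fraction, cfg.tmax_normal_s))
    if core.count() == 0:
        raise PipelineError("no measurable core")
    transform = register_rigid(ctp_mean, ncct, seed=cfg.seed)
    core_ncct = resample_mask(core, ncct, transform)
    if core_ncct.count() == 0:
        raise PipelineError("no measurable core")
    result = compute_nwu(
        ncct, core_ncct, csf, plane, thresholds=thresholds,
        mode="baseline-core", brain_mask=brain,
        min_voxels=cfg.min_region_voxels,
    )
    result.infarct_volume_ml = infarct_volume_ml(core_ncct)
    if transform.warning:
        result.warnings.append(transform.warning)
    return result
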