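"""CSF segmentation for exclusion from density measurements.

A classical HU-window baseline: CSF is near water (0 HU) and well below
parenchyma (~30-45 HU) on the phantom, so a [-5, 15] HU window inside the
brain, cleaned by a 1-voxel morphological opening and a minimum component
size, captures ventricles and larger sulcal spaces. On real follow-up CTs
a severely edematous infarct can fall inside any fixed window — learned
segmenters disambiguate by context — so the window is configurable and any
callable ``(CTVolume, VoxelMask) -> VoxelMask`` can be plugged into the
pipeline in place of this baseline.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, VoxelMask

__all__ = ["segment_csf"]


def segment_csf(
    volume: CTVolume,
    brain_mask: VoxelMask,
    csf_hu_low: float = -5.0,
    csf_hu_high: float = 15.0,
    csf_min_component_ml: float = 0.3,
) -> VoxelMask:
    """Segment CSF spaces inside the brain mask by HU window.

    The output is always a subset of ``brain_mask``; an empty mask is valid
    (no CSF-range tissue). Widening the window can only grow the output:
    thresholding, opening, and minimum-size filtering are all monotone in
    the candidate set.
    """
    cand = (
        brain_mask.voxels.astype(bool)
        & (volume.voxels >= csf_hu_low)
        & (volume.voxels <= csf_hu_high)
    )
    # 1-voxel-radius opening by reconstruction, in-plane: erosion survivors
    # seed their full connected component back, so speckle disappears while
    # genuine compartments keep their blurred boundary voxels. The erosion
    # is in-plane only — head CT slices are thick (3-5 mm), and a 3D
    # erosion would erase any structure under three slices tall.
    cross = np.zeros((3, 3, 1), dtype=bool)
    cross[1, :, 0] = True
    cross[:, 1, 0] = True
    seed = ndimage.binary_erosion(cand, structure=cross)
    labels, n = ndimage.label(cand, structure=np.ones((3, 3, 3)))
    if n == 0:
        return VoxelMask.on_grid(np.zeros(volume.shape, dtype=np.uint8), volume)
    survivors = np.unique(labels[seed])
    survivors = survivors[survivors > 0]
    if survivors.size == 0:
        return VoxelMask.on_grid(np.zeros(volume.shape, dtype=np.uint8), volume)
    min_vox = csf_min_component_ml * 1000.0 / volume.voxel_volume_mm3
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=survivors)
    keep = survivors[sizes >= min_vox]
    out = np.isin(labels, keep)
    return VoxelMask.on_grid(out, volume)
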