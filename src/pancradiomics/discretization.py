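"""Grey-level discretization of ROI intensities.

Texture matrices operate on integer grey levels, not raw intensities: two
adjacent voxels differing by 0.01 on the normalized [0,1] scale are almost
certainly noise, and binning (fixed bin *count*, equal-width over the ROI's
own min-max range) keeps such voxels in the same level.  Bin counts are the
powers of two 2..256; sweeping them is one axis of the feature grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import Mask3D, ValidationError, Volume3D

__all__ = ["VALID_BIN_COUNTS", "DiscretizationConfig", "LevelMap", "discretize"]

VALID_BIN_COUNTS = (2, 4, 8, 16, 32, 64, 128, 256)


@dataclass(frozen=True)
class DiscretizationConfig:
    bin_count: int = 32

    def __post_init__(self) -> None:
        if self.bin_count not in VALID_BIN_COUNTS:
            raise ValidationError(
                f"bin_count must be a power of two in {VALID_BIN_COUNTS}, got {self.bin_count}"
            )


@dataclass
class LevelMap:
    """Integer grey levels over an ROI.

    ``levels`` holds values 1..bin_count inside the ROI and the sentinel 0
    outside it.  ``bin_edges`` are the ``bin_count + 1`` equal-width edges
    the discretization used (logged for audit).
    """

    levels: np.ndarray
    roi: np.ndarray
    bin_count: int
    bin_edges: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        inside = self.levels[self.roi]
        if inside.size and (inside.min() < 1 or inside.max() > self.bin_count):
            raise ValidationError("in-ROI levels must lie in [1, bin_count]")
        if np.any(self.levels[~self.roi] != 0):
            raise ValidationError("out-of-ROI voxels must carry the sentinel 0")

    @property
    def n_voxels(self) -> int:
        return int(self.roi.sum())


def discretize(
    volume: Volume3D,
    roi: Mask3D | np.ndarray,
    config: DiscretizationConfig | int = DiscretizationConfig(),
) -> LevelMap:
    """Map in-ROI intensities onto integer levels 1..bin_count.

    Equal-width bins span the ROI's own [min, max] intensity range (texture
    should reflect intra-tumor contrast, not scan-wide range); the maximum
    intensity maps to ``bin_count``, not ``bin_count + 1``.  A constant ROI
    maps every voxel to level 1.
    """
    if isinstance(config, int):
        config = DiscretizationConfig(config)
    roi_arr = roi.foreground() if isinstance(roi, Mask3D) else np.asarray(roi, bool)
    if roi_arr.shape != volume.voxels.shape:
        raise ValidationError("ROI shape does not match volume shape")
    if not roi_arr.any():
        raise ValidationError("ROI is empty")
    vals = volume.voxels[roi_arr].astype(np.float64)
    if not np.isfinite(vals).all():
        raise ValidationError("ROI contains non-finite intensities")
    b = config.bin_count
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.voxels.shape, dtype=np.int16)
    if hi == lo:
        levels[roi_arr] = 1
        edges = np.linspace(lo, lo + 1.0, b + 1)
    else:
        edges = np.linspace(lo, hi, b + 1)
        lv = np.floor((vals - lo) / (hi - lo) * b).astype(np.int64) + 1
        np.clip(lv, 1, b, out=lv)
        levels[roi_arr] = lv
    return LevelMap(levels, roi_arr, b, edges, volume.spacing)
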