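"""Texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) and their features.

All matrix constructions consume a :class:`~pancradiomics.discretization.LevelMap`
(levels 1..B inside the ROI, 0 outside).  Spatial accumulation is 2D
in-plane — the four planar quadrant directions 0/45/90/135 degrees — summed
over axial slices; only the size-zone matrix, being direction-free, uses
full 3D 26-connectivity.  The *kernel* parameter bounds the neighborhood
radius (Chebyshev distance) within which voxel relationships are counted:
co-occurrences are accumulated at offsets of length 1..kernel along an
angle, dependence and grey-tone-difference statistics count all in-plane
neighbors within the kernel radius.

Degenerate inputs (an ROI too small to form a single voxel pair, a
constant-denominator feature such as correlation on a zero-variance matrix)
yield NaN sentinels; downstream screening filters them, mirroring the usual
removal of unusable/infinite feature values.

Feature definitions follow the IBSI/common radiomics conventions, except
four co-occurrence features that have no published formula and are defined
explicitly here (see :func:`glcm_features`): *inverse cluster shade* and
*inverse cluster tendency* are the cluster moments of the complement
distribution p'(i,j) proportional to max(p) - p(i,j); *Gaussian left polar*
is the lower-triangular (i >= j) probability mass Gaussian-weighted by the
level difference with sigma = B/4, and *inverse Gaussian left polar* its
complementary weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .discretization import LevelMap
from .io_preprocess import ValidationError

__all__ = [
    "ANGLES",
    "TextureParams",
    "GLCMatrix",
    "GLRLMatrix",
    "GLSZMatrix",
    "GLDMatrix",
    "NGTDMStats",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "compute_gldm",
    "compute_ngtdm",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "average_feature_maps",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "GLDM_FEATURES",
    "NGTDM_FEATURES",
]

# In-plane (dy, dx) unit offsets for the four quadrant directions.  Rows (y)
# grow downward in array order, so 45 degrees pairs up-and-right.
ANGLES: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class TextureParams:
    """Texture-sweep parameters: bin count, kernel radius and angles.

    ``kernel`` is the maximal neighborhood radius (the area A around a
    voxel): co-occurrence offsets run at distances 1..kernel, dependence and
    grey-tone-difference neighborhoods span Chebyshev radius ``kernel``.
    """

    bin_count: int
    kernel: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.kernel <= 5:
            raise ValidationError(f"kernel must be in [1, 5], got {self.kernel}")
        if not self.angles:
            raise ValidationError("angles must be non-empty")
        for a in self.angles:
            if a not in ANGLES:
                raise ValidationError(f"unknown angle {a}; valid: {sorted(ANGLES)}")
        if self.gldm_alpha < 0:
            raise ValidationError("gldm_alpha must be >= 0")


@dataclass
class GLCMatrix:
    counts: np.ndarray  # (B, B) symmetric
    bin_count: int
    symmetric: bool = True
    degenerate: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class GLRLMatrix:
    counts: np.ndarray  # (B, max_run_length), column j-1 <-> run length j
    bin_count: int
    n_voxels: int  # ROI voxels decomposed into runs


@dataclass
class GLSZMatrix:
    counts: np.ndarray  # (B, max_zone_size), column s-1 <-> zone size s
    bin_count: int
    n_voxels: int


@dataclass
class GLDMatrix:
    counts: np.ndarray  # (B, max_dependence + 1), column k <-> dependence k
    bin_count: int


@dataclass
class NGTDMStats:
    """Per-level occurrence probabilities p_i and summed deviations s_i."""

    levels: np.ndarray  # occurring level values (subset of 1..B)
    p: np.ndarray  # occurrence probability per occurring level, sums to 1
    s: np.ndarray  # summed |level - neighborhood mean| per occurring level
    n_valid: int  # voxels with at least one in-ROI neighbor
    bin_count: int


def _require_levelmap(levels: LevelMap) -> None:
    if levels.n_voxels == 0:
        raise ValidationError("empty ROI")


# ---------------------------------------------------------------------------
# grey-level co-occurrence matrix
# ---------------------------------------------------------------------------


def _offset_pairs(lv: np.ndarray, dy: int, dx: int):
    """Return (center, neighbor) level arrays for all in-plane pairs with both
    voxels in the ROI at offset (dy, dx), pooled over slices."""
    nz, ny, nx = lv.shape
    y0, y1 = max(0, -dy), min(ny, ny - dy)
    x0, x1 = max(0, -dx), min(nx, nx - dx)
    if y0 >= y1 or x0 >= x1:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    a = lv[:, y0:y1, x0:x1]
    b = lv[:, y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    valid = (a > 0) & (b > 0)
    return a[valid].astype(np.int64), b[valid].astype(np.int64)


def compute_glcm(
    levels: LevelMap,
    params: TextureParams,
    angle: int,
    distance: int = 1,
) -> GLCMatrix:
    """Symmetric co-occurrence counts at one in-plane offset.

    The offset is ``distance`` voxels along ``angle``; pairs are counted per
    slice (both voxels inside the ROI) and symmetrized by adding the
    transpose, so the matrix total is twice the number of ordered pairs.
    An ROI admitting no pair at this offset yields an all-zero matrix
    flagged degenerate.
    """
    _require_levelmap(levels)
    if angle not in params.angles:
        raise ValidationError(f"angle {angle} not in params.angles {params.angles}")
    if not 1 <= distance <= params.kernel:
        raise ValidationError(f"distance must be in [1, kernel={params.kernel}]")
    dy, dx = ANGLES[angle]
    b = params.bin_count
    i, j = _offset_pairs(levels.levels, dy * distance, dx * distance)
    counts = np.zeros((b, b), dtype=np.int64)
    if i.size:
        np.add.at(counts, (i - 1, j - 1), 1)
    counts = counts + counts.T
    return GLCMatrix(counts, b, symmetric=True, degenerate=i.size == 0)


@lru_cache(maxsize=16)
def _ij_grids(b: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(1, b + 1, dtype=np.float64)
    return np.meshgrid(i, i, indexing="ij")


GLCM_FEATURES = (
    "contrast",
    "dissimilarity",
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
    "cluster_tendency",
    "correlation",
    "joint_energy",
    "joint_entropy",
    "inverse_difference",
    "inverse_difference_moment",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "difference_entropy",
    "difference_variance",
    "inverse_cluster_shade",
    "inverse_cluster_tendency",
    "gaussian_left_polar",
    "inverse_gaussian_left_polar",
)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def glcm_features(matrix: GLCMatrix) -> dict[str, float]:
    """The 20 co-occurrence features (16 standard + 4 bespoke; see module
    docstring for the bespoke definitions).  A zero-total matrix returns NaN
    sentinels for every feature."""
    b = matrix.bin_count
    if matrix.total == 0 or matrix.degenerate:
        return {name: float("nan") for name in GLCM_FEATURES}
    p = matrix.counts.astype(np.float64) / matrix.total
    ii, jj = _ij_grids(b)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    lv = np.arange(1, b + 1, dtype=np.float64)
    mu_x = float((px * lv).sum())
    mu_y = float((py * lv).sum())
    sig_x = float(np.sqrt((px * (lv - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (lv - mu_y) ** 2).sum()))

    diff = np.abs(ii - jj)
    feats: dict[str, float] = {}
    feats["contrast"] = float((p * (ii - jj) ** 2).sum())
    feats["dissimilarity"] = float((p * diff).sum())
    feats["autocorrelation"] = float((p * ii * jj).sum())
    dev = ii + jj - mu_x - mu_y
    feats["cluster_shade"] = float((p * dev**3).sum())
    feats["cluster_prominence"] = float((p * dev**4).sum())
    feats["cluster_tendency"] = float((p * dev**2).sum())
    if sig_x > 0 and sig_y > 0:
        feats["correlation"] = (feats["autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y)
    else:
        feats["correlation"] = float("nan")
    feats["joint_energy"] = float((p**2).sum())
    feats["joint_entropy"] = _entropy2(p.ravel())
    feats["inverse_difference"] = float((p / (1.0 + diff)).sum())
    feats["inverse_difference_moment"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    feats["maximum_probability"] = float(p.max())

    # sum / difference distributions
    k_sum = np.arange(2, 2 * b + 1, dtype=np.float64)
    p_sum = np.zeros(2 * b - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, b, dtype=np.float64)
    p_diff = np.zeros(b)
    np.add.at(p_diff, diff.astype(int).ravel(), p.ravel())
    feats["sum_average"] = float((p_sum * k_sum).sum())
    feats["sum_entropy"] = _entropy2(p_sum)
    feats["difference_entropy"] = _entropy2(p_diff)
    mu_d = float((p_diff * k_diff).sum())
    feats["difference_variance"] = float((p_diff * (k_diff - mu_d) ** 2).sum())

    # bespoke features ------------------------------------------------------
    comp = p.max() - p
    comp_total = comp.sum()
    if comp_total > 0:
        pc = comp / comp_total
        pcx = pc.sum(axis=1)
        pcy = pc.sum(axis=0)
        mu_cx = float((pcx * lv).sum())
        mu_cy = float((pcy * lv).sum())
        devc = ii + jj - mu_cx - mu_cy
        feats["inverse_cluster_shade"] = float((pc * devc**3).sum())
        feats["inverse_cluster_tendency"] = float((pc * devc**2).sum())
    else:  # uniform matrix: complement distribution undefined
        feats["inverse_cluster_shade"] = float("nan")
        feats["inverse_cluster_tendency"] = float("nan")
    sigma = b / 4.0
    gauss = np.exp(-((ii - jj) ** 2) / (2.0 * sigma**2))
    lower = ii >= jj
    feats["gaussian_left_polar"] = float((p * gauss)[lower].sum())
    feats["inverse_gaussian_left_polar"] = float((p * (1.0 - gauss))[lower].sum())
    return feats


# ---------------------------------------------------------------------------
# grey-level run-length matrix
# ---------------------------------------------------------------------------


def _lines_along(lv2d: np.ndarray, angle: int) -> list[np.ndarray]:
    """All maximal lines of a 2D slice along a direction."""
    if angle == 0:
        return list(lv2d)
    if angle == 90:
        return list(lv2d.T)
    ny, nx = lv2d.shape
    if angle == 45:
        # anti-diagonals traversed up-right
        flipped = lv2d[::-1]
        return [np.diagonal(flipped, offset=k).copy() for k in range(-(ny - 1), nx)]
    if angle == 135:
        # main diagonals traversed down-right; runs are direction-symmetric
        return [np.diagonal(lv2d, offset=k).copy() for k in range(-(ny - 1), nx)]
    raise ValidationError(f"unknown angle {angle}")


def compute_glrlm(levels: LevelMap, angle: int) -> GLRLMatrix:
    """Run-length counts along one in-plane direction, pooled over slices.

    A run is a maximal sequence of equal levels along the direction;
    out-of-ROI voxels (level 0) break runs.  Every ROI voxel belongs to
    exactly one run, so sum_ij j * counts[i, j] equals the ROI voxel count.
    """
    _require_levelmap(levels)
    if angle not in ANGLES:
        raise ValidationError(f"unknown angle {angle}")
    b = levels.bin_count
    pieces: list[np.ndarray] = []
    sep = np.zeros(1, dtype=np.int64)
    for sl in levels.levels:
        for line in _lines_along(np.asarray(sl), angle):
            if line.size:
                pieces.append(line.astype(np.int64))
                pieces.append(sep)
    big = np.concatenate(pieces) if pieces else sep
    # run-length encode: boundaries where the value changes
    change = np.flatnonzero(np.diff(big)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [big.size])))
    values = big[starts]
    keep = values > 0
    values, lengths = values[keep], lengths[keep]
    max_len = int(lengths.max()) if lengths.size else 1
    counts = np.zeros((b, max_len), dtype=np.int64)
    if values.size:
        np.add.at(counts, (values - 1, lengths - 1), 1)
    return GLRLMatrix(counts, b, levels.n_voxels)


GLRLM_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis",
    "run_percentage",
    "run_entropy",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "grey_level_non_uniformity",
    "run_variance",
    "grey_level_variance",
)


def _weighted_matrix_features(
    counts: np.ndarray,
    size_index_base: int,
    n_voxels: int | None,
    names: Mapping[str, str],
) -> dict[str, float]:
    """Shared run/zone/dependence feature arithmetic.

    ``counts[i, c]`` tallies (level i+1, size ``c + size_index_base``);
    run/zone matrices index sizes from 1, the dependence matrix from 0 with
    the conventional ``k + 1`` weighting (so the same code path applies with
    ``size_index_base = 1``after shifting).
    """
    total = counts.sum()
    out: dict[str, float] = {}
    if total == 0:
        return {}
    p = counts.astype(np.float64) / total
    b, m = counts.shape
    i = np.arange(1, b + 1, dtype=np.float64)[:, None]
    j = (np.arange(m, dtype=np.float64) + size_index_base)[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    iv = i.ravel()
    jv = j.ravel()
    out[names["short"]] = float((p / j**2).sum())
    out[names["long"]] = float((p * j**2).sum())
    out[names["low"]] = float((p / i**2).sum())
    out[names["high"]] = float((p * i**2).sum())
    out[names["short_low"]] = float((p / (i**2 * j**2)).sum())
    out[names["short_high"]] = float((p * i**2 / j**2).sum())
    out[names["long_low"]] = float((p * j**2 / i**2).sum())
    out[names["long_high"]] = float((p * (i * j) ** 2).sum())
    row_tot = counts.sum(axis=1).astype(np.float64)
    col_tot = counts.sum(axis=0).astype(np.float64)
    out[names["gln"]] = float((row_tot**2).sum() / total)
    out[names["sn"]] = float((col_tot**2).sum() / total)
    out[names["snn"]] = float((col_tot**2).sum() / total**2)
    mu_j = float((pj * jv).sum())
    out[names["size_var"]] = float((pj * (jv - mu_j) ** 2).sum())
    mu_i = float((pi * iv).sum())
    out[names["grey_var"]] = float((pi * (iv - mu_i) ** 2).sum())
    out[names["entropy"]] = _entropy2(p.ravel())
    if n_voxels is not None:
        out[names["percentage"]] = float(total / n_voxels)
    return out


def glrlm_features(matrix: GLRLMatrix) -> dict[str, float]:
    """The 15 run-length features."""
    raw = _weighted_matrix_features(
        matrix.counts,
        1,
        matrix.n_voxels,
        names={
            "short": "short_run_emphasis",
            "long": "long_run_emphasis",
            "low": "low_grey_level_run_emphasis",
            "high": "high_grey_level_run_emphasis",
            "short_low": "short_run_low_grey_level_emphasis",
            "short_high": "short_run_high_grey_level_emphasis",
            "long_low": "long_run_low_grey_level_emphasis",
            "long_high": "long_run_high_grey_level_emphasis",
            "gln": "grey_level_non_uniformity",
            "sn": "run_length_non_uniformity",
            "snn": "run_length_non_uniformity_normalized",
            "size_var": "run_variance",
            "grey_var": "grey_level_variance",
            "entropy": "run_entropy",
            "percentage": "run_percentage",
        },
    )
    if not raw:
        return {name: float("nan") for name in GLRLM_FEATURES}
    return {name: raw[name] for name in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# grey-level size-zone matrix
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def compute_glszm(levels: LevelMap) -> GLSZMatrix:
    """Zone-size counts: connected (3D, 26-connectivity) regions of equal
    level, tallied by (level, zone size).  Direction-free."""
    _require_levelmap(levels)
    b = levels.bin_count
    lv = levels.levels
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for v in np.unique(lv[levels.roi]):
        lab, n = ndimage.label(lv == v, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level.append((int(v), sizes))
        max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((b, max_size), dtype=np.int64)
    for v, sizes in sizes_by_level:
        np.add.at(counts, (v - 1, sizes - 1), 1)
    return GLSZMatrix(counts, b, levels.n_voxels)


GLSZM_FEATURES = (
    "small_area_emphasis",
    "large_area_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_area_low_grey_level_emphasis",
    "small_area_high_grey_level_emphasis",
    "large_area_low_grey_level_emphasis",
    "large_area_high_grey_level_emphasis",
    "zone_percentage",
    "zone_variance",
    "zone_entropy",
    "size_zone_non_uniformity",
    "size_zone_non_uniformity_normalized",
    "grey_level_non_uniformity",
)


def glszm_features(matrix: GLSZMatrix) -> dict[str, float]:
    """The 14 size-zone features."""
    raw = _weighted_matrix_features(
        matrix.counts,
        1,
        matrix.n_voxels,
        names={
            "short": "small_area_emphasis",
            "long": "large_area_emphasis",
            "low": "low_grey_level_zone_emphasis",
            "high": "high_grey_level_zone_emphasis",
            "short_low": "small_area_low_grey_level_emphasis",
            "short_high": "small_area_high_grey_level_emphasis",
            "long_low": "large_area_low_grey_level_emphasis",
            "long_high": "large_area_high_grey_level_emphasis",
            "gln": "grey_level_non_uniformity",
            "sn": "size_zone_non_uniformity",
            "snn": "size_zone_non_uniformity_normalized",
            "size_var": "zone_variance",
            "grey_var": "_unused_grey_var",
            "entropy": "zone_entropy",
            "percentage": "zone_percentage",
        },
    )
    if not raw:
        return {name: float("nan") for name in GLSZM_FEATURES}
    return {name: raw[name] for name in GLSZM_FEATURES}


# ---------------------------------------------------------------------------
# grey-level dependence matrix
# ---------------------------------------------------------------------------


def _kernel_offsets(kernel: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-kernel, kernel + 1)
        for dx in range(-kernel, kernel + 1)
        if (dy, dx) != (0, 0)
    ]


def compute_gldm(levels: LevelMap, params: TextureParams, alpha: int | None = None) -> GLDMatrix:
    """Dependence counts: for every ROI voxel, the number of in-plane
    neighbors within Chebyshev radius ``params.kernel`` whose level differs
    by at most ``alpha`` (default ``params.gldm_alpha``, 0 = exact level).
    Each voxel is tallied once as (level, dependence)."""
    _require_levelmap(levels)
    if alpha is None:
        alpha = params.gldm_alpha
    lv = levels.levels.astype(np.int64)
    dep = np.zeros(lv.shape, dtype=np.int64)
    for dy, dx in _kernel_offsets(params.kernel):
        dep += _dependence_contribution(lv, dy, dx, alpha)
    b = params.bin_count
    roi = levels.roi
    vox_lv = lv[roi] - 1
    vox_dep = dep[roi]
    max_dep = int(vox_dep.max()) if vox_dep.size else 0
    counts = np.zeros((b, max_dep + 1), dtype=np.int64)
    np.add.at(counts, (vox_lv, vox_dep), 1)
    return GLDMatrix(counts, b)


def _dependence_contribution(lv: np.ndarray, dy: int, dx: int, alpha: int) -> np.ndarray:
    """1 where a voxel has an in-ROI neighbor at (dy, dx) within alpha."""
    out = np.zeros(lv.shape, dtype=np.int64)
    nz, ny, nx = lv.shape
    y0, y1 = max(0, -dy), min(ny, ny - dy)
    x0, x1 = max(0, -dx), min(nx, nx - dx)
    if y0 >= y1 or x0 >= x1:
        return out
    a = lv[:, y0:y1, x0:x1]
    bn = lv[:, y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    match = (a > 0) & (bn > 0) & (np.abs(a - bn) <= alpha)
    out[:, y0:y1, x0:x1] = match
    return out


GLDM_FEATURES = (
    "small_dependence_emphasis",
    "large_dependence_emphasis",
    "low_grey_level_emphasis",
    "high_grey_level_emphasis",
    "small_dependence_low_grey_level_emphasis",
    "small_dependence_high_grey_level_emphasis",
    "large_dependence_low_grey_level_emphasis",
    "large_dependence_high_grey_level_emphasis",
    "dependence_non_uniformity",
    "dependence_non_uniformity_normalized",
    "dependence_entropy",
    "dependence_variance",
)


def gldm_features(matrix: GLDMatrix) -> dict[str, float]:
    """The 12 dependence features; dependence k is weighted as (k + 1), so a
    matrix with all mass at dependence 0 maximises small-dependence emphasis
    under the (k+1)^-2 weighting."""
    raw = _weighted_matrix_features(
        matrix.counts,
        1,  # dependence k occupies column k; base 1 realises the (k+1) weight
        None,
        names={
            "short": "small_dependence_emphasis",
            "long": "large_dependence_emphasis",
            "low": "low_grey_level_emphasis",
            "high": "high_grey_level_emphasis",
            "short_low": "small_dependence_low_grey_level_emphasis",
            "short_high": "small_dependence_high_grey_level_emphasis",
            "long_low": "large_dependence_low_grey_level_emphasis",
            "long_high": "large_dependence_high_grey_level_emphasis",
            "gln": "_unused_gln",
            "sn": "dependence_non_uniformity",
            "snn": "dependence_non_uniformity_normalized",
            "size_var": "dependence_variance",
            "grey_var": "_unused_grey_var",
            "entropy": "dependence_entropy",
        },
    )
    if not raw:
        return {name: float("nan") for name in GLDM_FEATURES}
    return {name: raw[name] for name in GLDM_FEATURES}


# ---------------------------------------------------------------------------
# neighborhood grey-tone difference statistics
# ---------------------------------------------------------------------------

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

_COARSENESS_CAP = 1e6  # sentinel when sum p_i s_i == 0 (texture-free ROI)


def compute_ngtdm(levels: LevelMap, params: TextureParams) -> NGTDMStats:
    """Per-level occurrence probability p_i and summed deviation s_i from the
    in-plane neighborhood mean (Chebyshev radius ``params.kernel``, center
    excluded).  Voxels with no in-ROI neighbor do not contribute."""
    _require_levelmap(levels)
    k = params.kernel
    w = 2 * k + 1
    lv = levels.levels.astype(np.float64)
    roi = levels.roi.astype(np.float64)
    size = (1, w, w)
    nb_sum = ndimage.uniform_filter(lv * roi, size=size, mode="constant", cval=0.0) * (w * w)
    nb_cnt = ndimage.uniform_filter(roi, size=size, mode="constant", cval=0.0) * (w * w)
    nb_sum = nb_sum - lv * roi
    nb_cnt = np.rint(nb_cnt - roi)
    valid = levels.roi & (nb_cnt >= 0.5)
    mean_nb = np.zeros_like(lv)
    np.divide(nb_sum, nb_cnt, out=mean_nb, where=nb_cnt >= 0.5)
    dev = np.abs(lv - mean_nb)
    vox_lv = levels.levels[valid].astype(np.int64)
    vox_dev = dev[valid]
    n_valid = int(valid.sum())
    if n_valid == 0:
        return NGTDMStats(np.empty(0, np.int64), np.empty(0), np.empty(0), 0, params.bin_count)
    occurring = np.unique(vox_lv)
    n_i = np.array([(vox_lv == v).sum() for v in occurring], dtype=np.float64)
    s_i = np.array([vox_dev[vox_lv == v].sum() for v in occurring], dtype=np.float64)
    return NGTDMStats(occurring, n_i / n_valid, s_i, n_valid, params.bin_count)


def ngtdm_features(levels: LevelMap, params: TextureParams) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength from the
    neighborhood grey-tone difference construction."""
    stats = compute_ngtdm(levels, params)
    out = {name: float("nan") for name in NGTDM_FEATURES}
    if stats.n_valid == 0:
        return out
    i = stats.levels.astype(np.float64)
    p, s = stats.p, stats.s
    ng = len(i)
    n = stats.n_valid
    ps = float((p * s).sum())
    out["coarseness"] = 1.0 / ps if ps > 0 else _COARSENESS_CAP
    if ng > 1:
        pi_, pj_ = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        out["contrast"] = float(
            (pi_ * pj_ * (ii - jj) ** 2).sum() / (ng * (ng - 1)) * (s.sum() / n)
        )
        denom = float(np.abs(ii * pi_ - jj * pj_).sum())
        out["busyness"] = ps / denom if denom > 0 else 0.0
        out["complexity"] = float(
            (np.abs(ii - jj) * (pi_ * s[:, None] + pj_ * s[None, :]) / (pi_ + pj_)).sum() / n
        )
        s_sum = float(s.sum())
        out["strength"] = (
            float(((pi_ + pj_) * (ii - jj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
        )
    else:
        out["contrast"] = 0.0
        out["busyness"] = 0.0
        out["complexity"] = 0.0
        out["strength"] = 0.0
    return out


# ---------------------------------------------------------------------------
# angle averaging helper
# ---------------------------------------------------------------------------


def average_feature_maps(maps: Iterable[Mapping[str, float]]) -> dict[str, float]:
    """Average per-angle (or per-distance) feature mappings key-by-key.

    NaN sentinels propagate: if a feature is undefined at any angle the
    average is NaN, which the screening filter then removes.
    """
    maps = list(maps)
    if not maps:
        raise ValidationError("no feature maps to average")
    keys = list(maps[0])
    for m in maps[1:]:
        if list(m) != keys:
            raise ValidationError("feature maps have mismatched keys")
    return {k: float(np.mean([m[k] for m in maps])) for k in keys}
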