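"""Reading, writing and intensity preprocessing of CT volumes and masks.

Volumes and masks are held as numpy arrays in ``(z, y, x)`` axis order
(slice-major, matching ``SimpleITK.GetArrayFromImage``) together with the
per-axis physical spacing in millimetres.  Supported on-disk dialects are
NIfTI-1 (``.nii``/``.nii.gz``) and NRRD (``.nrrd``); a mask must share its
volume's grid exactly — no implicit resampling is ever performed.

Intensity preprocessing is limited to min–max normalization of the whole
scan to the range [0, 1]; no other filtering is applied to the voxel data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "GeometryError",
    "FormatError",
    "ValidationError",
    "NamingError",
    "Volume3D",
    "Mask3D",
    "CaseRecord",
    "read_volume",
    "read_mask",
    "read_case",
    "write_volume",
    "write_mask",
    "write_case",
    "normalize_intensity",
    "write_feature_table",
    "read_feature_table",
    "read_label_file",
    "write_label_file",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".nrrd")

REGION_CLASSES = ("head", "body_tail")


class GeometryError(ValueError):
    """Raised when a mask and volume do not share the same grid."""


class FormatError(ValueError):
    """Raised when a file cannot be read as NIfTI-1 or NRRD."""


class ValidationError(ValueError):
    """Raised on invalid voxel data (e.g. non-finite intensities)."""


class NamingError(ValueError):
    """Raised on feature-name collisions when writing a feature table."""


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be three positive values, got {spacing}")
    return spacing


@dataclass
class Volume3D:
    """A scalar voxel grid with physical spacing.

    Parameters
    ----------
    voxels:
        3D array of intensities, axis order ``(z, y, x)``.
    spacing:
        Physical voxel size in mm per axis, same ``(z, y, x)`` order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"volume must be 3D, got ndim={self.voxels.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class Mask3D:
    """An integer label grid aligned to a :class:`Volume3D`.

    ``label_map`` maps each nonzero integer code to a semantic name
    (e.g. ``{1: "tumor"}`` or ``{1: "head", 2: "body", 3: "tail"}``).
    Code 0 is always background and never appears in the map.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_map: Mapping[int, str] = field(default_factory=lambda: {1: "foreground"})

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"mask must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = self.labels.astype(np.uint8)
            else:
                as_int = np.rint(self.labels)
                if not np.array_equal(as_int, self.labels):
                    raise ValidationError("mask grid must hold integer labels")
                self.labels = as_int.astype(np.int32)
        self.spacing = _check_spacing(self.spacing)
        self.label_map = dict(self.label_map)
        present = set(np.unique(self.labels).tolist()) - {0}
        undeclared = present - set(self.label_map)
        if undeclared:
            raise ValidationError(
                f"mask contains codes {sorted(undeclared)} not in label_map"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def foreground(self) -> np.ndarray:
        """Boolean array of all nonzero-labeled voxels."""
        return self.labels > 0

    def count(self) -> int:
        return int(np.count_nonzero(self.labels))


@dataclass
class CaseRecord:
    """One scan: normalized volume, tumor ROI, pancreas mask and class label."""

    case_id: str
    volume: Volume3D
    tumor_mask: Mask3D
    pancreas_mask: Mask3D
    region_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.region_label is not None and self.region_label not in REGION_CLASSES:
            raise ValidationError(
                f"region_label must be one of {REGION_CLASSES}, got {self.region_label!r}"
            )
        if self.tumor_mask.count() == 0:
            raise ValidationError(f"case {self.case_id}: tumor mask is empty")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _read_image(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if not any(str(path).endswith(ext) for ext in _SUPPORTED_EXT):
        raise FormatError(f"unsupported image format: {path} (expected .nii/.nii.gz/.nrrd)")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # SimpleITK raises bare RuntimeError
        raise FormatError(f"could not read {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got ndim={arr.ndim}")
    sx, sy, sz = img.GetSpacing()
    return arr, (float(sz), float(sy), float(sx))


def _write_image(arr: np.ndarray, spacing: Sequence[float], path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if not any(str(path).endswith(ext) for ext in _SUPPORTED_EXT):
        raise FormatError(f"unsupported image format: {path} (expected .nii/.nii.gz/.nrrd)")
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    sz, sy, sx = spacing
    img.SetSpacing((float(sx), float(sy), float(sz)))
    sitk.WriteImage(img, path)


def read_volume(path: str | os.PathLike) -> Volume3D:
    arr, spacing = _read_image(path)
    return Volume3D(arr.astype(np.float64), spacing)


def read_mask(path: str | os.PathLike, label_map: Optional[Mapping[int, str]] = None) -> Mask3D:
    arr, spacing = _read_image(path)
    if label_map is None:
        codes = sorted(set(np.unique(arr).tolist()) - {0})
        label_map = {int(c): f"label_{int(c)}" for c in codes} or {1: "foreground"}
    return Mask3D(arr, spacing, label_map)


def write_volume(volume: Volume3D, path: str | os.PathLike) -> None:
    _write_image(volume.voxels, volume.spacing, path)


def write_mask(mask: Mask3D, path: str | os.PathLike) -> None:
    _write_image(mask.labels.astype(np.int16), mask.spacing, path)


def _check_geometry(name: str, path, ref: Volume3D, arr: np.ndarray, spacing) -> None:
    if arr.shape != ref.voxels.shape:
        raise GeometryError(
            f"{name} {path}: shape {arr.shape} does not match volume shape {ref.voxels.shape}"
        )
    if not np.allclose(spacing, ref.spacing, rtol=1e-5, atol=1e-6):
        raise GeometryError(
            f"{name} {path}: spacing {spacing} does not match volume spacing {ref.spacing}"
        )


def read_case(
    volume_path: str | os.PathLike,
    tumor_mask_path: str | os.PathLike,
    pancreas_mask_path: str | os.PathLike,
    case_id: Optional[str] = None,
    region_label: Optional[str] = None,
) -> CaseRecord:
    """Load a volume with its aligned tumor and pancreas masks.

    Grids must match exactly; any shape or spacing mismatch raises a
    :class:`GeometryError` naming the offending file.  No resampling is
    performed.
    """
    volume = read_volume(volume_path)
    t_arr, t_spc = _read_image(tumor_mask_path)
    _check_geometry("tumor mask", tumor_mask_path, volume, t_arr, t_spc)
    p_arr, p_spc = _read_image(pancreas_mask_path)
    _check_geometry("pancreas mask", pancreas_mask_path, volume, p_arr, p_spc)
    tumor = Mask3D((t_arr > 0).astype(np.uint8), volume.spacing, {1: "tumor"})
    pancreas = Mask3D((p_arr > 0).astype(np.uint8), volume.spacing, {1: "pancreas"})
    if case_id is None:
        base = os.path.basename(os.fspath(volume_path))
        for ext in _SUPPORTED_EXT:
            if base.endswith(ext):
                base = base[: -len(ext)]
                break
        case_id = base
    return CaseRecord(case_id, volume, tumor, pancreas, region_label)


def write_case(case: CaseRecord, directory: str | os.PathLike, fmt: str = ".nii.gz") -> dict[str, str]:
    """Write a case's volume and masks into ``directory``; returns the paths."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "volume": os.path.join(directory, f"{case.case_id}_volume{fmt}"),
        "tumor": os.path.join(directory, f"{case.case_id}_tumor{fmt}"),
        "pancreas": os.path.join(directory, f"{case.case_id}_pancreas{fmt}"),
    }
    write_volume(case.volume, paths["volume"])
    write_mask(case.tumor_mask, paths["tumor"])
    write_mask(case.pancreas_mask, paths["pancreas"])
    return paths


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------


def normalize_intensity(volume: Volume3D) -> Volume3D:
    """Min–max rescale a volume so its minimum maps to 0 and maximum to 1.

    A constant volume maps to all zeros (a constant carries no texture
    signal; zero is the conventional fixed point).  The map is monotone and
    idempotent.  Non-finite voxels raise :class:`ValidationError`.
    """
    v = np.asarray(volume.voxels, dtype=np.float64)
    if not np.isfinite(v).all():
        raise ValidationError("volume contains non-finite voxels")
    lo = float(v.min())
    hi = float(v.max())
    if hi == lo:
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return Volume3D(out, volume.spacing)


# ---------------------------------------------------------------------------
# feature tables and label files
# ---------------------------------------------------------------------------


def write_feature_table(table, path: str | os.PathLike) -> None:
    """Write a feature table as CSV (one row per case, one column per feature).

    The header encodes each feature's family and (bin, kernel, angle,
    distance) provenance.  Raises :class:`NamingError` on duplicate feature
    names and :class:`ValidationError` on an empty table.
    """
    df = table.to_dataframe()
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError("refusing to write an empty feature table")
    cols = list(df.columns)
    if len(cols) != len(set(cols)):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise NamingError(f"duplicate feature descriptors: {dupes[:5]}")
    df.to_csv(os.fspath(path), index=True, index_label="case_id")


def read_feature_table(path: str | os.PathLike):
    from .feature_grid import FeatureTable  # local import to avoid a cycle

    return FeatureTable.from_csv(path)


def write_label_file(labels: Mapping[str, str], path: str | os.PathLike) -> None:
    """Write per-case region labels as a two-column CSV (case_id,region_label)."""
    with open(os.fspath(path), "w") as fh:
        fh.write("case_id,region_label\n")
        for case_id, lab in labels.items():
            if lab not in REGION_CLASSES:
                raise ValidationError(f"unknown region label {lab!r} for case {case_id}")
            fh.write(f"{case_id},{lab}\n")


def read_label_file(path: str | os.PathLike) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(os.fspath(path)) as fh:
        header = fh.readline().strip().split(",")
        if header[:2] != ["case_id", "region_label"]:
            raise FormatError(f"{path}: expected header 'case_id,region_label'")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            case_id, lab = line.split(",")[:2]
            if lab not in REGION_CLASSES:
                raise ValidationError(f"unknown region label {lab!r} for case {case_id}")
            labels[case_id] = lab
    return labels
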