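"""The radiomic parameter sweep: families x bin counts x kernels x angles.

Each texture family is swept over the grid axes it genuinely depends on:

=========  =============================  =====================
family     swept axes                     columns (full grid)
=========  =============================  =====================
glcm       bin x distance(1..kernel) x angle   20 x 8 x 5 x 4 = 3200
glrlm      bin x angle                    15 x 8 x 4 = 480
glszm      bin                            14 x 8     = 112
gldm       bin x kernel                   12 x 8 x 5 = 480
ngtdm      bin x kernel                    5 x 8 x 5 = 200
firstorder (none; entropy uses the        15
           grid's largest bin count)
shape      (none)                         20
=========  =============================  =====================

The full default grid therefore yields 4507 feature columns per tumor.
Every column carries its provenance in the descriptor string
``family__name__b{bins}.k{kernel}.a{angle}.d{distance}`` (axes a family
does not sweep are omitted).  Any family failure on a case is recorded as a
NaN sentinel in that case's row — extraction never aborts a row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .discretization import VALID_BIN_COUNTS, discretize
from .firstorder_shape import (
    FIRSTORDER_FEATURES,
    SHAPE_FEATURES,
    firstorder_features,
    shape_features,
)
from .io_preprocess import CaseRecord, Mask3D, ValidationError, Volume3D
from .texture_matrices import (
    ANGLES,
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    TextureParams,
    compute_glcm,
    compute_gldm,
    compute_glrlm,
    compute_glszm,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "FAMILIES",
    "FAMILY_FEATURES",
    "FeatureDescriptor",
    "GridSpec",
    "FeatureTable",
    "enumerate_descriptors",
    "descriptor_count",
    "extract_all",
    "extract_cohort",
]

FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_FEATURES,
    "shape": SHAPE_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}
FAMILIES = tuple(FAMILY_FEATURES)


@dataclass(frozen=True)
class FeatureDescriptor:
    """A feature column: family, name and its parameter provenance."""

    family: str
    name: str
    bin_count: Optional[int] = None
    kernel: Optional[int] = None
    angle: Optional[int] = None
    distance: Optional[int] = None

    def column(self) -> str:
        parts = [self.family, self.name]
        params = "".join(
            f".{tag}{val}"
            for tag, val in (
                ("b", self.bin_count),
                ("k", self.kernel),
                ("a", self.angle),
                ("d", self.distance),
            )
            if val is not None
        ).lstrip(".")
        if params:
            parts.append(params)
        return "__".join(parts)

    @classmethod
    def parse(cls, column: str) -> "FeatureDescriptor":
        parts = column.split("__")
        if len(parts) < 2:
            raise ValidationError(f"not a feature descriptor: {column!r}")
        family, name = parts[0], parts[1]
        kwargs: dict[str, int] = {}
        if len(parts) == 3:
            for token in parts[2].split("."):
                m = re.fullmatch(r"([bkad])(\d+)", token)
                if not m:
                    raise ValidationError(f"bad provenance token {token!r} in {column!r}")
                key = {"b": "bin_count", "k": "kernel", "a": "angle", "d": "distance"}[m.group(1)]
                kwargs[key] = int(m.group(2))
        return cls(family, name, **kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class GridSpec:
    """Which bin counts, kernels, angles and families to sweep."""

    bin_counts: tuple[int, ...] = VALID_BIN_COUNTS
    kernels: tuple[int, ...] = (1, 2, 3, 4, 5)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    families: tuple[str, ...] = FAMILIES

    def __post_init__(self) -> None:
        if not (self.bin_counts and self.kernels and self.angles and self.families):
            raise ValidationError("grid axes must be non-empty")
        for b in self.bin_counts:
            if b not in VALID_BIN_COUNTS:
                raise ValidationError(f"invalid bin count {b}")
        for k in self.kernels:
            if not 1 <= k <= 5:
                raise ValidationError(f"invalid kernel {k}")
        for a in self.angles:
            if a not in ANGLES:
                raise ValidationError(f"invalid angle {a}")
        for f in self.families:
            if f not in FAMILIES:
                raise ValidationError(f"unknown family {f!r}")

    @classmethod
    def single(cls, bin_count: int = 32, kernel: int = 1, angle: int = 0) -> "GridSpec":
        """A one-setting grid (one bin count, one kernel, one angle)."""
        return cls(bin_counts=(bin_count,), kernels=(kernel,), angles=(angle,))


def enumerate_descriptors(grid: GridSpec) -> list[FeatureDescriptor]:
    """All feature columns of a grid, in canonical order."""
    out: list[FeatureDescriptor] = []
    for family in grid.families:
        names = FAMILY_FEATURES[family]
        if family == "firstorder":
            out.extend(FeatureDescriptor(family, n) for n in names)
        elif family == "shape":
            out.extend(FeatureDescriptor(family, n) for n in names)
        elif family == "glcm":
            for b in grid.bin_counts:
                for d in grid.kernels:  # kernel bounds the offset distance
                    for a in grid.angles:
                        out.extend(
                            FeatureDescriptor(family, n, bin_count=b, angle=a, distance=d)
                            for n in names
                        )
        elif family == "glrlm":
            for b in grid.bin_counts:
                for a in grid.angles:
                    out.extend(
                        FeatureDescriptor(family, n, bin_count=b, angle=a) for n in names
                    )
        elif family == "glszm":
            for b in grid.bin_counts:
                out.extend(FeatureDescriptor(family, n, bin_count=b) for n in names)
        elif family in ("gldm", "ngtdm"):
            for b in grid.bin_counts:
                for k in grid.kernels:
                    out.extend(
                        FeatureDescriptor(family, n, bin_count=b, kernel=k) for n in names
                    )
    return out


def descriptor_count(grid: GridSpec) -> int:
    """Closed-form column count of a grid (asserted against enumeration in
    the test suite)."""
    nb, nk, na = len(grid.bin_counts), len(grid.kernels), len(grid.angles)
    total = 0
    for family in grid.families:
        m = len(FAMILY_FEATURES[family])
        if family in ("firstorder", "shape"):
            total += m
        elif family == "glcm":
            total += m * nb * nk * na
        elif family == "glrlm":
            total += m * nb * na
        elif family == "glszm":
            total += m * nb
        else:  # gldm, ngtdm
            total += m * nb * nk
    return total


# ---------------------------------------------------------------------------
# feature table container
# ---------------------------------------------------------------------------


class FeatureTable:
    """Cases x features, provenance-tagged.

    Thin wrapper over a :class:`pandas.DataFrame` whose index holds case ids
    and whose columns are descriptor strings.  Values may contain NaN
    sentinels for unusable features; the screening module filters them.
    """

    def __init__(self, frame: pd.DataFrame):
        cols = list(frame.columns)
        if len(cols) != len(set(cols)):
            raise ValidationError("duplicate feature descriptors in table")
        self.frame = frame

    # construction ---------------------------------------------------------
    @classmethod
    def from_rows(
        cls, case_ids: Sequence[str], rows: Sequence[Sequence[float]], descriptors: Sequence[FeatureDescriptor]
    ) -> "FeatureTable":
        cols = [d.column() for d in descriptors]
        return cls(pd.DataFrame(np.asarray(rows, dtype=np.float64), index=list(case_ids), columns=cols))

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, index_col="case_id")
        frame.index = frame.index.astype(str)
        return cls(frame)

    # views ----------------------------------------------------------------
    @property
    def case_ids(self) -> list[str]:
        return [str(c) for c in self.frame.index]

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def descriptors(self) -> list[FeatureDescriptor]:
        return [FeatureDescriptor.parse(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=np.float64)

    @property
    def n_cases(self) -> int:
        return self.frame.shape[0]

    @property
    def n_features(self) -> int:
        return self.frame.shape[1]

    def subset_columns(self, columns: Sequence[str]) -> "FeatureTable":
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"missing descriptors: {missing[:5]}")
        return FeatureTable(self.frame.loc[:, list(columns)].copy())

    def subset_cases(self, case_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.frame.loc[list(case_ids)].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return self.frame

    def to_csv(self, path) -> None:
        from .io_preprocess import write_feature_table

        write_feature_table(self, path)

    @classmethod
    def concat(cls, tables: Iterable["FeatureTable"]) -> "FeatureTable":
        frames = [t.frame for t in tables]
        return cls(pd.concat(frames, axis=0))

    def __len__(self) -> int:
        return self.n_cases


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def _crop_to_roi(volume: Volume3D, roi: np.ndarray, margin: int = 6):
    idx = np.argwhere(roi)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, roi.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return Volume3D(volume.voxels[sl], volume.spacing), roi[sl]


def extract_all(case: CaseRecord, grid: GridSpec = GridSpec()) -> FeatureTable:
    """Extract every grid feature for one case; returns a one-row table.

    Texture families are computed on the tumor ROI discretized at each bin
    count; shape is parameter-free; first-order is computed once (its
    entropy is binned at the grid's largest bin count).  Repeated extraction
    of the same case is bit-identical, and any family failure yields NaN
    sentinels for that family's columns rather than aborting the row.
    """
    descriptors = enumerate_descriptors(grid)
    values: dict[str, float] = {}
    roi_full = case.tumor_mask.foreground()
    if not roi_full.any():
        raise ValidationError(f"case {case.case_id}: empty tumor ROI")
    vol, roi = _crop_to_roi(case.volume, roi_full, margin=max(grid.kernels) + 1)
    roi_mask = Mask3D(roi.astype(np.uint8), vol.spacing, {1: "tumor"})

    if "firstorder" in grid.families:
        try:
            fo = firstorder_features(vol, roi, entropy_bins=max(grid.bin_counts))
        except Exception:
            fo = {n: float("nan") for n in FIRSTORDER_FEATURES}
        for n, v in fo.items():
            values[FeatureDescriptor("firstorder", n).column()] = v
    if "shape" in grid.families:
        try:
            sh = shape_features(roi_mask)
        except Exception:
            sh = {n: float("nan") for n in SHAPE_FEATURES}
        for n, v in sh.items():
            values[FeatureDescriptor("shape", n).column()] = v

    texture_families = [f for f in grid.families if f in ("glcm", "glrlm", "glszm", "gldm", "ngtdm")]
    for b in grid.bin_counts:
        if not texture_families:
            break
        levels = discretize(vol, roi, b)
        if "glcm" in texture_families:
            params = TextureParams(bin_count=b, kernel=max(grid.kernels), angles=grid.angles)
            for d in grid.kernels:
                for a in grid.angles:
                    try:
                        feats = glcm_features(compute_glcm(levels, params, a, d))
                    except Exception:
                        feats = {n: float("nan") for n in GLCM_FEATURES}
                    for n, v in feats.items():
                        values[
                            FeatureDescriptor("glcm", n, bin_count=b, angle=a, distance=d).column()
                        ] = v
        if "glrlm" in texture_families:
            for a in grid.angles:
                try:
                    feats = glrlm_features(compute_glrlm(levels, a))
                except Exception:
                    feats = {n: float("nan") for n in GLRLM_FEATURES}
                for n, v in feats.items():
                    values[FeatureDescriptor("glrlm", n, bin_count=b, angle=a).column()] = v
        if "glszm" in texture_families:
            try:
                feats = glszm_features(compute_glszm(levels))
            except Exception:
                feats = {n: float("nan") for n in GLSZM_FEATURES}
            for n, v in feats.items():
                values[FeatureDescriptor("glszm", n, bin_count=b).column()] = v
        for k in grid.kernels:
            params_k = TextureParams(bin_count=b, kernel=k, angles=grid.angles)
            if "gldm" in texture_families:
                try:
                    feats = gldm_features(compute_gldm(levels, params_k))
                except Exception:
                    feats = {n: float("nan") for n in GLDM_FEATURES}
                for n, v in feats.items():
                    values[FeatureDescriptor("gldm", n, bin_count=b, kernel=k).column()] = v
            if "ngtdm" in texture_families:
                try:
                    feats = ngtdm_features(levels, params_k)
                except Exception:
                    feats = {n: float("nan") for n in NGTDM_FEATURES}
                for n, v in feats.items():
                    values[FeatureDescriptor("ngtdm", n, bin_count=b, kernel=k).column()] = v

    row = [values[d.column()] for d in descriptors]
    return FeatureTable.from_rows([case.case_id], [row], descriptors)


def extract_cohort(cases: Iterable[CaseRecord], grid: GridSpec = GridSpec()) -> FeatureTable:
    """Extract the grid for every case and stack the rows into one table."""
    tables = [extract_all(case, grid) for case in cases]
    if not tables:
        raise ValidationError("no cases to extract")
    return FeatureTable.concat(tables)
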