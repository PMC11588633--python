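"""Synthetic phantom cohorts with the statistical structure of the real study.

Each case is a 3D grid holding an elongated, curved, tapering pancreas-like
tube (bulkier at the head end), a tumor placed in the head or the body/tail
section, and intensities built from smooth background variation plus
class-specific correlated noise inside the tumor.  The planted class
contrasts emulate what the CT analysis reports about pancreatic tumors:

* head tumors are smaller (equivalent-sphere diameters drawn uniformly
  from 2.4-3.1 cm) and hyperintense (+0.15 on the [0,1] scale by default);
* body/tail tumors are larger (5.6-6.1 cm) and darker than the
  surrounding gland;
* tumor texture differs by class through the correlation length of the
  in-tumor noise field (the minimal imaging stand-in for cellular-
  arrangement differences).

Volumes are quantized to 16-bit and min-max normalized to [0,1], and the
default cohort split is 58 head / 42 body-tail cases.  A *null* cohort puts
both classes through an identical generative process (no offset, shared
size range and texture) for type-I-error and chance-level-AUC calibration.
All randomness flows from a mandatory integer seed; cohorts are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_preprocess import CaseRecord, Mask3D, ValidationError, Volume3D, normalize_intensity

__all__ = ["PhantomSpec", "generate_cohort", "generate_null_cohort", "generate_case"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a phantom cohort.

    Diameter ranges are equivalent-sphere diameters in cm; the intensity
    offset is additive on the normalized [0,1] scale; texture correlation
    lengths are Gaussian-kernel sigmas in mm.
    """

    seed: int
    n_head: int = 58
    n_bodytail: int = 42
    head_diameter_range: tuple[float, float] = (2.4, 3.1)
    bodytail_diameter_range: tuple[float, float] = (5.6, 6.1)
    head_intensity_offset: float = 0.15
    head_texture_sigma_mm: float = 2.5
    bodytail_texture_sigma_mm: float = 5.0
    texture_amplitude: float = 0.06
    grid_shape: tuple[int, int, int] = (48, 96, 96)  # (z, y, x)
    spacing: tuple[float, float, float] = (2.5, 2.0, 2.0)  # mm

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_head < 2 or self.n_bodytail < 2:
            raise ValidationError("need at least 2 cases per class")
        for rng_ in (self.head_diameter_range, self.bodytail_diameter_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValidationError(f"diameter range must be positive and ordered: {rng_}")
        if any(s <= 0 for s in self.spacing) or any(n < 8 for n in self.grid_shape):
            raise ValidationError("invalid grid geometry")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _centerline(t: np.ndarray, rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Pancreas centerline in physical mm, head (bulky end) at t=0 and at
    the smaller-x side (patient-right convention)."""
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.spacing
    ext_x = nx * sx
    ext_y = ny * sy
    ext_z = nz * sz
    length = 0.68 * ext_x
    x = 0.15 * ext_x + length * t
    y = 0.5 * ext_y + 0.12 * ext_y * np.sin(np.pi * t) + rng.normal(0, 3.0) * np.sin(2 * np.pi * t)
    z = 0.5 * ext_z + 8.0 * (t - 0.5) + rng.normal(0, 2.0)
    return np.column_stack([z, np.atleast_1d(y), x])


def _pancreas_radius(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Taper from a bulky head (~14 mm) to a slim tail (~6 mm)."""
    base = 14.0 - 8.0 * t
    wobble = 0.8 * np.sin(3 * np.pi * t + rng.uniform(0, 2 * np.pi))
    return np.clip(base + wobble, 4.0, None)


def _paint_tube(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of balls along the centerline -> pancreas mask."""
    mask = np.zeros(spec.grid_shape, dtype=bool)
    spacing = np.asarray(spec.spacing)
    t = np.linspace(0.0, 1.0, 160)
    centers = _centerline(t, rng, spec)
    radii = _pancreas_radius(t, rng)
    for c, r in zip(centers, radii):
        lo = np.maximum(np.floor((c - r) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / spacing).astype(int) + 1, spec.grid_shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            *(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij"
        )
        pts = np.stack([zz, yy, xx], axis=-1) * spacing
        inside = ((pts - c) ** 2).sum(axis=-1) <= r * r
        mask[zz[inside], yy[inside], xx[inside]] = True
    return mask


def _smooth_noise(shape, sigma_vox, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-correlated noise field, normalized to unit variance."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = g.std()
    return g / sd if sd > 0 else g


def _tumor_mask(
    center_mm: np.ndarray,
    diameter_cm: float,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturbed ellipsoid of the requested equivalent-sphere diameter."""
    spacing = np.asarray(spec.spacing)
    r0 = diameter_cm * 10.0 / 2.0  # mm
    aniso = rng.uniform(0.85, 1.18, size=3)
    aniso /= np.prod(aniso) ** (1.0 / 3.0)  # volume-preserving
    semi = r0 * aniso
    lo = np.maximum(np.floor((center_mm - 1.4 * semi.max()) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + 1.4 * semi.max()) / spacing).astype(int) + 1, spec.grid_shape)
    if np.any(lo >= hi):
        raise ValidationError(
            "tumor does not fit the grid; enlarge grid_shape or shrink the diameter range"
        )
    grids = np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij")
    pts = np.stack(grids, axis=-1) * spacing
    u = np.sqrt((((pts - center_mm) / semi) ** 2).sum(axis=-1))
    bump = _smooth_noise(u.shape, sigma_vox=3.0, rng=rng)
    local = u <= 1.0 + 0.07 * bump
    mask = np.zeros(spec.grid_shape, dtype=bool)
    mask[tuple(slice(a, b) for a, b in zip(lo, hi))] = local
    if not mask.any():
        raise ValidationError("degenerate tumor mask (diameter below voxel size?)")
    return mask


# ---------------------------------------------------------------------------
# case and cohort generation
# ---------------------------------------------------------------------------


def generate_case(
    case_id: str,
    region: str,
    spec: PhantomSpec,
    rng: np.random.Generator,
    *,
    null_process: bool = False,
) -> CaseRecord:
    """One phantom case.  With ``null_process`` the class label is carried
    but has no influence on the generative process."""
    spacing = np.asarray(spec.spacing)
    pancreas = _paint_tube(spec, rng)

    if null_process:
        diameter = rng.uniform(3.5, 4.5)
        t_center = rng.uniform(0.10, 0.85)
        offset = 0.0
        sigma_mm = 0.5 * (spec.head_texture_sigma_mm + spec.bodytail_texture_sigma_mm)
    elif region == "head":
        diameter = rng.uniform(*spec.head_diameter_range)
        t_center = rng.uniform(0.06, 0.20)
        offset = spec.head_intensity_offset
        sigma_mm = spec.head_texture_sigma_mm
    else:
        diameter = rng.uniform(*spec.bodytail_diameter_range)
        t_center = rng.uniform(0.45, 0.85)
        offset = 0.0
        sigma_mm = spec.bodytail_texture_sigma_mm

    center = _centerline(np.array([t_center]), rng, spec)[0]
    tumor = _tumor_mask(center, diameter, spec, rng)

    # intensity model: smooth background, brighter gland, class-shifted
    # tumor base + correlated texture, mild sensor noise, 16-bit quantization
    vol = 0.32 + 0.05 * _smooth_noise(spec.grid_shape, sigma_vox=(2.0, 2.5, 2.5), rng=rng)
    vol[pancreas] += 0.06
    sigma_vox = tuple(sigma_mm / s for s in spec.spacing)
    texture = _smooth_noise(spec.grid_shape, sigma_vox=sigma_vox, rng=rng)
    tumor_base = 0.30 + offset
    vol[tumor] = tumor_base + spec.texture_amplitude * texture[tumor]
    vol += 0.01 * rng.standard_normal(spec.grid_shape)
    vol = np.clip(vol, 0.0, 1.0)
    quantized = np.rint(vol * 65535.0).astype(np.uint16)

    volume = normalize_intensity(Volume3D(quantized.astype(np.float64), tuple(spacing)))
    volume.voxels = volume.voxels.astype(np.float32)  # storage; math upcasts
    return CaseRecord(
        case_id=case_id,
        volume=volume,
        tumor_mask=Mask3D(tumor.astype(np.uint8), tuple(spacing), {1: "tumor"}),
        pancreas_mask=Mask3D(pancreas.astype(np.uint8), tuple(spacing), {1: "pancreas"}),
        region_label=region,
    )


def _cohort(spec: PhantomSpec, null_process: bool) -> list[CaseRecord]:
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_head + spec.n_bodytail
    children = ss.spawn(n_total)
    cases: list[CaseRecord] = []
    for i in range(n_total):
        region = "head" if i < spec.n_head else "body_tail"
        rng = np.random.default_rng(children[i])
        prefix = "null" if null_process else "case"
        cases.append(
            generate_case(f"{prefix}_{i:03d}_{region}", region, spec, rng, null_process=null_process)
        )
    return cases


def generate_cohort(spec: PhantomSpec) -> list[CaseRecord]:
    """A labeled cohort with the planted class contrasts (default 58 head +
    42 body/tail cases)."""
    return _cohort(spec, null_process=False)


def generate_null_cohort(spec: PhantomSpec) -> list[CaseRecord]:
    """A calibration cohort: identical generative process for both classes
    (no intensity offset, shared size range and texture), so any detected
    class difference is a false positive."""
    return _cohort(spec, null_process=True)
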