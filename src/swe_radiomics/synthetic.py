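"""Synthetic paired B-mode / SWE phantom cohorts.

Generates desk-scale cohorts with the statistical structure the downstream
analysis assumes: two lesion classes on a fatty background, where benign
masses are homogeneous and soft and malignant masses carry heterogeneous
speckle, higher stiffness, and a stiffer peritumoral rim (the maximum
stiffness area of a malignant mass sits in the peritumoral tissue, which is
why malignant SWE contours include adjacent tissue).  Lesions are smooth
star-convex blobs (random radial harmonics) rather than ellipses so that
ROI and segmentation code faces realistic boundaries.

Nothing here attempts acoustic realism; the generator exists so that every
pipeline stage is exercisable and testable without any image downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import matplotlib
import numpy as np
from scipy import ndimage

from .exceptions import DataError, InvalidSpecError
from .quant import Box, ElasticityMap

BIRADS_LEVELS = ("3", "4a", "4b", "4c", "5")

#: color ramp used for the SWE overlay: dark blue -> light blue -> green ->
#: orange -> red with increasing stiffness (matplotlib's "jet").
_SWE_CMAP = matplotlib.colormaps["jet"]


@dataclass
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Stiffness defaults put the two classes on either side of the ~46 kPa
    e_max working cutoff reported for breast masses: benign around 25 kPa,
    malignant around 120 kPa with a +40 kPa peritumoral rim.  Fat rests
    near 8 kPa.  ``texture_heterogeneity`` is the log-normal speckle sigma
    per class (benign, malignant).
    """

    n_benign: int = 20
    n_malignant: int = 20
    image_height: int = 96
    image_width: int = 128
    pixel_spacing: float = 0.15  # mm/px
    benign_stiffness_mean: float = 25.0  # kPa
    malignant_stiffness_mean: float = 120.0  # kPa
    stiffness_noise_sd: float = 8.0  # kPa
    rim_stiffness_boost: float = 40.0  # kPa added in the peritumoral annulus
    fat_stiffness_mean: float = 8.0  # kPa
    texture_heterogeneity: tuple[float, float] = (0.05, 0.25)
    boundary_irregularity: tuple[float, float] = (0.08, 0.18)  # (benign, malignant)
    lesion_diameter_range: tuple[float, float] = (5.0, 9.0)  # mm
    rim_width_mm: float = 1.0
    birads_error_rate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise InvalidSpecError("case counts must be non-negative")
        if self.image_height <= 0 or self.image_width <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        if self.pixel_spacing <= 0:
            raise InvalidSpecError("pixel spacing must be positive")
        if self.malignant_stiffness_mean < self.benign_stiffness_mean:
            raise InvalidSpecError(
                "malignant stiffness mean must be >= benign mean "
                "(equal means give a deliberate null cohort)"
            )
        lo, hi = self.lesion_diameter_range
        if not (0 < lo <= hi):
            raise InvalidSpecError("lesion diameter range must be positive and ordered")
        if self.stiffness_noise_sd < 0 or self.rim_stiffness_boost < 0:
            raise InvalidSpecError("noise SD and rim boost must be non-negative")


@dataclass
class Case:
    """One patient's paired image bundle."""

    case_id: str
    bmode: np.ndarray  # (H, W) uint8 grayscale
    swe_color: np.ndarray  # (H, W, 3) uint8
    elasticity: ElasticityMap
    bmode_mask: np.ndarray  # bool
    swe_mask: np.ndarray  # bool
    fat_mask: np.ndarray  # bool, reference fatty tissue inside the SWE box
    swe_box: Box
    label: str  # "benign" | "malignant"
    spacing: float  # mm/px
    birads_like: str | None = None

    def validate(self) -> None:
        shape = self.bmode.shape
        for name in ("bmode_mask", "swe_mask", "fat_mask"):
            if getattr(self, name).shape != shape:
                raise DataError(f"{name} shape differs from the image raster")
        if self.swe_color.shape[:2] != shape or self.elasticity.values.shape != shape:
            raise DataError("SWE rasters must share the B-mode raster shape")
        if not self.bmode_mask.any() or not self.swe_mask.any():
            raise DataError("lesion masks must be non-empty")
        box = self.swe_box.as_mask(shape)
        if (self.swe_mask & ~box).any():
            raise DataError("SWE lesion mask must lie inside the acquisition box")
        if (self.fat_mask & self.swe_mask).any():
            raise DataError("fat mask must be disjoint from the SWE lesion mask")
        if self.label not in ("benign", "malignant"):
            raise DataError(f"unknown label {self.label!r}")


def stiffness_ramp_position(elasticity: np.ndarray, display_max: float) -> np.ndarray:
    """Normalized position on the color ramp: kPa clipped to [0, display_max] -> [0, 1]."""
    if display_max <= 0:
        raise ValueError("display_max must be positive")
    elasticity = np.asarray(elasticity, dtype=np.float64)
    if np.any(elasticity < 0):
        raise DataError("elasticity values must be non-negative")
    return np.clip(elasticity / display_max, 0.0, 1.0)


def render_swe_colormap(elasticity: np.ndarray, display_max: float = 180.0) -> np.ndarray:
    """Render a kPa map as the clinical stiffness overlay (uint8 RGB).

    The ramp runs dark blue (soft) through light blue, green and orange to
    red (stiff); values above ``display_max`` clamp to the red end.
    """
    pos = stiffness_ramp_position(elasticity, display_max)
    rgba = _SWE_CMAP(pos)
    return (rgba[..., :3] * 255).round().astype(np.uint8)


def perturb_mask(mask: np.ndarray, magnitude: float, seed: int = 0) -> np.ndarray:
    """Displace a mask boundary by a smooth random field of amplitude <= magnitude (px).

    Stands in for a second rater / repeat segmentation session: the signed
    Euclidean distance to the boundary is thresholded against a
    Gaussian-smoothed noise field scaled to the requested amplitude.
    Deterministic in ``seed``; ``magnitude=0`` returns the mask unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be non-empty")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return mask.copy()
    signed = np.where(
        mask,
        ndimage.distance_transform_edt(mask),
        -ndimage.distance_transform_edt(~mask),
    )
    rng = np.random.default_rng(seed)
    fld = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=4.0)
    fld *= magnitude / np.abs(fld).max()
    out = signed > fld
    if not out.any():  # pathological amplitude vs lesion size: keep the deepest pixel
        out = signed >= signed.max()
    return out


def _star_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    mean_radius_px: float,
    rng: np.random.Generator,
    irregularity: float = 0.10,
    n_harmonics: int = 5,
) -> np.ndarray:
    """Smooth star-convex blob: radius modulated by random low-order harmonics."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    theta = np.arctan2(dy, dx)
    modulation = np.zeros(shape)
    for k in range(1, n_harmonics + 1):
        amp = rng.normal(0.0, irregularity / k)
        phase = rng.uniform(0, 2 * np.pi)
        modulation += amp * np.cos(k * theta + phase)
    r_theta = mean_radius_px * np.clip(1.0 + modulation, 0.4, 1.8)
    return dy * dy + dx * dx <= r_theta * r_theta


def _speckle(shape, rng, sigma_log: float, smooth: float = 1.0) -> np.ndarray:
    """Multiplicative log-normal speckle field with mild spatial correlation."""
    f = rng.normal(0.0, 1.0, size=shape)
    if smooth > 0:
        f = ndimage.gaussian_filter(f, sigma=smooth)
        sd = f.std()
        if sd > 0:
            f /= sd
    return np.exp(sigma_log * f)


def _draw_birads(label: str, error_rate: float, rng: np.random.Generator) -> str:
    """Noisy ordinal category: a label-conditional draw over the 3..5 scale.

    This is plumbing for the comparison statistics only; it does not model
    radiologist behaviour.
    """
    if label == "malignant":
        weights = np.array([0.02, 0.08, 0.20, 0.40, 0.30])
    else:
        weights = np.array([0.55, 0.30, 0.10, 0.04, 0.01])
    if rng.uniform() < error_rate:
        weights = weights[::-1]
    return str(rng.choice(BIRADS_LEVELS, p=weights / weights.sum()))


def _generate_case(spec: CohortSpec, label: str, case_id: str, rng: np.random.Generator) -> Case:
    h, w = spec.image_height, spec.image_width
    sp = spec.pixel_spacing
    inset_r, inset_c = max(2, h // 12), max(2, w // 12)
    box = Box(inset_r, inset_c, h - inset_r, w - inset_c)

    diameter_mm = rng.uniform(*spec.lesion_diameter_range)
    radius_px = diameter_mm / 2.0 / sp
    rim_px = max(1, int(round(spec.rim_width_mm / sp)))
    # keep lesion + rim comfortably inside the acquisition box
    max_r = min(radius_px, 0.5 * min(box.height, box.width) - rim_px - 2)
    radius_px = max(3.0, max_r)
    jitter = 0.08 * min(h, w)
    center = (
        h / 2 + rng.uniform(-jitter, jitter),
        w / 2 + rng.uniform(-jitter, jitter),
    )
    malignant = label == "malignant"
    # malignant masses are more irregular (spiculated margins)
    lesion = _star_blob((h, w), center, radius_px, rng,
                        irregularity=spec.boundary_irregularity[1 if malignant else 0])

    texture = spec.texture_heterogeneity[1 if malignant else 0]
    lesion_mean = spec.malignant_stiffness_mean if malignant else spec.benign_stiffness_mean

    background = spec.fat_stiffness_mean * _speckle((h, w), rng, 0.15, smooth=2.0)
    lesion_field = lesion_mean * _speckle((h, w), rng, texture, smooth=1.5)
    elasticity = np.where(lesion, lesion_field, background)
    elasticity += rng.normal(0.0, spec.stiffness_noise_sd, size=(h, w)) * lesion
    rim = ndimage.binary_dilation(lesion, iterations=rim_px) & ~lesion
    if malignant:
        elasticity += spec.rim_stiffness_boost * rim
    elasticity = np.clip(elasticity, 0.0, None).astype(np.float32)

    # B-mode: mid-gray fatty speckle, hypoechoic lesion; malignant lesions get
    # heavier internal speckle (heterogeneous echotexture).
    bg = 0.45 * _speckle((h, w), rng, 0.12, smooth=1.0)
    lesion_echo = 0.22 * _speckle((h, w), rng, max(texture, 0.05), smooth=0.8)
    bmode_f = np.where(lesion, lesion_echo, bg)
    bmode = (np.clip(bmode_f, 0.0, 1.0) * 255).round().astype(np.uint8)

    # contouring convention: non-homogeneous (stiff-rimmed) masses are
    # contoured to include the adjacent peritumoral tissue, homogeneous
    # masses at the mass border — keyed to the actual rim stiffening, so a
    # null cohort carries no label-dependent contouring artifact
    swe_mask = (lesion | rim) if (malignant and spec.rim_stiffness_boost > 0) else lesion
    swe_mask &= box.as_mask((h, w))
    fat_gap = ndimage.binary_dilation(lesion, iterations=rim_px + 3)
    fat_mask = box.as_mask((h, w)) & ~fat_gap
    fat_mask[: box.top + 1] = False  # stay off the box border so ROIs fit

    emap = ElasticityMap(elasticity, sp, box)
    return Case(
        case_id=case_id,
        bmode=bmode,
        swe_color=render_swe_colormap(elasticity),
        elasticity=emap,
        bmode_mask=lesion,
        swe_mask=swe_mask,
        fat_mask=fat_mask,
        swe_box=box,
        label=label,
        spacing=sp,
        birads_like=_draw_birads(label, spec.birads_error_rate, rng),
    )


def generate_cohort(spec: CohortSpec, case_id_prefix: str = "case") -> list[Case]:
    """Generate ``n_benign + n_malignant`` cases, bit-reproducible from ``spec.seed``.

    Benign and malignant cases are interleaved deterministically by index
    (benign first), each drawn from its own seeded substream so that the
    cohort is stable under changes to the other class count.
    """
    spec.validate()
    labels = ["benign"] * spec.n_benign + ["malignant"] * spec.n_malignant
    cases = []
    for i, label in enumerate(labels):
        rng = np.random.default_rng([spec.seed % (2**31 - 1), i])
        case = _generate_case(spec, label, f"{case_id_prefix}_{i:04d}", rng)
        case.validate()
        cases.append(case)
    return cases


def null_spec(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with identical class distributions (no signal)."""
    return replace(
        spec,
        malignant_stiffness_mean=spec.benign_stiffness_mean,
        rim_stiffness_boost=0.0,
        texture_heterogeneity=(spec.texture_heterogeneity[0], spec.texture_heterogeneity[0]),
        boundary_irregularity=(spec.boundary_irregularity[0], spec.boundary_irregularity[0]),
        birads_error_rate=0.5,
    )
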