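"""Quantitative shear-wave elastography (SWE) parameters.

Works on a per-pixel Young's modulus map (kPa) and reproduces the clinical
measurement protocol for solid breast masses: a small round ROI (2 mm^2 by
default) placed within or adjacent to the mass so as to capture the maximum
stiffness area, a same-sized round ROI in normal fatty tissue inside the
acquisition box, and a mass-encompassing round ROI for the stiffness
standard deviation.  The four derived parameters are

* ``e_max``   - maximum elasticity in the max-stiffness ROI (kPa)
* ``e_mean``  - mean elasticity in the max-stiffness ROI (kPa)
* ``e_ratio`` - lesion-ROI mean divided by fat-ROI mean (dimensionless)
* ``e_sd``    - standard deviation over the mass-encompassing ROI (kPa)

Each parameter is measured in triplicate; the triplicate is collapsed by
taking the maximum of ``e_max`` and the median of the other three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DataError, PlacementError, UndefinedStatisticError


class Box(NamedTuple):
    """Axis-aligned rectangle, half-open pixel ranges [top, bottom) x [left, right)."""

    top: int
    left: int
    bottom: int
    right: int

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    def contains_point(self, row: float, col: float) -> bool:
        return self.top <= row < self.bottom and self.left <= col < self.right

    def as_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.top : self.bottom, self.left : self.right] = True
        return m


@dataclass
class ElasticityMap:
    """Per-pixel Young's modulus in kPa plus acquisition geometry."""

    values: np.ndarray  # 2-D float array, kPa
    spacing: float  # mm per pixel
    acquisition_box: Box

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise DataError("elasticity map must be a 2-D raster")
        if np.any(self.values < 0):
            raise DataError("elasticity values must be non-negative (kPa)")
        if not self.spacing > 0:
            raise DataError("pixel spacing must be positive (mm/px)")
        if not isinstance(self.acquisition_box, Box):
            self.acquisition_box = Box(*self.acquisition_box)


@dataclass(frozen=True)
class CircularROI:
    """Round measurement ROI in pixel coordinates."""

    center: tuple[int, int]  # (row, col)
    radius: float  # px
    area: float  # mm^2


@dataclass(frozen=True)
class QuantSWEParams:
    e_max: float
    e_mean: float
    e_ratio: float
    e_sd: float


def roi_radius_px(area_mm2: float, spacing: float) -> float:
    """Radius in pixels of a circle with the given physical area.

    area = pi * (radius_px * spacing)^2  =>  radius_px = sqrt(area/pi) / spacing
    """
    if area_mm2 <= 0 or spacing <= 0:
        raise ValueError("area and spacing must be positive")
    return math.sqrt(area_mm2 / math.pi) / spacing


def _disc(radius: float) -> np.ndarray:
    """Boolean disc kernel of the given pixel radius (center pixel included)."""
    r = int(math.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= radius * radius


def circle_mask(shape: tuple[int, int], roi: CircularROI) -> np.ndarray:
    """Boolean raster of the pixels covered by ``roi``."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = roi.center
    return (yy - r0) ** 2 + (xx - c0) ** 2 <= roi.radius * roi.radius


def _circle_fits_inside(valid_region: np.ndarray, radius: float) -> np.ndarray:
    """Centers whose full disc lies inside ``valid_region`` (binary erosion)."""
    return ndimage.binary_erosion(
        valid_region, structure=_disc(radius), border_value=0
    )


def _scan_order_argmax(score: np.ndarray, valid: np.ndarray, tol: float = 1e-9) -> tuple[int, int]:
    """First center (row-major) whose score is within ``tol`` of the best.

    The tolerance absorbs float summation noise so that physically tied
    centers obey the documented smallest-row-then-column tie-break.
    """
    masked = np.where(valid, score, -np.inf)
    best = masked.max()
    if not np.isfinite(best):
        raise PlacementError("no admissible ROI center")
    rows, cols = np.nonzero(masked >= best - tol)
    return int(rows[0]), int(cols[0])


def _disc_means(values: np.ndarray, radius: float) -> np.ndarray:
    """Mean elasticity of the disc centered at every pixel (exact summation)."""
    kernel = _disc(radius).astype(np.float64)
    sums = ndimage.correlate(values.astype(np.float64), kernel, mode="constant", cval=0.0)
    return sums / kernel.sum()


def place_max_stiffness_roi(
    emap: ElasticityMap, lesion_mask: np.ndarray, roi_area: float = 2.0
) -> CircularROI:
    """Place the round ROI that captures the maximum stiffness area.

    Candidate centers lie within the lesion mask dilated by one ROI radius
    ("within or adjacent to the mass"), with the whole circle inside the
    acquisition box.  Among candidates the circle with the highest mean
    elasticity wins; exact ties resolve to the smallest row, then column.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.shape != emap.values.shape:
        raise DataError("lesion mask shape must match the elasticity map")
    if not lesion_mask.any():
        raise PlacementError("empty lesion mask")
    box_mask = emap.acquisition_box.as_mask(emap.values.shape)
    if not lesion_mask[box_mask].any():
        raise PlacementError("lesion lies outside the acquisition box")

    radius = roi_radius_px(roi_area, emap.spacing)
    near_lesion = ndimage.binary_dilation(lesion_mask, structure=_disc(radius))
    inside_box = _circle_fits_inside(box_mask, radius)
    valid = near_lesion & inside_box
    if not valid.any():
        raise PlacementError("ROI circle does not fit near the lesion inside the box")
    means = _disc_means(emap.values, radius)
    center = _scan_order_argmax(means, valid)
    return CircularROI(center=center, radius=radius, area=roi_area)


def place_fat_roi(
    emap: ElasticityMap,
    fat_mask: np.ndarray,
    roi_area: float = 2.0,
    lesion_mask: np.ndarray | None = None,
) -> CircularROI:
    """Place the reference ROI in normal fatty tissue inside the acquisition box.

    The circle must lie fully inside ``fat_mask`` (and the box).  When a
    lesion mask is supplied the center farthest from the lesion is chosen;
    ties resolve in scan order.
    """
    fat_mask = np.asarray(fat_mask, dtype=bool)
    if fat_mask.shape != emap.values.shape:
        raise DataError("fat mask shape must match the elasticity map")
    radius = roi_radius_px(roi_area, emap.spacing)
    box_mask = emap.acquisition_box.as_mask(emap.values.shape)
    valid = _circle_fits_inside(fat_mask & box_mask, radius)
    if not valid.any():
        raise PlacementError("no fatty-tissue region can contain the ROI circle")
    if lesion_mask is not None and np.asarray(lesion_mask).any():
        distance = ndimage.distance_transform_edt(~np.asarray(lesion_mask, dtype=bool))
    else:
        distance = np.zeros_like(emap.values, dtype=np.float64)
    center = _scan_order_argmax(distance, valid, tol=0.0)
    return CircularROI(center=center, radius=radius, area=roi_area)


def max_inscribed_circle(lesion_mask: np.ndarray, spacing: float) -> CircularROI:
    """Largest circle inscribed in the lesion mask (via distance transform).

    Used as the mass-encompassing round ROI over which ``e_sd`` is taken.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise PlacementError("empty lesion mask")
    dist = ndimage.distance_transform_edt(lesion_mask)
    center = _scan_order_argmax(dist, lesion_mask, tol=0.0)
    radius = float(dist[center])
    return CircularROI(center=center, radius=radius, area=math.pi * (radius * spacing) ** 2)


def compute_quant_params(
    emap: ElasticityMap,
    lesion_roi: CircularROI,
    fat_roi: CircularROI,
    mass_roi: CircularROI,
    sd_ddof: int = 0,
) -> QuantSWEParams:
    """Evaluate the four quantitative parameters on placed ROIs.

    ``sd_ddof=0`` gives the population standard deviation for ``e_sd``
    (the device convention is not public; pass 1 for the sample form).
    """
    values = emap.values.astype(np.float64)
    lesion_px = values[circle_mask(values.shape, lesion_roi)]
    fat_px = values[circle_mask(values.shape, fat_roi)]
    mass_px = values[circle_mask(values.shape, mass_roi)]
    if lesion_px.size == 0 or fat_px.size == 0 or mass_px.size == 0:
        raise PlacementError("an ROI covers no pixels")
    fat_mean = float(fat_px.mean())
    if fat_mean == 0:
        raise UndefinedStatisticError("fat ROI mean elasticity is zero; e_ratio undefined")
    lesion_mean = float(lesion_px.mean())
    return QuantSWEParams(
        e_max=float(lesion_px.max()),
        e_mean=lesion_mean,
        e_ratio=lesion_mean / fat_mean,
        e_sd=float(mass_px.std(ddof=sd_ddof)),
    )


def aggregate_repeats(triplet: Sequence[QuantSWEParams]) -> QuantSWEParams:
    """Collapse a triplicate: max of e_max, median of the other parameters."""
    if len(triplet) != 3:
        raise ValueError(f"exactly 3 repeated measurements required, got {len(triplet)}")
    return QuantSWEParams(
        e_max=max(p.e_max for p in triplet),
        e_mean=float(np.median([p.e_mean for p in triplet])),
        e_ratio=float(np.median([p.e_ratio for p in triplet])),
        e_sd=float(np.median([p.e_sd for p in triplet])),
    )


def measure_case(
    emap: ElasticityMap,
    lesion_mask: np.ndarray,
    fat_mask: np.ndarray,
    roi_area: float = 2.0,
    n_repeats: int = 3,
    jitter_sd: float = 2.0,
    seed: int = 0,
    sd_ddof: int = 0,
) -> QuantSWEParams:
    """Triplicate measurement with seeded acquisition jitter.

    Each repeat adds zero-mean Gaussian noise (``jitter_sd`` kPa, clipped at
    zero) to the map before ROI placement, emulating repeated acquisitions;
    repeats are then aggregated with :func:`aggregate_repeats`.
    """
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        noisy = np.clip(
            emap.values + rng.normal(0.0, jitter_sd, size=emap.values.shape), 0.0, None
        )
        m = ElasticityMap(noisy, emap.spacing, emap.acquisition_box)
        lesion_roi = place_max_stiffness_roi(m, lesion_mask, roi_area)
        fat_roi = place_fat_roi(m, fat_mask, roi_area, lesion_mask=lesion_mask)
        mass_roi = max_inscribed_circle(lesion_mask, m.spacing)
        repeats.append(compute_quant_params(m, lesion_roi, fat_roi, mass_roi, sd_ddof=sd_ddof))
    return aggregate_repeats(repeats)


def quant_table(cases, roi_area: float = 2.0, jitter_sd: float = 2.0, seed: int = 0) -> pd.DataFrame:
    """Per-case aggregated quantitative parameters for a cohort of cases."""
    rows = []
    for i, case in enumerate(cases):
        params = measure_case(
            case.elasticity,
            case.swe_mask,
            case.fat_mask,
            roi_area=roi_area,
            jitter_sd=jitter_sd,
            seed=(seed * 100003 + i) % (2**31 - 1),
        )
        rows.append(
            {
                "case_id": case.case_id,
                "label": case.label,
                "e_max": params.e_max,
                "e_mean": params.e_mean,
                "e_ratio": params.e_ratio,
                "e_sd": params.e_sd,
            }
        )
    return pd.DataFrame(rows)
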