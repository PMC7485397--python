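"""Case-bundle I/O, network-input patch extraction, and segmentation agreement.

A case is stored as a per-case directory of plain rasters (float TIFF for
the elasticity map, PNG for the B-mode image, SWE overlay and 0/255 masks)
tied together by a cohort-level ``manifest.csv``.  Masks may also be NIfTI
(``.nii``/``.nii.gz``) on the read path, since manual segmentations are
commonly exported that way.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

from .exceptions import DataError, FormatError, NoLesionError
from .quant import Box, ElasticityMap
from .synthetic import Case

#: network input size as (height, width); the full-scale geometry is
#: landscape 302 x 430, reduced desk-scale runs configure a smaller size.
DEFAULT_PATCH_SIZE = (302, 430)

MANIFEST_COLUMNS = [
    "case_id", "label", "spacing", "birads_like", "swe_box",
    "bmode", "swe_color", "elasticity", "bmode_mask", "swe_mask", "fat_mask",
    "rater", "session",
]


@dataclass
class PatchInput:
    """Fixed-size 3-channel network input in [0, 1]."""

    pixels: np.ndarray  # (H, W, 3) float32 in [0, 1]
    source_modality: str  # "bmode" | "swe"
    case_id: str

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError("patch must be a 3-channel raster")
        if self.source_modality not in ("bmode", "swe"):
            raise FormatError(f"unknown modality {self.source_modality!r}")


@dataclass
class RaterSegmentations:
    """Masks of one case keyed by (rater, session)."""

    case_id: str
    modality: str
    masks: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.masks:
            raise FormatError("at least one segmentation required")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise FormatError("all segmentations of a case must share one shape")


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) between binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise FormatError("masks must share one shape")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise DataError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / total


def classify_dice_band(d: float) -> str:
    """Agreement band of a Dice value.

    Bands are closed on their printed two-decimal endpoints
    (0.75-1.00 excellent, 0.50-0.74 good, 0.25-0.49 moderate, <0.25 poor);
    values in the unprinted gaps fall to the lower band.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("Dice value must be in [0, 1]")
    if d >= 0.75:
        return "excellent"
    if d >= 0.50:
        return "good"
    if d >= 0.25:
        return "moderate"
    return "poor"


def extract_patch(
    image: np.ndarray,
    mask: np.ndarray,
    margin: int = 0,
    target_size: tuple[int, int] = DEFAULT_PATCH_SIZE,
    source_modality: str = "bmode",
    case_id: str = "",
) -> PatchInput:
    """Crop the mask's bounding box and resize it to the network input size.

    The box is expanded by ``margin`` pixels and clipped to the image, the
    crop is resampled bilinearly to ``target_size`` (height, width) with no
    aspect preservation, and intensities are min-max scaled to [0, 1]
    per patch (a constant crop maps to all zeros).  Grayscale inputs are
    replicated to 3 channels; masks are used for the box only, never
    resampled.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise FormatError("mask shape must match the image")
    if not mask.any():
        raise NoLesionError("cannot extract a patch from an empty mask")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + 1 + margin, image.shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + 1 + margin, image.shape[1])
    crop = image[r0:r1, c0:c1].astype(np.float64)
    if crop.ndim == 2:
        crop = np.repeat(crop[:, :, None], 3, axis=2)
    out = resize(
        crop, (*target_size, 3), order=1, preserve_range=True, anti_aliasing=False
    )
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)
    return PatchInput(out.astype(np.float32), source_modality, case_id)


# ---------------------------------------------------------------------------
# case bundle I/O


def _read_mask(path: Path) -> np.ndarray:
    if not path.exists():
        raise IOError(f"missing mask file: {path}")
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        return np.squeeze(data) > 0
    return iio.imread(path) > 0


def _box_to_str(box: Box) -> str:
    return f"{box.top}:{box.left}:{box.bottom}:{box.right}"


def _box_from_str(s: str) -> Box:
    return Box(*(int(v) for v in s.split(":")))


def write_case(case_dir: str | os.PathLike, case: Case) -> dict:
    """Write one case bundle; returns its manifest row (relative paths)."""
    case.validate()
    d = Path(case_dir)
    d.mkdir(parents=True, exist_ok=True)
    iio.imwrite(d / "bmode.png", case.bmode)
    iio.imwrite(d / "swe_color.png", case.swe_color)
    tifffile.imwrite(d / "elasticity.tif", case.elasticity.values.astype(np.float32))
    for name in ("bmode_mask", "swe_mask", "fat_mask"):
        iio.imwrite(d / f"{name}.png", (getattr(case, name).astype(np.uint8) * 255))
    return {
        "case_id": case.case_id,
        "label": case.label,
        "spacing": case.spacing,
        "birads_like": case.birads_like or "",
        "swe_box": _box_to_str(case.swe_box),
        "bmode": f"{d.name}/bmode.png",
        "swe_color": f"{d.name}/swe_color.png",
        "elasticity": f"{d.name}/elasticity.tif",
        "bmode_mask": f"{d.name}/bmode_mask.png",
        "swe_mask": f"{d.name}/swe_mask.png",
        "fat_mask": f"{d.name}/fat_mask.png",
        "rater": "r1",
        "session": "s1",
    }


def read_case(cohort_dir: str | os.PathLike, row: pd.Series | dict) -> Case:
    """Reconstruct a Case from a manifest row; validates every invariant."""
    root = Path(cohort_dir)

    def p(key: str) -> Path:
        path = root / str(row[key])
        if not path.exists():
            raise IOError(f"missing file: {path}")
        return path

    bmode = iio.imread(p("bmode"))
    swe_color = iio.imread(p("swe_color"))
    elasticity = tifffile.imread(p("elasticity")).astype(np.float32)
    if np.any(elasticity < 0):
        raise DataError("elasticity TIFF contains negative values")
    masks = {}
    for name in ("bmode_mask", "swe_mask", "fat_mask"):
        m = _read_mask(p(name))
        if m.shape != bmode.shape:
            raise FormatError(f"{name} shape {m.shape} does not match raster {bmode.shape}")
        masks[name] = m
    spacing = float(row["spacing"])
    box = _box_from_str(str(row["swe_box"]))
    birads = str(row["birads_like"]) or None
    if birads in ("", "nan", "None"):
        birads = None
    case = Case(
        case_id=str(row["case_id"]),
        bmode=bmode,
        swe_color=swe_color,
        elasticity=ElasticityMap(elasticity, spacing, box),
        bmode_mask=masks["bmode_mask"],
        swe_mask=masks["swe_mask"],
        fat_mask=masks["fat_mask"],
        swe_box=box,
        label=str(row["label"]),
        spacing=spacing,
        birads_like=birads,
    )
    case.validate()
    return case


def write_cohort(cohort_dir: str | os.PathLike, cases: list[Case]) -> Path:
    """Write all case bundles plus the cohort manifest; returns the manifest path."""
    root = Path(cohort_dir)
    root.mkdir(parents=True, exist_ok=True)
    rows = [write_case(root / c.case_id, c) for c in cases]
    manifest = root / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(cohort_dir: str | os.PathLike) -> list[Case]:
    root = Path(cohort_dir)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise IOError(f"missing file: {manifest}")
    df = pd.read_csv(manifest, dtype=str)
    return [read_case(root, row) for _, row in df.iterrows()]


def case_io(path: str | os.PathLike, mode: str, case: Case | None = None):
    """Single-entry read/write for one case directory (``manifest.csv`` inside)."""
    root = Path(path)
    if mode == "write":
        if case is None:
            raise ValueError("write mode requires a case")
        row = write_case(root, case)
        row = {**row, **{k: Path(v).name for k, v in row.items()
                         if k in ("bmode", "swe_color", "elasticity",
                                  "bmode_mask", "swe_mask", "fat_mask")}}
        pd.DataFrame([row], columns=MANIFEST_COLUMNS).to_csv(root / "manifest.csv", index=False)
        return root / "manifest.csv"
    if mode == "read":
        df = pd.read_csv(root / "manifest.csv", dtype=str)
        return read_case(root, df.iloc[0])
    raise ValueError(f"unknown mode {mode!r}")
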