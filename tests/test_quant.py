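"""Quantitative SWE parameters: ROI placement vs brute force, aggregation rules."""

import math

import numpy as np
import pytest

from swe_radiomics.exceptions import PlacementError, UndefinedStatisticError
from swe_radiomics.quant import (Box, CircularROI, ElasticityMap, QuantSWEParams,
                                 aggregate_repeats, circle_mask,
                                 compute_quant_params, max_inscribed_circle,
                                 place_fat_roi,
                                 place_max_stiffness_roi, quant_table,
                                 roi_radius_px)
from swe_radiomics.synthetic import CohortSpec, generate_cohort


def disc_mask(shape, center, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r


def brute_force_max_roi(emap, lesion_mask, roi_area):
    """Independent exhaustive search over every candidate center."""
    radius = roi_radius_px(roi_area, emap.spacing)
    h, w = emap.values.shape
    best = (-np.inf, None)
    box = emap.acquisition_box
    dil = disc_mask((h, w), (0, 0), 0)  # placeholder
    from scipy import ndimage

    rr = int(math.floor(radius))
    yy, xx = np.mgrid[-rr : rr + 1, -rr : rr + 1]
    struct = (yy * yy + xx * xx) <= radius * radius
    near = ndimage.binary_dilation(lesion_mask, structure=struct)
    for r0 in range(h):
        for c0 in range(w):
            if not near[r0, c0]:
                continue
            cm = circle_mask((h, w), CircularROI((r0, c0), radius, roi_area))
            rows, cols = np.nonzero(cm)
            if (rows.min() < box.top or rows.max() >= box.bottom
                    or cols.min() < box.left or cols.max() >= box.right):
                continue
            mean = emap.values[cm].mean()
            if mean > best[0] + 1e-9:
                best = (mean, (r0, c0))
    return best[1]


def test_roi_radius_formula():
    # 2 mm^2 at 0.1 mm/px: sqrt(2/pi)/0.1
    assert roi_radius_px(2.0, 0.1) == pytest.approx(math.sqrt(2 / math.pi) / 0.1, rel=1e-12)
    assert roi_radius_px(2.0, 0.1) == pytest.approx(7.98, abs=0.005)


def test_placement_matches_brute_force():
    rng = np.random.default_rng(4)
    values = rng.uniform(5, 50, size=(48, 48)).astype(np.float32)
    emap = ElasticityMap(values, 0.2, Box(2, 2, 46, 46))
    lesion = disc_mask((48, 48), (24, 22), 9)
    roi = place_max_stiffness_roi(emap, lesion, roi_area=2.0)
    assert roi.center == brute_force_max_roi(emap, lesion, 2.0)


def test_uniform_map_tie_breaks_to_scan_order():
    emap = ElasticityMap(np.full((40, 40), 30.0), 0.2, Box(1, 1, 39, 39))
    lesion = disc_mask((40, 40), (20, 20), 8)
    roi = place_max_stiffness_roi(emap, lesion, roi_area=2.0)
    assert roi.center == brute_force_max_roi(emap, lesion, 2.0)
    # first admissible center in scan order sits above the lesion center
    assert roi.center[0] < 20


def test_hot_disc_attracts_roi():
    # hot disc radius equals the ROI radius (~3.99 px at 0.2 mm/px), so the
    # only circle covering the whole hot area is the one centered on it
    values = np.full((60, 60), 10.0, dtype=np.float32)
    hot_center = (30, 33)
    values[disc_mask((60, 60), hot_center, roi_radius_px(2.0, 0.2))] = 200.0
    emap = ElasticityMap(values, 0.2, Box(2, 2, 58, 58))
    lesion = disc_mask((60, 60), (30, 30), 10)
    roi = place_max_stiffness_roi(emap, lesion, roi_area=2.0)
    assert roi.center == hot_center
    assert roi.center == brute_force_max_roi(emap, lesion, 2.0)


def test_lesion_outside_box_is_placement_error():
    emap = ElasticityMap(np.full((40, 40), 10.0), 0.2, Box(0, 0, 20, 20))
    lesion = disc_mask((40, 40), (32, 32), 5)
    with pytest.raises(PlacementError):
        place_max_stiffness_roi(emap, lesion, roi_area=2.0)


class TestFatROI:
    def test_circle_disjoint_from_lesion(self):
        emap = ElasticityMap(np.full((60, 60), 8.0), 0.2, Box(2, 2, 58, 58))
        lesion = disc_mask((60, 60), (30, 30), 8)
        fat = emap.acquisition_box.as_mask((60, 60)) & ~disc_mask((60, 60), (30, 30), 12)
        roi = place_fat_roi(emap, fat, 2.0, lesion_mask=lesion)
        assert not (circle_mask((60, 60), roi) & lesion).any()

    def test_narrow_strip_infeasible(self):
        emap = ElasticityMap(np.full((40, 40), 8.0), 0.2, Box(1, 1, 39, 39))
        fat = np.zeros((40, 40), bool)
        fat[5:7, 5:35] = True  # 2 px tall << ROI diameter (~7 px at 0.2 mm/px)
        with pytest.raises(PlacementError):
            place_fat_roi(emap, fat, 2.0)

    def test_tie_breaks_to_scan_order(self):
        emap = ElasticityMap(np.full((40, 40), 8.0), 0.2, Box(0, 0, 40, 40))
        fat = np.ones((40, 40), bool)
        roi = place_fat_roi(emap, fat, 2.0)  # no lesion: all distances zero
        r = int(math.floor(roi.radius))
        assert roi.center == (r, r)  # first center whose circle fits


class TestComputeParams:
    def test_constant_map(self):
        emap = ElasticityMap(np.full((30, 30), 50.0), 0.2, Box(0, 0, 30, 30))
        roi = CircularROI((15, 15), 4.0, 2.0)
        p = compute_quant_params(emap, roi, CircularROI((5, 5), 4.0, 2.0), roi)
        assert p == QuantSWEParams(50.0, 50.0, 1.0, 0.0)

    def test_ratio_division(self):
        values = np.full((30, 60), 10.58, dtype=np.float64)
        values[:, :30] = 210.0
        emap = ElasticityMap(values, 0.2, Box(0, 0, 30, 60))
        lesion_roi = CircularROI((15, 12), 4.0, 2.0)
        fat_roi = CircularROI((15, 45), 4.0, 2.0)
        p = compute_quant_params(emap, lesion_roi, fat_roi, lesion_roi)
        assert p.e_mean == pytest.approx(210.0, abs=1e-4)
        assert round(p.e_ratio, 2) == 19.85

    def test_two_pixel_sd_conventions(self):
        # radius-1 circle at (0,0) of a 1x2 raster covers exactly both pixels
        emap = ElasticityMap(np.array([[10.0, 20.0]]), 0.2, Box(0, 0, 1, 2))
        roi = CircularROI((0, 0), 1.0, 2.0)
        pop = compute_quant_params(emap, roi, roi, roi, sd_ddof=0)
        samp = compute_quant_params(emap, roi, roi, roi, sd_ddof=1)
        assert pop.e_sd == pytest.approx(5.0)
        assert samp.e_sd == pytest.approx(math.sqrt(50), abs=1e-9)

    def test_zero_fat_mean_undefined(self):
        emap = ElasticityMap(np.zeros((20, 20)), 0.2, Box(0, 0, 20, 20))
        roi = CircularROI((10, 10), 3.0, 2.0)
        with pytest.raises(UndefinedStatisticError):
            compute_quant_params(emap, roi, roi, roi)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(5, 80, (40, 40))
        emap = ElasticityMap(values, 0.2, Box(0, 0, 40, 40))
        lesion_roi = CircularROI((20, 20), 4.0, 2.0)
        fat_roi = CircularROI((8, 8), 4.0, 2.0)
        mass_roi = CircularROI((20, 20), 7.0, 6.0)
        p0 = compute_quant_params(emap, lesion_roi, fat_roi, mass_roi)
        c = 25.0
        p1 = compute_quant_params(
            ElasticityMap(values + c, 0.2, Box(0, 0, 40, 40)),
            lesion_roi, fat_roi, mass_roi)
        assert p1.e_max == pytest.approx(p0.e_max + c, rel=1e-6)
        assert p1.e_mean == pytest.approx(p0.e_mean + c, rel=1e-6)
        assert p1.e_sd == pytest.approx(p0.e_sd, abs=1e-4)
        assert abs(p1.e_ratio - 1) < abs(p0.e_ratio - 1)  # ratio shrinks toward 1


def test_max_inscribed_circle_of_disc():
    lesion = disc_mask((50, 50), (25, 25), 10)
    roi = max_inscribed_circle(lesion, spacing=0.2)
    assert roi.center == (25, 25)
    assert roi.radius == pytest.approx(10, abs=1.0)


class TestAggregate:
    def test_max_and_median_rules(self):
        triplet = [
            QuantSWEParams(100, 50, 3.0, 9.0),
            QuantSWEParams(90, 60, 4.0, 11.0),
            QuantSWEParams(110, 55, 5.0, 10.0),
        ]
        agg = aggregate_repeats(triplet)
        assert agg == QuantSWEParams(110, 55, 4.0, 10.0)

    def test_idempotent_on_identical(self):
        p = QuantSWEParams(80, 40, 2.0, 6.0)
        assert aggregate_repeats([p, p, p]) == p

    def test_arity(self):
        p = QuantSWEParams(80, 40, 2.0, 6.0)
        with pytest.raises(ValueError):
            aggregate_repeats([p, p])


def test_cohort_group_separation_under_wide_gap():
    spec = CohortSpec(n_benign=8, n_malignant=8, benign_stiffness_mean=25.0,
                      malignant_stiffness_mean=120.0, stiffness_noise_sd=8.0, seed=13)
    cases = generate_cohort(spec)
    df = quant_table(cases, seed=2)
    gm = df.groupby("label")["e_max"].mean()
    assert gm["malignant"] > gm["benign"]
    # every malignant case individually exceeds the benign mean under this gap
    assert df[df.label == "malignant"]["e_max"].min() > gm["benign"]
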