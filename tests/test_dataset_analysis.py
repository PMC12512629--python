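"""Box-area statistics, size-class shift, chi-square, heatmaps,
crown coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from wsldetect.dataset_analysis import (
    COCO_MEDIUM_MAX,
    COCO_SMALL_MAX,
    absolute_heatmap,
    area_stats,
    assign_to_tooth,
    chi_square_2x2,
    coco_size_class,
    crown_coverage,
    downscale_shift,
    peripheral_mass_fraction,
    relative_heatmap,
)
from wsldetect.slicing import proportional_resize
from wsldetect.synthetic import GeneratorConfig, iter_images

from conftest import box


class TestAreaStats:
    def test_one_box_per_coco_class(self):
        s = area_stats([100.0, 2000.0, 10000.0])
        assert (s.n_small, s.n_medium, s.n_large) == (1, 1, 1)

    def test_single_box_collapsed_quantiles(self):
        s = area_stats([box(0, 0, 10, 30)])
        assert s.median == s.q1 == s.q3 == 300

    def test_linear_interpolation_median(self):
        s = area_stats([1.0, 2.0, 3.0, 4.0])
        assert s.median == pytest.approx(2.5)
        assert s.q1 == pytest.approx(1.75)

    def test_class_boundaries_half_open(self):
        # small < 1024 <= medium < 9216 <= large (1024 = 32^2, 9216 = 96^2)
        assert coco_size_class(1023.0) == "small"
        assert coco_size_class(1024.0) == "medium"
        assert coco_size_class(9215.0) == "medium"
        assert coco_size_class(9216.0) == "large"
        s = area_stats([1023.0, 1024.0, 9215.0, 9216.0])
        assert (s.n_small, s.n_medium, s.n_large) == (1, 2, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            area_stats([])


class TestDownscaleShift:
    TR = proportional_resize(4000, 3000, 640)

    def test_median_area_crosses_small_boundary(self):
        before, after = downscale_shift([2898.0] * 5, self.TR)
        assert before.median == pytest.approx(2898)
        assert after.median == pytest.approx(2898 * 0.16**2)  # 74.19
        assert before.n_small == 0 and after.n_small == 5

    def test_scale_one_identity(self):
        tr = proportional_resize(640, 640, 640)
        before, after = downscale_shift([500.0, 2000.0], tr)
        assert before == after

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_small_fraction_nondecreasing_under_downscale(self, seed):
        rng = np.random.default_rng(seed)
        areas = list(rng.lognormal(8, 1, size=30))
        scale = float(rng.uniform(0.1, 1.0))
        tr = proportional_resize(1000, 1000, int(1000 * scale))
        before, after = downscale_shift(areas, tr)
        assert after.small_fraction >= before.small_fraction


class TestChiSquare:
    def test_no_association_zero(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        stat, _ = chi_square_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[5, 5], [0, 0]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 200, size=(2, 2))
        stat, p = chi_square_2x2(table)
        ref = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestAbsoluteHeatmap:
    def test_full_image_box_uniform(self):
        hm = absolute_heatmap([box(0, 0, 100, 80)], [(100, 80)], grid_size=8)
        assert hm.values == pytest.approx(np.ones((8, 8)))

    def test_empty_all_zero(self):
        hm = absolute_heatmap([], [], grid_size=8)
        assert not hm.values.any()

    def test_mass_conservation(self):
        rng = np.random.default_rng(2)
        boxes, dims = [], []
        for _ in range(20):
            w, h = int(rng.integers(50, 200)), int(rng.integers(50, 200))
            x0, y0 = rng.uniform(0, w - 10), rng.uniform(0, h - 10)
            boxes.append(box(x0, y0, x0 + rng.uniform(1, w - x0),
                             y0 + rng.uniform(1, h - y0)))
            dims.append((w, h))
        g = 16
        hm = absolute_heatmap(boxes, dims, grid_size=g)
        expected = sum(b.area / (w * h) for b, (w, h) in zip(boxes, dims)) * g * g
        assert hm.values.sum() == pytest.approx(expected)


class TestRelativeHeatmap:
    def test_affine_mapping_into_unit_square(self):
        tooth = box(100, 200, 200, 400)
        lesion = box(150, 380, 170, 400)
        hm = relative_heatmap([lesion], [tooth], grid_size=10)
        # relative extent x in [0.5, 0.7], y in [0.9, 1.0]
        ys, xs = np.nonzero(hm.values)
        assert xs.min() == 5 and xs.max() == 6
        assert ys.min() == 9 and ys.max() == 9

    def test_lesion_equal_to_tooth_fills_square(self):
        t = box(10, 10, 50, 90)
        hm = relative_heatmap([t], [t], grid_size=6)
        assert hm.values == pytest.approx(np.ones((6, 6)))

    def test_unassignable_lesion_dropped_and_counted(self):
        hm = relative_heatmap([box(500, 500, 520, 520)], [box(0, 0, 100, 100)],
                              grid_size=4)
        assert hm.n_dropped == 1
        assert not hm.values.any()

    def test_assignment_by_max_intersection(self):
        small = box(0, 0, 10, 10)
        big = box(5, 0, 200, 200)
        lesion = box(4, 0, 9, 5)  # 20 px in small... 4x5 in big
        assert assign_to_tooth(lesion, [small, big]) == 0

    def test_generator_output_is_peripherally_biased(self, preset_cfg):
        total = None
        for _, rec in iter_images(preset_cfg, 8, seed=77):
            hm = relative_heatmap(rec.boxes("wsl"), rec.boxes("tooth"),
                                  grid_size=32)
            total = hm.values if total is None else total + hm.values
            assert hm.n_dropped == 0  # every lesion sits inside a tooth
        from wsldetect.dataset_analysis import Heatmap

        pooled = Heatmap(values=total, frame="tooth")
        frac = peripheral_mass_fraction(pooled, band=0.25)
        central = 1 - frac
        assert frac > central  # periphery carries the majority of the mass


class TestCrownCoverage:
    TOOTH = box(0, 0, 100, 100)

    def test_lesion_equal_to_tooth(self):
        assert crown_coverage([self.TOOTH], self.TOOTH) == pytest.approx(1.0)

    def test_two_disjoint_lesions(self):
        les = [box(10, 10, 20, 20), box(50, 50, 60, 60)]
        assert crown_coverage(les, self.TOOTH) == pytest.approx(0.02)

    def test_overlapping_lesions_counted_once(self):
        les = [box(10, 10, 30, 30), box(10, 10, 30, 30)]
        assert crown_coverage(les, self.TOOTH) == pytest.approx(0.04)

    def test_lesion_clipped_to_tooth(self):
        assert crown_coverage([box(90, 90, 120, 120)], self.TOOTH) == \
            pytest.approx(0.01)

    def test_disjoint_lesion_zero(self):
        assert crown_coverage([box(200, 200, 220, 220)], self.TOOTH) == 0.0
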