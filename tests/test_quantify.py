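"""Exclusion, area measurement, binning and agreement statistics."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hequant import Calibration
from hequant.quantify import (
    ExclusionBox,
    agreement_stats,
    apply_exclusions,
    bin_percentages,
    bland_altman,
    compare_methods,
    correlation_coefficient,
    icc_agreement,
    load_exclusion_boxes,
    measure_area,
    pearson_correlation,
    percent_detected,
    validate_grading_table,
)

CAL = Calibration(mm_per_pixel=0.01)


class TestExclusions:
    def test_empty_box_list_is_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 20)) > 0.5
        assert np.array_equal(apply_exclusions(m, []), m)

    def test_whole_frame_box_empties_mask(self):
        m = np.ones((20, 20), dtype=bool)
        assert not apply_exclusions(m, [ExclusionBox(0, 0, 20, 20)]).any()

    def test_overlapping_boxes_remove_union(self):
        """Brute-force per-pixel check of the removed region."""
        rng = np.random.default_rng(1)
        m = rng.random((20, 20)) > 0.4
        boxes = [ExclusionBox(2, 3, 10, 12), ExclusionBox(7, 8, 15, 18)]
        out = apply_exclusions(m, boxes)
        for y in range(20):
            for x in range(20):
                inside = any(b.x0 <= x < b.x1 and b.y0 <= y < b.y1 for b in boxes)
                assert out[y, x] == (m[y, x] and not inside)

    def test_out_of_bounds_box_warned_and_ignored(self, caplog):
        m = np.ones((10, 10), dtype=bool)
        with caplog.at_level(logging.WARNING, logger="hequant"):
            out = apply_exclusions(m, [ExclusionBox(50, 50, 60, 60)])
        assert out.all()
        assert "ignored" in caplog.text

    def test_never_adds_and_idempotent(self):
        rng = np.random.default_rng(2)
        m = rng.random((15, 15)) > 0.5
        boxes = [ExclusionBox(0, 0, 7, 7), ExclusionBox(5, 5, 30, 30)]
        once = apply_exclusions(m, boxes)
        assert once.sum() <= m.sum()
        assert np.array_equal(apply_exclusions(once, boxes), once)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ExclusionBox(5, 5, 5, 9)

    def test_load_csv_and_json(self, tmp_path):
        csv = tmp_path / "boxes.csv"
        csv.write_text("x0,y0,x1,y1\n1,2,3,4\n5,6,9,10\n")
        assert load_exclusion_boxes(csv) == [ExclusionBox(1, 2, 3, 4), ExclusionBox(5, 6, 9, 10)]
        js = tmp_path / "boxes.json"
        js.write_text('[{"x0": 1, "y0": 2, "x1": 3, "y1": 4}]')
        assert load_exclusion_boxes(js) == [ExclusionBox(1, 2, 3, 4)]
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing"):
            load_exclusion_boxes(bad)


class TestAreas:
    def test_hundred_pixels_at_ten_micron(self):
        m = np.zeros((30, 30), dtype=bool)
        m[:10, :10] = True
        rep = measure_area(m, CAL)
        assert rep.pixel_count == 100
        assert rep.area_mm2 == pytest.approx(0.01)
        assert rep.n_components == 1

    def test_empty_mask(self):
        rep = measure_area(np.zeros((10, 10), dtype=bool), CAL)
        assert rep.pixel_count == 0 and rep.area_mm2 == 0.0 and rep.n_components == 0
        assert rep.components == ()

    def test_two_separated_squares(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:5, 2:5] = True
        m[10:13, 10:13] = True
        rep = measure_area(m, CAL)
        assert rep.n_components == 2
        assert [c[0] for c in rep.components] == [9, 9]
        assert sum(c[0] for c in rep.components) == rep.pixel_count

    def test_diagonal_touch_is_one_component_with_8conn(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2, 2] = m[3, 3] = True
        assert measure_area(m, CAL).n_components == 1
        assert measure_area(m, CAL, connectivity=4).n_components == 2

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(3)
        a = rng.random((16, 16)) > 0.6
        b = (rng.random((16, 16)) > 0.6) & ~a
        assert measure_area(a | b, CAL).area_mm2 == pytest.approx(
            measure_area(a, CAL).area_mm2 + measure_area(b, CAL).area_mm2
        )

    def test_missing_calibration_instructs_user(self):
        with pytest.raises(ValueError, match="mm_per_pixel"):
            measure_area(np.ones((5, 5), dtype=bool), None)

    def test_compare_methods_sign_convention(self):
        m = np.zeros((40, 40), dtype=bool)
        m[:10, :10] = True  # proposed: 100 px = 0.01 mm^2
        prop = measure_area(m, CAL)
        m2 = np.zeros((40, 40), dtype=bool)
        m2[:5, :10] = True  # baseline: 50 px = 0.005 mm^2
        base = measure_area(m2, CAL)
        diff = compare_methods(base, prop)
        assert diff.difference_mm2 == pytest.approx(-0.005)  # baseline underestimates
        assert diff.ratio == pytest.approx(0.5)
        same = compare_methods(prop, prop)
        assert same.difference_mm2 == 0.0

    def test_compare_methods_degenerate_and_mismatch(self):
        empty = measure_area(np.zeros((10, 10), dtype=bool), CAL)
        d = compare_methods(empty, empty)
        assert d.ratio is None and not d.ratio_defined
        other = measure_area(np.zeros((10, 10), dtype=bool), Calibration(0.02))
        with pytest.raises(ValueError, match="calibration"):
            compare_methods(empty, other)


class TestPercentages:
    def test_extremes_and_half(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[:4, :] = True
        assert percent_detected(truth, truth) == 100.0
        assert percent_detected(~truth, truth) == 0.0
        half = truth.copy()
        half[:2, :] = False
        assert percent_detected(half, truth) == 50.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percent_detected(np.ones((5, 5), bool), np.zeros((5, 5), bool))

    def test_binning_convention(self):
        assert bin_percentages([10, 45, 75, 95]) == (1, 1, 1, 1)
        assert bin_percentages([30]) == (0, 1, 0, 0)   # 30 belongs to 30-60
        assert bin_percentages([90, 100]) == (0, 0, 0, 2)
        assert bin_percentages([]) == (0, 0, 0, 0)
        with pytest.raises(ValueError):
            bin_percentages([50, 101])


class TestCorrelation:
    def test_identical_series(self):
        assert correlation_coefficient([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal_series(self):
        assert correlation_coefficient([1, 0], [0, 1]) == 0.0

    def test_printed_formula_fixture(self):
        # sum(xy) = 3 + 4 + 3 = 10; sum(x^2) = sum(y^2) = 14
        assert correlation_coefficient([1, 2, 3], [3, 2, 1]) == pytest.approx(10 / 14)

    def test_uncentered_differs_from_pearson(self):
        x, y = [1, 2, 3], [3, 2, 1]
        assert pearson_correlation(x, y) == pytest.approx(-1.0)
        assert correlation_coefficient(x, y) > 0

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=12),
           st.floats(0.1, 10), st.floats(0.1, 10))
    def test_positive_scale_invariance_and_bound(self, xs, a, b):
        x = np.asarray(xs)
        y = np.asarray(xs)[::-1] + 1.0
        if (x * x).sum() == 0 or (y * y).sum() == 0:
            return
        cc = correlation_coefficient(x, y)
        assert -1.0 <= cc <= 1.0
        assert correlation_coefficient(a * x, b * y) == pytest.approx(cc, abs=1e-9)

    def test_zero_series_rejected(self):
        with pytest.raises(ValueError):
            correlation_coefficient([0, 0], [1, 2])


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman([3, 4, 5], [3, 4, 5])
        assert (ba.bias, ba.lower_loa, ba.upper_loa) == (0.0, 0.0, 0.0)

    def test_plus_minus_one(self):
        ba = bland_altman([1, 0], [0, 1])
        assert ba.bias == 0.0
        assert ba.upper_loa == pytest.approx(1.96 * np.sqrt(2))
        assert ba.lower_loa == pytest.approx(-1.96 * np.sqrt(2))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(30), rng.random(30)
        base = bland_altman(x, y)
        shifted = bland_altman(x + 2.5, y)
        assert shifted.bias == pytest.approx(base.bias + 2.5)
        assert shifted.upper_loa - shifted.lower_loa == pytest.approx(
            base.upper_loa - base.lower_loa
        )

    def test_ordering_invariant(self):
        ba = bland_altman([1, 5, 2], [2, 3, 9])
        assert ba.lower_loa <= ba.bias <= ba.upper_loa

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1], [2])


def _grading_table(rng=None, n=30, noise=0.0, offset=0.0):
    rng = rng or np.random.default_rng(0)
    base = rng.uniform(20, 95, n)
    rows = []
    for grader in "AB":
        for session in (1, 2):
            vals = np.clip(base + rng.normal(0, noise, n) + offset, 0, 100)
            rows += [
                {"image_id": f"img{i:02d}", "grader": grader, "session": session,
                 "percent_detected": v}
                for i, v in enumerate(vals)
            ]
    return pd.DataFrame(rows)


class TestICC:
    def test_duplicated_columns_give_unity(self):
        table = _grading_table(noise=0.0)
        assert icc_agreement(table, "intra", "A") == pytest.approx(1.0)
        assert icc_agreement(table, "inter") == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(7)
        rows = []
        for session in (1, 2):
            for i in range(200):
                rows.append({"image_id": i, "grader": "A", "session": session,
                             "percent_detected": rng.uniform(0, 100)})
        icc = icc_agreement(pd.DataFrame(rows), "intra", "A")
        assert abs(icc) < 0.2

    def test_small_noise_high_agreement(self):
        rng = np.random.default_rng(8)
        table = _grading_table(rng, n=50, noise=1.0)  # sigma = 1% of range
        assert icc_agreement(table, "intra", "A") > 0.95

    def test_incomplete_design_lists_missing(self):
        table = _grading_table().iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            icc_agreement(table, "intra", "B")

    def test_table_validation(self):
        table = _grading_table()
        with pytest.raises(ValueError, match="missing columns"):
            validate_grading_table(table.drop(columns=["session"]))
        dup = pd.concat([table, table.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_grading_table(dup)
        bad = table.copy()
        bad.loc[0, "percent_detected"] = 150.0
        with pytest.raises(ValueError, match="\\[0, 100\\]"):
            validate_grading_table(bad)


class TestAgreementStats:
    def test_bundle_consistency(self):
        rng = np.random.default_rng(9)
        table = _grading_table(rng, n=30, noise=2.0)
        st_ = agreement_stats(table, "intra", "A")
        assert 0.9 < st_.icc <= 1.0
        assert 0.99 < st_.cc <= 1.0
        assert st_.bland_altman.lower_loa <= st_.bland_altman.bias <= st_.bland_altman.upper_loa

    def test_plot_written(self, tmp_path):
        from hequant.quantify import bland_altman_plot

        ba = bland_altman([1.0, 2.0, 3.0], [1.1, 2.2, 2.9])
        out = tmp_path / "ba.png"
        bland_altman_plot(ba, out)
        assert out.stat().st_size > 0
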