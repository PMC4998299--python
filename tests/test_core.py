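import warnings

import numpy as np
import pytest

from trendim import (
    Category,
    ChangeClassification,
    ChangeObservation,
    NonPositiveMeasurementWarning,
    PairedSeries,
    RateCategory,
    RegionStatus,
    RepeatabilitySpec,
    TrendSummary,
    classify_change,
    classify_series,
    compare_devices,
    interchangeability_lines,
    is_interpretable,
    iter_changes,
    precision_interval,
    rate_category,
    region_status,
    summarize,
)


class TestRepeatabilitySpec:
    def test_percent_inputs_convert_to_fraction(self):
        assert RepeatabilitySpec(5).coefficient == pytest.approx(0.05)
        assert RepeatabilitySpec.from_percent(20).coefficient == pytest.approx(0.20)
        assert RepeatabilitySpec(0.05).coefficient == pytest.approx(0.05)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 100.0, float("nan"), float("inf")])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            RepeatabilitySpec(bad)


class TestPrecisionInterval:
    @pytest.mark.parametrize(
        "value,rc,expected",
        [
            (4.0, 0.05, (3.8, 4.2)),
            (0.0, 0.20, (0.0, 0.0)),
            (2.5, 0.20, (2.0, 3.0)),
            (-2.0, 0.10, (-2.2, -1.8)),  # |value| keeps lo <= hi
        ],
    )
    def test_multiplicative_interval(self, value, rc, expected):
        lo, hi = precision_interval(value, rc)
        assert (lo, hi) == pytest.approx(expected)
        assert lo <= hi

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            precision_interval(float("nan"), 0.05)


class TestInterpretabilityScreen:
    @pytest.mark.parametrize(
        "rm1,rm2,rc,expected",
        [
            (4.0, 5.0, 0.05, True),
            (4.0, 4.2, 0.20, False),
            (3.0, 3.0, 0.05, False),
            (5.0, 4.0, 0.05, True),  # symmetric in the two readings
        ],
    )
    def test_disjoint_intervals_required(self, rm1, rm2, rc, expected):
        assert is_interpretable(rm1, rm2, rc) is expected

    def test_touching_intervals_count_as_overlap(self):
        # intervals (3.8, 4.2) and (4.2, 4.642...) share exactly one point
        rm2 = 4.2 / 0.95
        assert precision_interval(rm2, 0.05)[0] == pytest.approx(4.2)
        assert not is_interpretable(4.0, rm2, 0.05)


class TestInterchangeabilityLines:
    def test_identity_pair_zeroes_the_offset(self):
        lines = interchangeability_lines(3, 3, 0.05)
        assert lines.upper == pytest.approx((1.05, 0.0))
        assert lines.lower == pytest.approx((0.95, 0.0))

    @pytest.mark.parametrize(
        "rm1,tm1,rc,slopes,intercept",
        [
            (4, 3, 0.05, (1.05, 0.95), 1.05),
            (4, 5, 0.20, (1.2, 0.8), -1.2),
        ],
    )
    def test_published_equations(self, rm1, tm1, rc, slopes, intercept):
        lines = interchangeability_lines(rm1, tm1, rc)
        assert (lines.upper[0], lines.lower[0]) == pytest.approx(slopes)
        assert lines.upper[1] == pytest.approx(intercept)
        assert lines.lower[1] == pytest.approx(intercept)

    def test_symmetric_intercepts_switch(self):
        lines = interchangeability_lines(4, 3, 0.05, symmetric_intercepts=True)
        assert lines.upper[1] == pytest.approx(1.05)
        assert lines.lower[1] == pytest.approx(0.95)


class TestRegionStatus:
    def test_inside_between_the_line_evaluations(self):
        # zone at Y=5 spans [0.95*5 + 1.05, 1.05*5 + 1.05] = [5.8, 6.3]
        lines = interchangeability_lines(4, 3, 0.05)
        assert lines.bounds_at(5) == pytest.approx((5.8, 6.3))
        assert region_status(6, 5, lines, 0.05) is RegionStatus.INSIDE

    def test_identity_point_inside_identity_zone(self):
        lines = interchangeability_lines(3, 3, 0.05)
        assert region_status(5, 5, lines, 0.05) is RegionStatus.INSIDE

    def test_outside_when_precision_interval_misses_zone(self):
        # zone [5.8, 6.3]; interval of 8 at 5% is (7.6, 8.4)
        lines = interchangeability_lines(4, 3, 0.05)
        assert region_status(8, 5, lines, 0.05) is RegionStatus.OUTSIDE

    def test_boundary_overlap_when_only_interval_reaches_zone(self):
        # zone [5.8, 6.3]; 6.5 is outside but its interval (6.175, 6.825)
        # reaches back into the zone
        lines = interchangeability_lines(4, 3, 0.05)
        assert region_status(6.5, 5, lines, 0.05) is RegionStatus.BOUNDARY_OVERLAP

    def test_point_exactly_on_a_line_is_inside(self):
        lines = interchangeability_lines(4, 3, 0.05)
        assert region_status(6.3, 5, lines, 0.05) is RegionStatus.INSIDE


class TestClassifyChange:
    @pytest.mark.parametrize(
        "quad,rc,expected",
        [
            ((3, 3, 5, 5), 0.05, Category.INTERCHANGEABLE),
            ((4, 4, 4.1, 6), 0.20, Category.UNINTERPRETABLE),
            ((4, 3, 8, 5), 0.05, Category.NONINTERCHANGEABLE),
            ((4, 3, 6.5, 5), 0.05, Category.GRAY_ZONE),
        ],
    )
    def test_two_step_algorithm(self, quad, rc, expected):
        assert classify_change(ChangeObservation(*quad), rc).category is expected

    def test_uninterpretable_ignores_test_values(self):
        # wildly different test readings, same overlapping reference pair
        for tm2 in (0.1, 6.0, 60.0):
            cls = classify_change(ChangeObservation(4, 4, 4.1, tm2), 0.20)
            assert cls.category is Category.UNINTERPRETABLE

    def test_color_follows_category(self):
        assert ChangeClassification(Category.UNINTERPRETABLE).color == "blue"
        assert ChangeClassification(Category.NONINTERCHANGEABLE).color == "red"
        assert ChangeClassification(Category.GRAY_ZONE).color == "orange"
        assert ChangeClassification(Category.INTERCHANGEABLE).color == "green"

    def test_non_positive_measurement_warns(self):
        with pytest.warns(NonPositiveMeasurementWarning):
            classify_change(ChangeObservation(1.0, -0.2, 3.0, 3.0), 0.05)


class TestSeriesHandling:
    def test_changes_from_consecutive_pairs_only(self):
        series = PairedSeries(
            "S", "d", ((1.0, 1.0, 0), (2.0, 2.0, 1), (3.0, 3.0, 3), (4.0, 4.0, 4))
        )
        spans = [(a, b) for a, b, _ in iter_changes(series)]
        assert spans == [(0, 1), (3, 4)]  # the 1 -> 3 gap is not bridged

    def test_time_index_must_increase(self):
        with pytest.raises(ValueError):
            PairedSeries("S", "d", ((1.0, 1.0, 1), (2.0, 2.0, 1)))

    def test_classify_series_table(self, identity_series):
        table = classify_series([identity_series], 0.05)
        assert len(table) == len(identity_series) - 1
        assert set(table["category"]) <= {c.value for c in Category}
        assert (table["delta_rm"] == table["delta_tm"]).all()


class TestSummary:
    def test_counts_partition_and_rate(self):
        cats = (
            [Category.UNINTERPRETABLE] * 3
            + [Category.NONINTERCHANGEABLE] * 2
            + [Category.GRAY_ZONE] * 1
            + [Category.INTERCHANGEABLE] * 4
        )
        s = summarize(cats)
        assert s.n_total == 10
        assert s.n_interpretable == 7
        assert s.tim_rate == pytest.approx(4 / 7)

    def test_gray_zone_in_denominator_not_numerator(self):
        s = summarize([Category.GRAY_ZONE] * 5 + [Category.INTERCHANGEABLE] * 5)
        assert s.tim_rate == pytest.approx(0.5)

    def test_empty_input(self):
        s = summarize([])
        assert s.n_total == 0
        assert s.tim_rate is None
        assert s.category_label is RateCategory.UNDEFINED

    def test_all_uninterpretable_rate_undefined_not_zero(self):
        s = summarize([Category.UNINTERPRETABLE] * 4)
        assert s.tim_rate is None

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            TrendSummary(5, 1, 1, 1, 1)


class TestRateCategory:
    @pytest.mark.parametrize(
        "rate,expected",
        [
            (0.95, RateCategory.EXCELLENT),
            (1.0, RateCategory.EXCELLENT),
            (0.90, RateCategory.GOOD),
            (0.94, RateCategory.GOOD),
            (0.75, RateCategory.POOR),
            (0.89, RateCategory.POOR),
            (0.67, RateCategory.NOT_CLINICALLY_RELEVANT),
            (0.0, RateCategory.NOT_CLINICALLY_RELEVANT),
            (None, RateCategory.UNDEFINED),
        ],
    )
    def test_thresholds(self, rate, expected):
        assert rate_category(rate) is expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rate_category(1.2)


class TestCompareDevices:
    def test_identical_summaries_are_homogeneous(self):
        s = TrendSummary(10, 2, 3, 1, 4, device="a")
        stat, p = compare_devices([s, s])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_pearson_chi_square(self):
        # 2x2 table [[30, 54], [18, 66]] from the chi-square definition:
        # sum (observed - expected)^2 / expected on marginal-product expecteds
        obs = np.array([[30.0, 54.0], [18.0, 66.0]])
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        by_hand = float(((obs - expected) ** 2 / expected).sum())
        stat, p = compare_devices(
            [
                TrendSummary(84, 0, 54, 0, 30, device="a"),
                TrendSummary(84, 0, 66, 0, 18, device="b"),
            ]
        )
        assert stat == pytest.approx(by_hand)
        assert 0 < p < 1

    def test_zero_denominator_device_excluded_with_warning(self):
        good = TrendSummary(10, 2, 3, 1, 4, device="a")
        empty = TrendSummary(4, 4, 0, 0, 0, device="b")
        with pytest.warns(UserWarning, match="no interpretable"):
            stat, p = compare_devices([good, good, empty])
        assert stat == pytest.approx(0.0)

    def test_fewer_than_two_usable_devices_raises(self):
        good = TrendSummary(10, 2, 3, 1, 4, device="a")
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                compare_devices([good])
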