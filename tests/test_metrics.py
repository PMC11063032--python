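"""Worked-example and edge-case tests for the germination indices."""
import numpy as np
import pytest

import httime as ht
from httime.timecourse import UndefinedIndexError


class TestCumulativeFraction:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((0, 5, 10), [0.0, 0.5, 1.0]),
            ((3, 3, 3), [0.3, 0.3, 0.3]),
            ((2, 7, 9), [0.2, 0.7, 0.9]),
        ],
    )
    def test_division_by_seeds_sown(self, make_tc, counts, expected):
        np.testing.assert_allclose(
            ht.cumulative_fraction(make_tc(counts)), expected
        )

    def test_zero_seeds_rejected(self, make_tc):
        with pytest.raises(ValueError):
            make_tc((0,), n=0)


class TestMeanGerminationTimeAndRate:
    def test_single_day(self, make_tc):
        assert ht.mean_germination_time(make_tc((10,), times=(2,))) == 2.0

    def test_weighted_average_of_daily_counts(self, make_tc):
        # new germinations 5, 3, 2 on days 1, 2, 3
        tc = make_tc((5, 8, 10))
        assert ht.mean_germination_time(tc) == pytest.approx(1.7)
        assert ht.mean_germination_rate(tc) == pytest.approx(1 / 1.7)

    def test_gap_days(self, make_tc):
        tc = make_tc((1, 2), times=(1, 3))
        assert ht.mean_germination_time(tc) == 2.0

    def test_zero_germination_is_undefined_not_zero(self, make_tc):
        tc = make_tc((0, 0, 0))
        with pytest.raises(UndefinedIndexError) as err:
            ht.mean_germination_time(tc)
        assert err.value.reason == "no_germination"
        with pytest.raises(UndefinedIndexError):
            ht.mean_germination_rate(tc)


class TestGerminationEnergy:
    @pytest.mark.parametrize(
        "counts, times, expected",
        [
            ((5,), (1,), 50.0),          # 50% on day 1
            ((4, 7), (1, 2), 55.0),      # 40/1 + 30/2
            ((0, 0), (1, 2), 0.0),
        ],
    )
    def test_increment_over_day_sum(self, make_tc, counts, times, expected):
        assert ht.germination_energy(make_tc(counts, times=times)) == pytest.approx(expected)

    def test_subday_observation_rejected(self, make_tc):
        tc = make_tc((5,), times=(0.5,))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                ht.germination_energy(tc)


class TestGerminationRateIndex:
    def test_single_day_standard(self, make_tc):
        assert ht.germination_rate_index(make_tc((5,), times=(1,))) == 50.0

    def test_standard_weights_by_day(self, make_tc):
        tc = make_tc((4, 7))
        assert ht.germination_rate_index(tc, "standard") == pytest.approx(55.0)

    def test_as_printed_divides_by_two(self, make_tc):
        tc = make_tc((4, 7))
        assert ht.germination_rate_index(tc, "as_printed") == pytest.approx(35.0)

    def test_unknown_variant(self, make_tc):
        with pytest.raises(ValueError, match="variant"):
            ht.germination_rate_index(make_tc((4, 7)), "bogus")


class TestGerminationIndex:
    def test_all_on_day_one(self, make_tc):
        assert ht.germination_index(make_tc((10,), times=(1,))) == 100

    def test_declining_weights(self, make_tc):
        assert ht.germination_index(make_tc((2, 5))) == 10 * 2 + 9 * 3

    def test_no_germination(self, make_tc):
        assert ht.germination_index(make_tc((0, 0))) == 0

    def test_late_germination_warns_and_counts_zero(self, make_tc):
        tc = make_tc((2, 5), times=(1, 11))
        with pytest.warns(UserWarning, match="after day 10"):
            assert ht.germination_index(tc) == 20


class TestTimsonIndex:
    def test_saturated(self, make_tc):
        assert ht.timson_index(make_tc((10,), times=(1,)), 10) == 1000.0

    def test_sum_of_cumulative_percentages(self, make_tc):
        assert ht.timson_index(make_tc((5, 10)), 2) == 150.0

    def test_no_germination(self, make_tc):
        assert ht.timson_index(make_tc((0, 0))) == 0.0

    def test_empty_window(self, make_tc):
        with pytest.raises(ValueError):
            ht.timson_index(make_tc((5, 10)), 0)


class TestCoefficientOfVelocity:
    def test_equals_100_over_mgt(self, make_tc):
        assert ht.coefficient_velocity(make_tc((10,), times=(2,))) == 50.0
        assert ht.coefficient_velocity(make_tc((5, 8, 10))) == pytest.approx(100 / 1.7)
        assert ht.coefficient_velocity(make_tc((10,), times=(1,))) == 100.0

    def test_undefined_propagates(self, make_tc):
        with pytest.raises(UndefinedIndexError):
            ht.coefficient_velocity(make_tc((0,)))


class TestTimeTo50:
    def test_interpolated_crossing(self, make_tc):
        assert ht.time_to_50(make_tc((0, 10), times=(1, 2))) == 1.5

    def test_reached_at_first_observation(self, make_tc):
        assert ht.time_to_50(make_tc((5, 10), times=(1, 2))) == 1.0

    def test_below_half_is_undefined(self, make_tc):
        with pytest.raises(UndefinedIndexError) as err:
            ht.time_to_50(make_tc((0, 4)))
        assert err.value.reason == "below_half"


class TestSeedVigor:
    def test_length_and_weight_indices(self, make_tc):
        sm = ht.SeedlingMeasures(radicle_length=3.0, plumule_length=2.0, dry_weight=0.02)
        svi1, svi2 = ht.seed_vigor_indices(make_tc((8,), times=(1,)), sm)
        assert svi1 == pytest.approx(400.0)  # 5 cm x 80%
        sm2 = ht.SeedlingMeasures(0.0, 0.0, 0.02)
        _, svi_w = ht.seed_vigor_indices(make_tc((5,), times=(1,)), sm2)
        assert svi_w == pytest.approx(1.0)   # 0.02 g x 50%

    def test_zero_germination_gives_zero(self, make_tc):
        sm = ht.SeedlingMeasures(3.0, 2.0, 0.02)
        assert ht.seed_vigor_indices(make_tc((0,)), sm) == (0.0, 0.0)

    def test_negative_measures_rejected(self):
        with pytest.raises(ValueError):
            ht.SeedlingMeasures(-1.0, 2.0, 0.02)


class TestIndexReport:
    def test_undefined_entries_carry_reasons(self, make_tc):
        rep = ht.index_report(make_tc((0, 0)))
        assert rep.MGT is None
        assert rep.undefined_reasons["MGT"] == "no_germination"
        assert rep.undefined_reasons["T50"] == "below_half"
        assert rep.germination_percent == 0.0

    def test_full_report_consistency(self, make_tc):
        rep = ht.index_report(make_tc((5, 8, 10)),
                              ht.SeedlingMeasures(3.0, 2.0, 0.02))
        assert rep.MGR * rep.MGT == pytest.approx(1.0, abs=1e-12)
        assert rep.CVG == pytest.approx(100 * rep.MGR)
        assert rep.SVI_length == pytest.approx(500.0)
        assert rep.metadata["gri_variant"] == "standard"
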