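"""Activity factors, benchmark agreement, cutoff scan, ranking, composition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzscreen.benchmark import (
    ActivityRecord,
    ClassificationThresholds,
    benchmark,
    composition_summary,
    computational_factor,
    experimental_factor,
    optimize_cutoff,
    rank_candidates,
)


class TestFactors:
    @pytest.mark.parametrize(
        "activity,expected",
        [(11.2, 1), (1.2, 1), (1.0, 0), (0.8, -1), (0.0, -1)],
    )
    def test_experimental_factor_bands(self, activity, expected):
        assert experimental_factor(activity) == expected

    @pytest.mark.parametrize(
        "barrier,expected", [(12.5, -1), (7.3, 1), (18.9, -1), (12.49, 1)]
    )
    def test_computational_factor_cutoff_rule(self, barrier, expected):
        assert computational_factor(barrier, 12.5) == expected

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            experimental_factor(-0.1)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 20, allow_nan=False), min_size=2, max_size=20))
    def test_factors_are_monotone_step_functions(self, values):
        values = sorted(values)
        ef = [experimental_factor(v) for v in values]
        cf = [computational_factor(v, 12.5) for v in values]
        assert ef == sorted(ef)          # nondecreasing in activity
        assert cf == sorted(cf, reverse=True)  # nonincreasing in barrier


class TestBenchmark:
    def test_benchmark_set_agreement_is_15_of_22(self, set_s_records):
        report = benchmark(set_s_records)
        assert (report.n_agree, report.n_records) == (15, 22)
        assert report.agreement_percent == 68

    def test_high_and_low_activity_subgroups(self, set_s_records):
        report = benchmark(set_s_records)
        assert (report.high_activity.size, report.high_activity.n_correct) == (6, 4)
        assert (report.low_activity.size, report.low_activity.n_correct) == (8, 7)

    def test_twelve_mutants_classify_as_improving(self, set_s_records):
        assert sum(experimental_factor(r.activity) == 1 for r in set_s_records) == 12

    def test_agreement_invariant_to_record_order(self, set_s_records):
        fwd = benchmark(set_s_records)
        rev = benchmark(list(reversed(set_s_records)))
        assert fwd.n_agree == rev.n_agree

    def test_neutral_records_excluded_and_listed(self):
        records = [
            ActivityRecord("G1A", 2.0, 10.0),
            ActivityRecord("G2A", 1.0, 10.0),  # neutral band
            ActivityRecord("G3A", 0.1, 14.0),
        ]
        report = benchmark(records)
        assert report.n_records == 2
        assert report.neutral_excluded == ("G2A",)

    def test_empty_record_set_rejected(self):
        with pytest.raises(ValueError):
            benchmark([])


def grid_agreement(records, cutoff):
    """Brute-force oracle: per-record check at one cutoff."""
    return sum(
        experimental_factor(r.activity) == computational_factor(r.barrier, cutoff)
        for r in records
        if experimental_factor(r.activity) != 0
    )


class TestCutoffScan:
    def test_scan_on_benchmark_set_finds_15_including_12p5(self, set_s_records):
        scan = optimize_cutoff(set_s_records)
        assert scan.max_agreement == 15
        assert 12.5 in scan.optimal_cutoffs

    def test_scan_beats_any_dense_grid_cutoff(self, set_s_records):
        scan = optimize_cutoff(set_s_records)
        grid = [5 + 0.01 * k for k in range(1600)]
        assert scan.max_agreement >= max(grid_agreement(set_s_records, c) for c in grid)
        for c, score in scan.candidates:
            assert score == grid_agreement(set_s_records, c)

    def test_perfectly_separable_records_reach_full_agreement(self):
        records = [
            ActivityRecord("G1A", 5.0, 8.0),
            ActivityRecord("G2A", 4.0, 9.0),
            ActivityRecord("G3A", 0.2, 15.0),
            ActivityRecord("G4A", 0.1, 16.0),
        ]
        assert optimize_cutoff(records).max_agreement == 4

    def test_identical_barriers_opposite_factors_cap_at_one(self):
        records = [
            ActivityRecord("G1A", 5.0, 10.0),
            ActivityRecord("G2A", 0.1, 10.0),
        ]
        with pytest.raises(ValueError):
            optimize_cutoff(records)  # only one distinct barrier value
        records.append(ActivityRecord("G3A", 1.0, 11.0))  # neutral, adds a value
        scan = optimize_cutoff(records)
        assert scan.max_agreement == 1


class TestRanking:
    def test_lowest_barrier_candidate(self, set_l_top20):
        assert rank_candidates(set_l_top20, 1) == [("G39A-T103G-I189Y", 5.7)]

    def test_three_candidates_beat_wild_type_barrier(self, set_l_top20):
        assert sum(b < 7.5 for _, b in set_l_top20) == 3

    def test_output_sorted_and_is_n_smallest(self, set_l_top20):
        ranked = rank_candidates(set_l_top20, 7)
        barriers = [b for _, b in ranked]
        assert barriers == sorted(barriers)
        assert sorted(barriers) == sorted(b for _, b in set_l_top20)[:7]

    def test_n_larger_than_pool_returns_all(self, set_l_top20):
        assert len(rank_candidates(set_l_top20, 500)) == 20

    def test_ties_break_on_mutant_string(self):
        ranked = rank_candidates([("B2C", 1.0), ("A1C", 1.0)], 2)
        assert [m for m, _ in ranked] == ["A1C", "B2C"]


class TestComposition:
    def test_top20_order_histogram(self, set_l_top20):
        summary = composition_summary([m for m, _ in set_l_top20])
        assert summary.by_order == {2: 3, 3: 7, 4: 10}

    def test_top20_position_occurrences(self, set_l_top20):
        summary = composition_summary([m for m, _ in set_l_top20])
        assert summary.by_position[141] == 13
        assert summary.by_position[189] == 16
        assert summary.by_position[39] == 19  # all but one contain G39A

    def test_empty_input_gives_empty_summary(self):
        summary = composition_summary([])
        assert summary.by_order == {} and summary.by_position == {}
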