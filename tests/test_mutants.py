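"""Mutant identity, library counting and constrained enumeration."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzscreen.mutants import (
    ExclusionConstraint,
    MutantID,
    MutationLibrary,
    PointMutation,
    count_by_order,
    count_containing_pair,
    enumerate_mutants,
    intersect_sets,
    parse_mutant,
)

from .conftest import brute_force_enumerate


class TestParseMutant:
    def test_four_fold_label_parses_to_order_and_positions(self):
        m = parse_mutant("G39A-T103G-W104F-L278A")
        assert m.order == 4
        assert m.positions == {39, 103, 104, 278}

    def test_token_order_is_canonicalized_by_position(self):
        assert str(parse_mutant("L278A-G39A")) == "G39A-L278A"

    def test_wild_type_forms(self):
        assert parse_mutant("WT").order == 0
        assert str(MutantID(())) == "WT"

    @pytest.mark.parametrize("bad", ["G39G", "G39A-G39S", "39A", "G39A--L278A", "Z39A"])
    def test_malformed_or_inconsistent_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_mutant(bad)

    def test_round_trip_over_full_enumeration(self, library, exclusions):
        for m in enumerate_mutants(library, 4, exclusions):
            assert parse_mutant(str(m)) == m


# small random libraries over distinct positions with g_i <= 5
@st.composite
def small_libraries(draw):
    n_pos = draw(st.integers(1, 6))
    positions = draw(
        st.lists(st.integers(1, 400), min_size=n_pos, max_size=n_pos, unique=True)
    )
    residues = "ACDEFGHIKLMNPQRSTVWY"
    records = []
    for pos in positions:
        wt = draw(st.sampled_from(residues))
        pool = [r for r in residues if r != wt]
        subs = draw(st.lists(st.sampled_from(pool), min_size=1, max_size=5, unique=True))
        records.append((pos, wt, subs))
    return MutationLibrary.from_records(records)


class TestCounting:
    def test_combinatorial_library_per_order_counts(self, library):
        assert [count_by_order(library, o) for o in (1, 2, 3, 4)] == [13, 64, 154, 193]
        assert sum(count_by_order(library, o) for o in (1, 2, 3, 4)) == 424

    def test_order_beyond_positions_counts_zero(self):
        lib = MutationLibrary.from_records([(10, "A", ["G", "S", "T"])])
        assert count_by_order(lib, 2) == 0

    def test_two_position_pair_count(self):
        lib = MutationLibrary.from_records([(1, "A", ["G", "S"]), (2, "L", ["I", "V", "F"])])
        assert count_by_order(lib, 2) == 6

    @settings(max_examples=100, derandomize=True)
    @given(small_libraries())
    def test_closed_form_matches_brute_force_per_order(self, lib):
        counts = Counter(m.order for m in brute_force_enumerate(lib, len(lib.positions)))
        for o in range(1, len(lib.positions) + 1):
            assert count_by_order(lib, o) == counts.get(o, 0)

    @settings(max_examples=50, derandomize=True)
    @given(small_libraries())
    def test_total_equals_product_form(self, lib):
        total = sum(count_by_order(lib, o) for o in range(1, len(lib.positions) + 1))
        prod = 1
        for g in lib.multiplicities:
            prod *= 1 + g
        assert total == prod - 1


class TestEnumeration:
    def test_steric_exclusion_leaves_386(self, library, exclusions):
        assert len(enumerate_mutants(library, 4, exclusions)) == 386

    def test_per_order_counts_without_exclusions_match_closed_form(self, library):
        counts = Counter(m.order for m in enumerate_mutants(library, 4))
        assert counts == {1: 13, 2: 64, 3: 154, 4: 193}

    def test_excluded_four_fold_count_is_24(self, library, exclusions):
        with_ex = Counter(m.order for m in enumerate_mutants(library, 4, exclusions))
        assert 193 - with_ex[4] == 24

    def test_single_position_library_yields_only_singles(self):
        lib = MutationLibrary.from_records([(7, "W", ["F", "Y"])])
        muts = enumerate_mutants(lib, 4)
        assert sorted(str(m) for m in muts) == ["W7F", "W7Y"]

    def test_no_duplicates_and_no_forbidden_pairs(self, library, exclusions):
        muts = enumerate_mutants(library, 4, exclusions)
        assert len(set(muts)) == len(muts)
        assert all(exclusions.allows(m) for m in muts)

    def test_exclusion_equals_set_difference(self, library, exclusions):
        """Inclusion-exclusion check: filtered set == all minus pair-containing."""
        everything = set(enumerate_mutants(library, 4))
        containing = {
            m for m in everything if not exclusions.allows(m)
        }
        assert set(enumerate_mutants(library, 4, exclusions)) == everything - containing


class TestContainingPair:
    def test_forbidden_pair_counts_by_order(self, library):
        pairs = [
            (PointMutation.parse("A141N"), PointMutation.parse("I189Y")),
            (PointMutation.parse("A141Q"), PointMutation.parse("I189Y")),
        ]
        for order, expected in [(2, 2), (3, 12), (4, 24)]:
            assert sum(count_containing_pair(library, p, order) for p in pairs) == expected

    def test_order_one_cannot_contain_a_pair(self, library):
        pair = (PointMutation.parse("A141N"), PointMutation.parse("I189Y"))
        assert count_containing_pair(library, pair, 1) == 0

    def test_specific_pair_double_count(self, library):
        pair = (PointMutation.parse("G39A"), PointMutation.parse("L278A"))
        assert count_containing_pair(library, pair, 2) == 1

    def test_matches_brute_force_on_combinatorial_library(self, library):
        pair = (PointMutation.parse("A141N"), PointMutation.parse("I189Y"))
        all_muts = brute_force_enumerate(library, 4)
        for order in (2, 3, 4):
            direct = sum(
                1 for m in all_muts
                if m.order == order and m.contains(pair[0]) and m.contains(pair[1])
            )
            assert count_containing_pair(library, pair, order) == direct

    def test_pair_member_outside_library_rejected(self, library):
        pair = (PointMutation.parse("P38H"), PointMutation.parse("I189Y"))
        with pytest.raises(ValueError):
            count_containing_pair(library, pair, 2)


class TestIntersect:
    def test_benchmark_overlap_is_15(self, library, exclusions, set_s_records):
        screened = enumerate_mutants(library, 4, exclusions)
        bench = [parse_mutant(r.mutant) for r in set_s_records]
        assert len(intersect_sets(screened, bench)) == 15

    def test_identity_is_the_full_mutation_set(self):
        assert intersect_sets([parse_mutant("G39A")], [parse_mutant("G39A-L278A")]) == []

    def test_empty_and_order_invariance(self, set_s_records):
        ids = [parse_mutant(r.mutant) for r in set_s_records]
        assert intersect_sets(ids, []) == []
        assert intersect_sets(ids, reversed(ids)) == intersect_sets(ids, ids)


class TestExclusionConstraint:
    def test_same_position_pair_rejected(self):
        with pytest.raises(ValueError):
            ExclusionConstraint.from_pairs([("A141N", "A141Q")])
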