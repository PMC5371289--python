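"""Decision tree, comparison counting, and summary tabulations."""

import pytest

from phenomatch import (TrajectoryCall, assign_symbol,
                        count_possible_comparisons, pairwise_significance,
                        summarize, SYMBOL_GLYPHS)

PAIRS = (("P1", "P2"), ("P1", "P3"), ("P2", "P3"))


def results(s12=None, s13=None, s23=None):
    """Pair outcomes from signed ints (+1/-1 significant, 0 not, None undef)."""
    out = {}
    for pair, s in zip(PAIRS, (s12, s13, s23)):
        out[pair] = None if s is None else (s != 0, s)
    return out


class TestPairwiseSignificance:
    def test_disjoint_intervals_significant_increase(self):
        assert pairwise_significance((2.0, 3.0), (4.0, 5.0), 2.5, 4.5) \
            == (True, 1)

    def test_overlapping_intervals_not_significant(self):
        assert pairwise_significance((2.0, 4.0), (3.5, 5.0), 3.0, 4.2) \
            == (False, 0)

    def test_touching_endpoints_not_disjoint(self):
        assert pairwise_significance((0.10, 0.20), (0.20, 0.30), 0.15, 0.25) \
            == (False, 0)


class TestAssignSymbol:
    @pytest.mark.parametrize("signs, klass, symbol", [
        # timing: consistent decrease in dates = precocity "/"
        (dict(s12=-1, s13=-1, s23=0), "timing", "inc"),
        # timing: period 2 earlier than both neighbours, ends similar = "C"
        (dict(s12=-1, s13=0, s23=1), "timing", "C"),
        # timing: period 2 later than both = "Ɔ"
        (dict(s12=1, s13=0, s23=-1), "timing", "revC"),
        # timing: consistent delay = "\"
        (dict(s12=1, s13=1, s23=1), "timing", "dec"),
        # magnitude: increase then decrease = bump "Ɔ"
        (dict(s12=1, s13=0, s23=-1), "magnitude", "revC"),
        # magnitude: monotone increase = "/"
        (dict(s12=0, s13=1, s23=1), "magnitude", "inc"),
        # magnitude: dip = "C"
        (dict(s12=-1, s13=0, s23=1), "magnitude", "C"),
        # no significant pair
        (dict(s12=0, s13=0, s23=0), "timing", "NS"),
        # single significant end-to-end trend
        (dict(s12=0, s13=-1, s23=0), "timing", "inc"),
        # single P1-P2 difference with no end trend reads as an extremum
        (dict(s12=1, s13=0, s23=0), "timing", "revC"),
    ])
    def test_decision_tree(self, signs, klass, symbol):
        call = assign_symbol(results(**signs), klass)
        assert call.symbol == symbol
        assert call.n_significant_pairs == sum(
            v != 0 for v in signs.values())

    def test_two_period_units_only_get_monotone_shapes(self):
        # an absent first period leaves a single defined pair
        call = assign_symbol(results(s23=1), "timing")
        assert call.symbol == "dec"          # dates increased = delay "\"
        call = assign_symbol(results(s23=-1), "magnitude")
        assert call.symbol == "dec"
        assert call.n_significant_pairs == 1

    def test_contradictory_directions_majority_with_warning(self):
        call = assign_symbol(results(s12=1, s13=1, s23=-1), "magnitude")
        assert call.symbol == "inc"
        assert call.warning is not None

    def test_balanced_contradiction_is_ns_with_warning(self):
        call = assign_symbol(results(s12=1, s13=-1, s23=0), "magnitude")
        assert call.symbol == "NS"
        assert call.warning is not None

    def test_all_pairs_undefined_is_undef(self):
        call = assign_symbol({p: None for p in PAIRS}, "timing")
        assert call.symbol == "undef"

    def test_legacy_overlap_convention_swaps_monotone_glyphs(self):
        res = results(s12=0, s13=-1, s23=0)   # overlap decrease
        assert assign_symbol(res, "magnitude",
                             indicator="overlap").symbol == "dec"
        assert assign_symbol(res, "magnitude", indicator="overlap",
                             legacy_overlap_symbols=True).symbol == "inc"

    def test_glyph_serialisation(self):
        assert SYMBOL_GLYPHS == {"C": "C", "revC": "Ɔ", "inc": "/",
                                 "dec": "\\", "NS": "NS", "undef": ""}


class TestPossibleComparisons:
    def test_study_layout_counts_55(self):
        presence = {f"full{i}": (True, True, True) for i in range(18)}
        presence["late"] = (False, True, True)
        assert count_possible_comparisons(presence) == 55

    def test_single_period_species_contributes_none(self):
        assert count_possible_comparisons({"a": (True, False, False)}) == 0

    def test_matches_brute_force_enumeration(self, rng):
        from itertools import combinations
        for _ in range(25):
            presence = {f"s{i}": tuple(rng.random(3) < 0.7)
                        for i in range(8)}
            brute = sum(
                sum(1 for a, b in combinations(range(3), 2)
                    if flags[a] and flags[b])
                for flags in presence.values())
            assert count_possible_comparisons(presence) == brute


class TestSummarize:
    def make_calls(self, spec):
        return [TrajectoryCall(unit=(s,), indicator=i, symbol=sym,
                               n_significant_pairs=n)
                for s, i, sym, n in spec]

    def test_all_ns_gives_zero_totals(self):
        calls = self.make_calls([("a", i, "NS", 0)
                                 for i in ("T", "Q10", "Q50", "Q90", "Tr")])
        tables = summarize(calls, presence={"a": (True, True, True)})
        for entry in tables.stats["per_indicator"].values():
            assert entry["significant_pairs"] == 0
            assert not entry["exceeds_chance_threshold"]
        assert tables.stats["pct_cells_changed"] == 0.0

    def test_cell_format_and_totals(self):
        calls = self.make_calls([
            ("a", "T", "inc", 2), ("a", "Tr", "NS", 0),
            ("b", "T", "C", 1), ("b", "Tr", "dec", 3),
        ])
        tables = summarize(calls, presence={"a": (True,) * 3,
                                            "b": (True,) * 3})
        assert tables.species_table.loc["a", "T"] == "/ (2)"
        assert tables.species_table.loc["b", "Tr"] == "\\ (3)"
        assert tables.species_table.loc["a", "Tr"] == "NS"
        stats = tables.stats
        assert stats["per_indicator"]["T"]["significant_pairs"] == 3
        assert stats["possible_pairwise_comparisons"] == 6
        assert stats["pct_cells_changed"] == 75.0

    def test_undefined_cells_excluded_from_denominators(self):
        calls = self.make_calls([("a", "T", "undef", 0),
                                 ("b", "T", "inc", 1)])
        tables = summarize(calls, presence={"a": (False, True, False),
                                            "b": (True,) * 3})
        assert tables.stats["cells_defined"] == 1
        assert tables.stats["pct_cells_changed"] == 100.0

    def test_interaction_summary_and_overlap_strings(self):
        icalls = [
            TrajectoryCall(("f", "z1"), "overlap", "revC", 1),
            TrajectoryCall(("f", "z2"), "overlap", "NS", 0),
            TrajectoryCall(("g", "z1"), "overlap", "undef", 0),
        ]
        tables = summarize([], icalls,
                           overlap_period_means={
                               ("f", "z1"): (0.27, 0.40, 0.50)})
        it = tables.stats["interactions"]
        assert it["documented"] == 2
        assert it["changed"] == 1
        assert it["pct_changed"] == 50.0
        assert it["symbol_counts"]["revC"] == 1
        assert tables.overlap_changes.iloc[0]["change"] == "27% -> 50%"
        assert tables.interaction_table.loc["f", "z1"] == "Ɔ"
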