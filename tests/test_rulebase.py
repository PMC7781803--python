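"""Rule knowledge base: vocabulary, loading, reasoning, validation."""

import json
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syndromedx.rulebase import (
    ELEMENTS,
    PATTERNS,
    CombinationRule,
    PatternLookupError,
    RuleBase,
    SchemaError,
    SyndromeElement,
    SyndromePattern,
    VocabularyError,
    load_rulebase,
)


def name_derived_elements(pattern_name: str) -> set:
    """Oracle: elements whose names can be read off the pattern name."""
    out = set()
    name = pattern_name.replace("hot", "heat")
    for el in ("phlegm", "wind", "cold", "heat", "lung", "spleen", "kidney"):
        if el in name:
            out.add(el)
    if "deficiency" in name:
        if "qi" in name:
            out.add("qi-deficiency")
        if "yin" in name:
            out.add("yin-deficiency")
    return out


class TestVocabulary:
    def test_element_construction_enforces_closed_vocabulary(self):
        assert SyndromeElement("phlegm") == "phlegm"
        with pytest.raises(VocabularyError):
            SyndromeElement("dampness")

    def test_pattern_construction_enforces_closed_vocabulary(self):
        assert SyndromePattern("cold wheezing") == "cold wheezing"
        with pytest.raises(VocabularyError):
            SyndromePattern("liver fire")


class TestLoading:
    def test_default_table_covers_all_ten_patterns(self, rb):
        assert len(rb) == 10
        assert sorted(map(str, rb.patterns)) == sorted(PATTERNS)

    def test_default_table_elements_contain_name_derived_elements(self, rb):
        # each pattern's rule must contain every element readable from its name
        for p in PATTERNS:
            derived = name_derived_elements(p)
            assert derived <= set(map(str, rb.elements_for_pattern(p))), p

    def test_empty_element_set_is_a_schema_error(self, tmp_path):
        path = tmp_path / "rules.json"
        path.write_text(json.dumps({"version": "x", "rules": [
            {"pattern": "cold wheezing", "elements": [], "priority": 1}]}))
        with pytest.raises(SchemaError):
            load_rulebase(path)

    def test_unknown_label_is_a_vocabulary_error(self, tmp_path):
        path = tmp_path / "rules.json"
        path.write_text(json.dumps({"version": "x", "rules": [
            {"pattern": "cold wheezing", "elements": ["dampness"], "priority": 1}]}))
        with pytest.raises(VocabularyError):
            load_rulebase(path)

    def test_duplicate_element_sets_load_but_are_reported(self, tmp_path):
        path = tmp_path / "rules.json"
        path.write_text(json.dumps({"version": "x", "rules": [
            {"pattern": "hot wheezing", "elements": ["heat", "phlegm", "lung"], "priority": 1},
            {"pattern": "phlegm-heat obstruction in lung", "elements": ["phlegm", "heat", "lung"], "priority": 2},
        ]}))
        rb = load_rulebase(path)
        report = rb.validate()
        assert report.duplicate_sets == [(0, 1)]

    def test_duplicate_priorities_are_rejected(self):
        rule = lambda p, pr: CombinationRule(
            SyndromePattern(p), frozenset({SyndromeElement("lung")}), pr)
        with pytest.raises(SchemaError):
            RuleBase([rule("cold wheezing", 1), rule("hot wheezing", 1)])


class TestElementsForPattern:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ("qi-deficiency of lung and spleen", {"qi-deficiency", "lung", "spleen"}),
            ("yin-deficiency of lung", {"yin-deficiency", "lung"}),
            ("phlegm obstruction in lung", {"phlegm", "lung"}),
        ],
    )
    def test_decomposition_matches_name_oracle(self, rb, pattern, expected):
        assert set(map(str, rb.elements_for_pattern(pattern))) == expected

    def test_absent_pattern_raises_lookup_error(self, rb):
        small = RuleBase(rules=rb.rules[:3])
        with pytest.raises(PatternLookupError):
            small.elements_for_pattern("hot wheezing")


class TestPatternForElements:
    def test_exact_set_gives_exact_status(self, rb):
        for p in PATTERNS:
            res = rb.pattern_for_elements(rb.elements_for_pattern(p))
            assert res.status == "exact"
            assert res.pattern == p
            assert res.overlap_score == 1.0

    def test_extra_element_gives_partial_with_jaccard_score(self, rb):
        els = set(rb.elements_for_pattern("phlegm obstruction in lung")) | {"kidney"}
        # exhaustive oracle over all rules
        best = max(
            len(frozenset(els) & r.elements) / len(frozenset(els) | r.elements)
            for r in rb.rules
        )
        res = rb.pattern_for_elements(els)
        assert res.status == "partial"
        assert res.pattern == "phlegm obstruction in lung"
        assert res.overlap_score == pytest.approx(best)
        assert res.overlap_score == pytest.approx(2 / 3)

    def test_duplicate_sets_resolve_to_priority_winner_as_ambiguous(self):
        rules = [
            CombinationRule(SyndromePattern("hot wheezing"),
                            frozenset(map(SyndromeElement, ["heat", "phlegm", "lung"])), 2),
            CombinationRule(SyndromePattern("phlegm-heat obstruction in lung"),
                            frozenset(map(SyndromeElement, ["heat", "phlegm", "lung"])), 1),
        ]
        rb2 = RuleBase(rules)
        res = rb2.pattern_for_elements({"heat", "phlegm", "lung"})
        assert res.status == "ambiguous"
        assert res.pattern == "phlegm-heat obstruction in lung"  # priority 1 wins
        assert set(res.matched_rule_ids) == {0, 1}

    def test_below_floor_gives_none(self, rb):
        res = rb.pattern_for_elements({"kidney"})
        assert res.status == "none"
        assert res.pattern is None

    def test_empty_element_set_is_a_precondition_error(self, rb):
        with pytest.raises(ValueError):
            rb.pattern_for_elements(set())

    def test_reasoning_is_deterministic(self, rb):
        els = {"wind", "heat", "lung", "phlegm"}
        assert rb.pattern_for_elements(els) == rb.pattern_for_elements(els)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(ELEMENTS), min_size=1, max_size=9))
    def test_overlap_score_bounds_and_equality(self, els):
        rb = load_rulebase()
        res = rb.pattern_for_elements(els)
        assert 0.0 <= res.overlap_score <= 1.0
        exact_exists = any(frozenset(els) == r.elements for r in rb.rules)
        assert (res.overlap_score == 1.0) == exact_exists


class TestValidation:
    def test_default_table_round_trips_every_pattern(self, rb):
        report = rb.validate()
        assert report.ok
        assert set(report.roundtrip) == set(PATTERNS)
        assert all(report.roundtrip.values())

    def test_missing_pattern_is_a_coverage_failure(self, rb):
        partial = RuleBase([r for r in rb.rules if r.pattern != "cold wheezing"])
        report = partial.validate()
        assert report.missing_patterns == ["cold wheezing"]

    def test_unused_element_is_warned(self, rb):
        no_kidney = RuleBase([r for r in rb.rules if "kidney" not in r.elements])
        report = no_kidney.validate()
        assert "kidney" in report.unused_elements

    def test_jaccard_is_symmetric_across_all_rule_pairs(self, rb):
        from syndromedx.rulebase import _jaccard

        for a, b in combinations([r.elements for r in rb.rules], 2):
            assert _jaccard(a, b) == _jaccard(b, a)
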