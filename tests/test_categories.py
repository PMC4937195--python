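"""Category matching: n-gram similarity, frequency scales, rules, snippets."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from phenoconnect import dsl
from phenoconnect.categories import (
    CategoryMatchError,
    MatchRule,
    RuleConfigurationError,
    apply_rules,
    default_rules,
    generate_map_snippet,
    match_categories,
    match_frequency,
    match_lexical,
    ngram_similarity,
    parse_frequency,
)
from phenoconnect.emx import Category


def _cats(*pairs):
    return [Category(code, label) for code, label in pairs]


def _oracle_dice(a, b):
    """Independent brute-force bigram Dice on normalised, padded strings."""

    def norm(s):
        return " ".join(re.sub(r"[^\w\s]", " ", s.casefold()).split())

    def grams(s):
        s = f" {s} "
        return {s[i : i + 2] for i in range(len(s) - 1)}

    na, nb = norm(a), norm(b)
    if na == nb:
        return 1.0
    if not na or not nb:
        return 0.0
    ga, gb = grams(na), grams(nb)
    return 2 * len(ga & gb) / (len(ga) + len(gb))


class TestNgram:
    def test_identity_is_one(self):
        assert ngram_similarity("Male", "Male") == 1.0
        assert ngram_similarity("Male", "MALE!") == 1.0  # case/punctuation-blind

    def test_empty_vs_nonempty_is_zero(self):
        assert ngram_similarity("", "x") == 0.0

    def test_wrong_label_scores_below_right_label(self):
        assert ngram_similarity("Male", "Female") < ngram_similarity("Female", "Female")

    @settings(max_examples=300, derandomize=True)
    @given(st.text(max_size=12), st.text(max_size=12))
    def test_equals_brute_force_oracle_and_is_symmetric(self, a, b):
        s = ngram_similarity(a, b)
        assert s == pytest.approx(_oracle_dice(a, b))
        assert s == ngram_similarity(b, a)
        assert 0.0 <= s <= 1.0


class TestLexical:
    def test_gender_example(self):
        target = _cats(("0", "Male"), ("1", "Female"))
        source = _cats(("1", "Male"), ("2", "Female"))
        assert match_lexical(target, source).as_dict() == {"1": "0", "2": "1"}

    def test_identity_on_same_category_set(self):
        cats = _cats(("a", "Low"), ("b", "Medium"), ("c", "High"))
        assert match_lexical(cats, cats).as_dict() == {"a": "a", "b": "b", "c": "c"}

    def test_many_to_one_argmax(self):
        target = _cats(("0", "no"), ("1", "yes"))
        source = _cats(("1", "yes"), ("2", "yes definitely"), ("3", "no"))
        result = match_lexical(target, source).as_dict()
        # brute-force argmax over every pair
        for src in _cats(("1", "yes"), ("2", "yes definitely"), ("3", "no")):
            best = max(target, key=lambda t: ngram_similarity(src.label, t.label))
            assert result[src.code] == best.code


class TestFrequency:
    @pytest.mark.parametrize(
        "label, amount, unit",
        [
            ("2–4 times a week", 3.0, "week"),
            ("2-4 times per week", 3.0, "week"),
            ("once a day", 1.0, "day"),
            ("twice a month", 2.0, "month"),
            ("5 times per year", 5.0, "year"),
            ("daily", 1.0, "day"),
            ("every day", 1.0, "day"),
        ],
    )
    def test_patterns(self, label, amount, unit):
        f = parse_frequency(label)
        assert f is not None
        assert (f.amount, f.time_unit) == (amount, unit)

    def test_non_frequency_label(self):
        assert parse_frequency("Male") is None

    def test_rate_normalisation(self):
        assert parse_frequency("7 times a week").rate_per_day == pytest.approx(1.0)

    def test_nearest_rate_wins(self):
        targets = _cats(("a", "1–3 times per week"), ("b", "5–7 times per week"))
        source = _cats(("s", "2–4 times a week"))
        mapped, leftover = match_frequency(targets, source)
        assert mapped.as_dict() == {"s": "a"} and leftover == []

    def test_identical_labels_map_identically(self):
        cats = _cats(("x", "2–4 times a week"))
        mapped, _ = match_frequency(cats, cats)
        assert mapped.as_dict() == {"x": "x"}

    def test_many_sources_converge_on_one_target(self):
        targets = _cats(("1", "never eats"), ("2", "every day"))
        sources = _cats(("a", "daily"), ("b", "6–7 times a week"))
        mapped, leftover = match_frequency(targets, sources)
        assert mapped.as_dict() == {"a": "2", "b": "2"}

    def test_non_parsing_sources_left_over(self):
        targets = _cats(("1", "once a week"))
        sources = _cats(("a", "sometimes"), ("b", "twice a week"))
        mapped, leftover = match_frequency(targets, sources)
        assert mapped.as_dict() == {"b": "1"}
        assert [c.code for c in leftover] == ["a"]


class TestRules:
    def test_never_maps_to_no(self):
        target = _cats(("0", "No"), ("1", "Yes"))
        source = _cats(("9", "Never"))
        mapped, leftover = apply_rules(target, source, default_rules())
        assert mapped.as_dict() == {"9": "0"}
        assert mapped.provenance_of("9") == "rule"

    def test_empty_rule_list_passes_everything_through(self):
        target = _cats(("0", "No"))
        source = _cats(("9", "Never"))
        mapped, leftover = apply_rules(target, source, [])
        assert mapped.pairs == [] and [c.code for c in leftover] == ["9"]

    def test_rule_overrides_lexical_best(self):
        # lexically 'Never' is closest to 'Never married'; the rule forces 'No'
        target = _cats(("0", "No"), ("1", "Never married"))
        source = _cats(("9", "Never"))
        combined = match_categories(target, source, default_rules())
        assert combined.as_dict() == {"9": "0"}
        assert combined.provenance_of("9") == "rule"
        without_rules = match_categories(target, source, [])
        assert without_rules.as_dict() == {"9": "1"}

    def test_conflicting_equal_priority_rules_raise(self):
        rules = [
            MatchRule("never", "no", priority=5),
            MatchRule("never", "none", priority=5),
        ]
        with pytest.raises(RuleConfigurationError):
            apply_rules(_cats(("0", "no"), ("1", "none")), _cats(("9", "never")), rules)

    def test_null_target_drops_source_code(self):
        mapped, leftover = apply_rules(
            _cats(("0", "No")), _cats(("9", "Unknown")), default_rules()
        )
        assert mapped.null_mapped == ["9"] and not leftover


class TestCombined:
    def test_gender_is_lexical_provenance(self):
        result = match_categories(
            _cats(("0", "Male"), ("1", "Female")), _cats(("1", "Male"), ("2", "Female"))
        )
        assert result.as_dict() == {"1": "0", "2": "1"}
        assert {p.provenance for p in result.pairs} == {"lexical"}

    def test_consumption_scale_is_frequency_provenance(self):
        result = match_categories(
            _cats(("1", "1–3 times a month"), ("2", "2–4 times a week")),
            _cats(("a", "once a month"), ("b", "3 times per week")),
        )
        assert {p.provenance for p in result.pairs} == {"frequency"}
        assert result.as_dict() == {"a": "1", "b": "2"}

    def test_rules_dominate_frequency_dominates_lexical(self):
        target = _cats(("0", "No"), ("1", "2–4 times a week"), ("2", "something else"))
        source = _cats(("x", "Never"), ("y", "3 times a week"), ("z", "something else"))
        result = match_categories(target, source, default_rules())
        assert result.provenance_of("x") == "rule"
        assert result.provenance_of("y") == "frequency"
        assert result.provenance_of("z") == "lexical"
        assert result.as_dict() == {"x": "0", "y": "1", "z": "2"}


class TestSnippet:
    def test_gender_snippet_text(self):
        cmap = match_lexical(
            _cats(("0", "Male"), ("1", "Female")), _cats(("1", "Male"), ("2", "Female"))
        )
        assert generate_map_snippet(cmap, "SEX") == "$('SEX').map({'1':'0','2':'1'})"

    def test_single_pair(self):
        cmap = match_lexical(_cats(("0", "No")), _cats(("9", "No")))
        assert generate_map_snippet(cmap, "A") == "$('A').map({'9':'0'})"

    def test_snippet_round_trips_through_interpreter(self):
        target = _cats(("0", "Male"), ("1", "Female"))
        source = _cats(("1", "Male"), ("2", "Female"))
        cmap = match_lexical(target, source)
        script = dsl.parse(generate_map_snippet(cmap, "SEX"))
        for src_code, tgt_code in cmap.as_dict().items():
            assert dsl.evaluate(script, {"SEX": src_code}).value == tgt_code

    def test_empty_map_is_generation_error(self):
        from phenoconnect.categories import CategoryMap

        with pytest.raises(CategoryMatchError):
            generate_map_snippet(CategoryMap(), "X")
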