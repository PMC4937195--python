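"""Scoring search results and generated algorithms against a gold standard."""

import pytest

from phenoconnect import dsl
from phenoconnect.emx import Attribute
from phenoconnect.evaluate import (
    EvaluationReport,
    classify_algorithm,
    classify_search,
    evaluate_project,
    functionally_equivalent,
)
from phenoconnect.generate import generate_project
from phenoconnect.search import MatchCandidate
from phenoconnect.synth import generate_fixture

from conftest import make_entity


def _cands(*names):
    return [
        MatchCandidate(
            source_attribute=Attribute(name=n, entity="bb", label=n),
            score=1.0 / (i + 1),
            rank=i + 1,
        )
        for i, n in enumerate(names)
    ]


class TestClassifySearch:
    def test_gold_at_rank_one_is_perfect(self):
        assert classify_search(_cands("gold", "other"), frozenset({"gold"})) == "perfect"

    def test_all_gold_within_top20_is_good(self):
        names = [f"n{i}" for i in range(20)]
        names[1], names[14] = "g1", "g2"
        assert classify_search(_cands(*names), frozenset({"g1", "g2"})) == "good"

    def test_gold_beyond_rank20_is_bad(self):
        names = [f"n{i}" for i in range(24)] + ["gold"]
        assert classify_search(_cands(*names), frozenset({"gold"})) == "bad"

    def test_empty_shortlist_is_bad(self):
        assert classify_search([], frozenset({"gold"})) == "bad"


@pytest.fixture()
def height_entity():
    return make_entity(
        "bb",
        [("Height", "decimal", "Height in cm")],
        rows=[{"Height": str(v)} for v in (150, 163, 180, 195)] + [{"Height": None}],
    )


class TestFunctionalEquivalence:
    def test_div_equals_unit_chain(self, height_entity, unit_engine):
        a = dsl.parse("$('Height').div(100).value()")
        b = dsl.parse("$('Height').unit('cm').toUnit('m').value()")
        assert functionally_equivalent(a, b, height_entity, unit_engine)

    def test_script_equivalent_to_itself(self, height_entity, unit_engine):
        a = dsl.parse("$('Height').div(100).value()")
        assert functionally_equivalent(a, a, height_entity, unit_engine)

    def test_incomplete_map_discriminated_by_data(self, unit_engine):
        data = make_entity(
            "bb",
            [("SEX", "string", "Sex")],
            rows=[{"SEX": "1"}, {"SEX": "2"}],
        )
        full = dsl.parse("$('SEX').map({'1':'0','2':'1'})")
        partial = dsl.parse("$('SEX').map({'1':'0'})")
        assert not functionally_equivalent(full, partial, data, unit_engine)
        # without a discriminating row they agree
        data.rows = [{"SEX": "1"}]
        assert functionally_equivalent(full, partial, data, unit_engine)


class TestClassifyAlgorithm:
    def test_equivalent_bmi_variants_are_perfect(self, unit_engine):
        data = make_entity(
            "bb",
            [("W", "decimal", "Weight (kg)"), ("H", "decimal", "Length (cm)")],
            rows=[{"W": "81", "H": "180"}, {"W": "66", "H": "150"}],
        )
        generated = dsl.parse("$('W').div($('H').div(100).pow(2)).value()")
        reference = "$('W').div($('H').unit('cm').toUnit('m').pow(2)).value()"
        assert classify_algorithm(generated, reference, data, unit_engine) == "perfect"

    def test_half_complete_map_is_good(self, unit_engine):
        # the data exercises an unmapped code, so the scripts are not
        # functionally equivalent, yet half the reference pairs are present
        data = make_entity(
            "bb", [("F", "string", "Freq")], rows=[{"F": "1"}, {"F": "3"}]
        )
        generated = dsl.parse("$('F').map({'1':'a','2':'b'})")
        reference = "$('F').map({'1':'a','2':'b','3':'c','4':'d'})"
        assert classify_algorithm(generated, reference, data, unit_engine) == "good"

    def test_contradicting_map_is_bad(self, unit_engine):
        data = make_entity("bb", [("F", "string", "Freq")], rows=[{"F": "1"}])
        generated = dsl.parse("$('F').map({'1':'x','2':'b'})")
        reference = "$('F').map({'1':'a','2':'b'})"
        assert classify_algorithm(generated, reference, data, unit_engine) == "bad"

    def test_right_attribute_wrong_conversion_is_good(self, unit_engine):
        data = make_entity(
            "bb", [("H", "decimal", "Height in cm")], rows=[{"H": "180"}]
        )
        generated = dsl.parse("$('H').value()")  # conversion missing
        reference = "$('H').div(100).value()"
        assert classify_algorithm(generated, reference, data, unit_engine) == "good"

    def test_wrong_source_attribute_is_bad(self, unit_engine):
        data = make_entity(
            "bb",
            [("H", "decimal", "Height"), ("W", "decimal", "Weight")],
            rows=[{"H": "180", "W": "80"}],
        )
        generated = dsl.parse("$('W').value()")
        assert classify_algorithm(generated, "$('H').value()", data, unit_engine) == "bad"

    def test_missing_algorithm_is_bad(self, unit_engine):
        data = make_entity("bb", [("H", "decimal", "Height")], rows=[])
        assert classify_algorithm(None, "$('H').value()", data, unit_engine) == "bad"


class TestReport:
    def test_all_perfect_project_is_100_percent(self):
        report = EvaluationReport(
            per_cell={("a", "s"): ("perfect", "perfect"), ("b", "s"): ("perfect", "perfect")}
        )
        table = report.percentage_table()
        assert table.loc["perfect", "perfect"] == 100.0
        assert report.useful_percentage == 100.0

    def test_percentages_sum_to_100(self):
        report = EvaluationReport(
            per_cell={
                ("a", "s"): ("perfect", "good"),
                ("b", "s"): ("good", "bad"),
                ("c", "s"): ("bad", "perfect"),
            }
        )
        assert report.percentage_table().values.sum() == pytest.approx(100.0, abs=0.1)

    def test_useful_cells_follow_colour_coding(self):
        report = EvaluationReport(
            per_cell={
                ("a", "s"): ("bad", "perfect"),  # useful corner
                ("b", "s"): ("perfect", "bad"),  # useful corner
                ("c", "s"): ("bad", "good"),  # not useful
                ("d", "s"): ("good", "good"),  # useful
            }
        )
        assert report.useful_percentage == pytest.approx(75.0)


class TestFixtureProperties:
    def test_same_seed_reproduces_fixture(self):
        a = generate_fixture(7, n_rows=10, n_biobanks=2)
        b = generate_fixture(7, n_rows=10, n_biobanks=2)
        for ea, eb in zip(a.sources, b.sources):
            for enta, entb in zip(ea.entities.values(), eb.entities.values()):
                assert enta.rows == entb.rows

    def test_gold_attributes_exist_in_sources(self, fixture_bundle):
        by_name = {s.name: s for s in fixture_bundle.sources}
        for (tname, sname), entry in fixture_bundle.gold.entries.items():
            attrs = {a.name for a in by_name[sname].iter_attributes()}
            assert entry.source_attributes <= attrs

    def test_cm_biobank_is_100x_m_biobank(self, fixture_bundle):
        cm_rows = fixture_bundle.sources[0].entity("biobank1").rows
        m_rows = fixture_bundle.sources[2].entity("biobank3").rows
        from decimal import Decimal

        for r_cm, r_m in zip(cm_rows, m_rows):
            if r_cm["HEIGHT"] is None or r_m["BODY_LENGTH"] is None:
                continue
            assert Decimal(r_cm["HEIGHT"]) == Decimal(r_m["BODY_LENGTH"]) * 100

    def test_gold_tsv_round_trip(self, fixture_bundle):
        from phenoconnect.synth import GoldStandard

        again = GoldStandard.from_tsv(fixture_bundle.gold.to_tsv())
        assert again.entries == fixture_bundle.gold.entries


def test_hand_classified_small_project_matches_report(unit_engine):
    """Cross-check evaluate_project against a by-hand classification of a
    2-biobank, 6-target fixture."""
    fx = generate_fixture(11, n_rows=12, n_biobanks=2)
    project = generate_project(
        fx.target, fx.sources, store=fx.store, unit_engine=unit_engine
    )
    report = evaluate_project(
        project, fx.gold, fx.sources, store=fx.store, unit_engine=unit_engine
    )
    assert report.n_cells == 12
    # every core mapping is found at rank 1 and the generated script matches
    # the reference on the data, so by hand every cell is (perfect, perfect)
    assert all(cell == ("perfect", "perfect") for cell in report.per_cell.values())
    assert report.useful_percentage == 100.0
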