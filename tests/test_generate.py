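"""Algorithm generation: templates, slot filling, fallbacks, projects."""

from decimal import Decimal

import pytest

from phenoconnect import dsl
from phenoconnect.emx import Attribute
from phenoconnect.generate import (
    TemplateFillError,
    default_templates,
    fill_template,
    find_template,
    generate_algorithm,
    generate_project,
)
from phenoconnect.search import MatchCandidate, index_source, shortlist

from conftest import make_entity, make_schema


def _attr(name, label, description="", data_type="decimal"):
    return Attribute(name=name, entity="bb", label=label, description=description, data_type=data_type)


def _cand(attr, rank=1, score=1.0):
    return MatchCandidate(source_attribute=attr, score=score, rank=rank)


@pytest.fixture(scope="module")
def catalogue():
    return default_templates()


@pytest.fixture()
def cohort_b():
    """A source dictionary with weight in kg and length in cm."""
    ent = make_entity(
        "cohort_b",
        [
            ("WEIGHT_1", "decimal", "Weight (kg)"),
            ("LENGT_1", "decimal", "Length (cm)"),
            ("PATID", "int", "Participant identifier"),
        ],
        rows=[
            {"WEIGHT_1": "81", "LENGT_1": "180", "PATID": "1"},
            {"WEIGHT_1": "66", "LENGT_1": "150", "PATID": "2"},
        ],
    )
    return make_schema("cohort_b", ent)


class TestFindTemplate:
    def test_bmi_target_triggers_bmi_template(self, catalogue):
        tpl = find_template(_attr("bmi", "Body Mass Index (kg/m^2)"), catalogue, [])
        assert tpl is not None and tpl.name == "bmi"

    def test_gender_target_triggers_nothing(self, catalogue):
        assert find_template(
            _attr("gender", "Gender", data_type="categorical"), catalogue, []
        ) is None

    def test_candidate_slot_match_proposes_template(self, catalogue):
        cand = _cand(_attr("LENGT_1", "Length (cm)"))
        tpl = find_template(_attr("x", "Unrelated label"), catalogue, [cand])
        assert tpl is not None and tpl.name == "bmi"


class TestFillTemplate:
    def test_bmi_with_cm_length_inserts_conversion(self, catalogue, unit_engine, cohort_b):
        bmi = next(t for t in catalogue if t.name == "bmi")
        cands = [
            _cand(_attr("WEIGHT_1", "Weight (kg)")),
            _cand(_attr("LENGT_1", "Length (cm)"), rank=2),
        ]
        algo = fill_template(bmi, cands, unit_engine)
        assert algo.script.referenced_attributes == {"WEIGHT_1", "LENGT_1"}
        value = dsl.evaluate(
            algo.script, {"WEIGHT_1": "81", "LENGT_1": "180"}, None, unit_engine
        ).value
        assert abs(value - Decimal("25")) < Decimal("1e-9")

    def test_slots_in_expected_units_need_no_conversion(self, catalogue, unit_engine):
        bmi = next(t for t in catalogue if t.name == "bmi")
        cands = [
            _cand(_attr("wt", "Weight in kg")),
            _cand(_attr("ht", "Height in m"), rank=2),
        ]
        algo = fill_template(bmi, cands, unit_engine)
        assert algo.text == "$('wt').div($('ht').pow(2)).value()"

    def test_wrong_dimension_candidate_fails_slot(self, catalogue, unit_engine):
        bmi = next(t for t in catalogue if t.name == "bmi")
        cands = [
            _cand(_attr("wt", "Weight in cm")),  # mass slot, length unit
            _cand(_attr("ht", "Height in m"), rank=2),
        ]
        with pytest.raises(TemplateFillError):
            fill_template(bmi, cands, unit_engine)

    def test_missing_slot_candidate_fails(self, catalogue, unit_engine):
        bmi = next(t for t in catalogue if t.name == "bmi")
        with pytest.raises(TemplateFillError, match="height"):
            fill_template(bmi, [_cand(_attr("wt", "Weight (kg)"))], unit_engine)


class TestGenerateAlgorithm:
    def test_unitless_target_assumes_source_unit(self, unit_engine):
        """With no unit on the target side, no conversion is generated."""
        source = make_schema(
            "bb",
            make_entity(
                "bb",
                [("height_cm", "decimal", "Height in cm"), ("weight_kg", "decimal", "Weight in kg")],
            ),
        )
        target = _attr("height", "Measured Standing Height")
        algo = generate_algorithm(target, source, unit_engine=unit_engine)
        assert algo.text == "$('height_cm').value()"
        assert algo.provenance == "rename"

    def test_unit_bearing_target_gets_conversion(self, unit_engine):
        source = make_schema(
            "bb", make_entity("bb", [("height_cm", "decimal", "Height in cm")])
        )
        target = _attr("height", "Standing height in m")
        algo = generate_algorithm(target, source, unit_engine=unit_engine)
        assert algo.text == "$('height_cm').div(100).value()"
        assert algo.provenance == "unit_conversion"

    def test_categorical_target_gets_map(self, unit_engine):
        source = make_schema(
            "bb",
            make_entity(
                "bb",
                [("SEX", "categorical", "Gender", [("1", "Male"), ("2", "Female")])],
            ),
        )
        target = Attribute(
            name="gender", entity="t", data_type="categorical", label="Gender"
        )
        from phenoconnect.emx import Category

        target.categories = [Category("0", "Male"), Category("1", "Female")]
        algo = generate_algorithm(target, source, unit_engine=unit_engine)
        assert algo.text == "$('SEX').map({'1':'0','2':'1'})"
        assert algo.provenance == "category_map"

    def test_bmi_template_path(self, unit_engine, cohort_b):
        """'Length (cm)' only becomes a height-slot candidate through the
        ontology synonym length-of-height, as in the real search."""
        from phenoconnect.synth import phenotype_store

        target = _attr("bmi", "Body Mass Index (kg/m^2)", "Weight over squared height")
        algo = generate_algorithm(
            target, cohort_b, store=phenotype_store(), unit_engine=unit_engine
        )
        assert algo.provenance == "template"
        assert algo.script.referenced_attributes == {"WEIGHT_1", "LENGT_1"}

    def test_no_candidates_gives_none(self, unit_engine):
        source = make_schema("bb", make_entity("bb", [("z", "string", "Zebra stripes")]))
        assert (
            generate_algorithm(_attr("height", "Height"), source, unit_engine=unit_engine)
            is None
        )


class TestProjectLevel:
    def test_cell_cardinality(self, fixture_bundle, unit_engine):
        project = generate_project(
            fixture_bundle.target,
            fixture_bundle.sources[:2],
            store=fixture_bundle.store,
            unit_engine=unit_engine,
        )
        n_targets = len(list(fixture_bundle.target.iter_data_attributes()))
        assert len(project.cells) == n_targets * 2

    def test_every_script_parses_and_references_source_attributes(
        self, fixture_bundle, unit_engine
    ):
        project = generate_project(
            fixture_bundle.target,
            fixture_bundle.sources,
            store=fixture_bundle.store,
            unit_engine=unit_engine,
        )
        by_name = {s.name: s for s in fixture_bundle.sources}
        for (tname, sname), cell in project.cells.items():
            if cell.algorithm is None:
                continue
            source_attrs = {a.name for a in by_name[sname].iter_attributes()}
            assert cell.script.referenced_attributes <= source_attrs

    def test_curated_cell_survives_regeneration(self, fixture_bundle, unit_engine):
        project = generate_project(
            fixture_bundle.target,
            fixture_bundle.sources[:1],
            store=fixture_bundle.store,
            unit_engine=unit_engine,
        )
        project.curate("stature", "biobank1", "$('HEIGHT').div(100).value()")
        generate_project(
            fixture_bundle.target,
            fixture_bundle.sources[:1],
            store=fixture_bundle.store,
            unit_engine=unit_engine,
            project=project,
        )
        cell = project.cell("stature", "biobank1")
        assert cell.state == "curated"
        assert cell.script_text == "$('HEIGHT').div(100).value()"

    def test_empty_source_gives_all_missing(self, fixture_bundle, unit_engine):
        from phenoconnect.emx import Entity, Schema

        empty = Schema(name="empty", entities={"empty": Entity(name="empty")})
        project = generate_project(
            fixture_bundle.target, [empty], store=fixture_bundle.store, unit_engine=unit_engine
        )
        assert all(c.state == "missing" for c in project.cells.values())

    def test_project_json_round_trip(self, fixture_bundle, unit_engine):
        from phenoconnect.generate import MappingProject

        project = generate_project(
            fixture_bundle.target,
            fixture_bundle.sources[:1],
            store=fixture_bundle.store,
            unit_engine=unit_engine,
        )
        again = MappingProject.from_json(project.to_json(), fixture_bundle.target)
        assert set(again.cells) == set(project.cells)
        for key, cell in project.cells.items():
            if cell.algorithm is not None:
                assert again.cells[key].script.canonical == cell.script.canonical


def test_chain_and_formula_styles_are_functionally_equivalent(unit_engine):
    source = make_schema(
        "bb",
        make_entity(
            "bb",
            [("height_cm", "decimal", "Height in cm")],
            rows=[{"height_cm": str(v)} for v in (150, 163, 180, 195)],
        ),
    )
    target = _attr("height", "Standing height in m")
    formula = generate_algorithm(
        target, source, unit_engine=unit_engine, snippet_style="formula"
    )
    chain = generate_algorithm(
        target, source, unit_engine=unit_engine, snippet_style="chain"
    )
    assert chain.text == "$('height_cm').unit('cm').toUnit('m').value()"
    ent = source.entity("bb")
    for row in ent.rows:
        a = dsl.evaluate(formula.script, row, ent, unit_engine).value
        b = dsl.evaluate(chain.script, row, ent, unit_engine).value
        assert abs(a - b) <= Decimal("1e-9")
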