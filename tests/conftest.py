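import io

import pytest

from phenoconnect.emx import Attribute, Category, Entity, Schema
from phenoconnect.ontology import load_ontology
from phenoconnect.synth import generate_fixture
from phenoconnect.units import UnitEngine


@pytest.fixture(scope="session")
def unit_engine():
    return UnitEngine()


@pytest.fixture(scope="session")
def fixture_bundle():
    """The packaged synthetic study: 3 biobanks, 50 participants, seed 42."""
    return generate_fixture(42, n_rows=50, n_biobanks=3)


@pytest.fixture()
def toy_store():
    """Tiny phenotype ontology: food > poultry > chicken, plus hypertension."""
    obo = """\
format-version: 1.2

[Term]
id: T:food
name: food

[Term]
id: T:poultry
name: poultry
is_a: T:food

[Term]
id: T:chicken
name: chicken
synonym: "breaded chicken" EXACT []
is_a: T:poultry

[Term]
id: T:htn
name: Hypertension
synonym: "high blood pressure" EXACT []
"""
    return load_ontology(io.StringIO(obo))


def make_entity(name, attr_specs, rows=()):
    """attr_specs: list of (name, data_type, label[, categories])."""
    ent = Entity(name=name)
    for spec in attr_specs:
        attr = Attribute(name=spec[0], entity=name, data_type=spec[1], label=spec[2])
        if len(spec) > 3:
            attr.categories = [Category(c, l) for c, l in spec[3]]
            attr.ref_entity = f"{spec[0]}_options"
        ent.attributes.append(attr)
    ent.rows = [dict(r) for r in rows]
    return ent


def make_schema(name, entity):
    schema = Schema(name=name, entities={entity.name: entity})
    for attr in entity.attributes:
        if attr.ref_entity:
            lookup = Entity(
                name=attr.ref_entity,
                attributes=[
                    Attribute(name="code", entity=attr.ref_entity),
                    Attribute(name="label", entity=attr.ref_entity),
                ],
                rows=[{"code": c.code, "label": c.label} for c in attr.categories],
            )
            schema.entities[attr.ref_entity] = lookup
    return schema
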