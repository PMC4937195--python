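"""Synthetic multi-biobank fixtures with gold-standard mappings.

The generator emulates the setting the engine is built for: one pooled-study
target schema (height, weight, gender, BMI, a food-frequency scale and
hypertension) and up to three source biobanks whose dictionaries diverge in
terminology (Height / Length / Body length), units (cm vs m, kg vs g),
category codings (1/2 vs M/F vs 0/1 for gender) and frequency scales.
One target (hypertension) shares no label token with its source attributes
and is only findable through ontology synonyms. A small phenotype ontology
and per-cell gold mappings with reference algorithms accompany the data.

Everything is deterministic given the seed; per participant, the cm-coded
height is exactly 100x the m-coded biobank's value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional

import numpy as np

from .emx import Attribute, Category, Entity, Schema, write_emx
from .ontology import OntologyStore, load_ontology

PHENOTYPE_OBO = """\
format-version: 1.2
ontology: phenoconnect-synthetic-phenotypes

[Term]
id: PHENO:0001
name: gender
synonym: "sex" EXACT []
synonym: "geslacht" EXACT []

[Term]
id: PHENO:0002
name: hypertension
synonym: "high blood pressure" EXACT []
synonym: "elevated blood pressure" EXACT []

[Term]
id: PHENO:0003
name: weight
synonym: "body weight" EXACT []
synonym: "mass" EXACT []
synonym: "body mass" EXACT []

[Term]
id: PHENO:0004
name: height
synonym: "body height" EXACT []
synonym: "standing height" EXACT []
synonym: "length" EXACT []
synonym: "body length" EXACT []
synonym: "stature" EXACT []

[Term]
id: PHENO:0005
name: body mass index
synonym: "bmi" EXACT []
synonym: "quetelet index" EXACT []

[Term]
id: PHENO:0006
name: food

[Term]
id: PHENO:0007
name: potato
synonym: "aardappel" EXACT []
is_a: PHENO:0006

[Term]
id: PHENO:0008
name: poultry
is_a: PHENO:0006

[Term]
id: PHENO:0009
name: chicken
synonym: "breaded chicken" EXACT []
is_a: PHENO:0008
"""


@dataclass(frozen=True)
class GoldEntry:
    """Human-curated truth for one (target attribute, source biobank) cell."""

    source_attributes: frozenset[str]
    reference_script: str


@dataclass
class GoldStandard:
    """Gold mappings keyed by (target attribute name, source schema name)."""

    entries: dict[tuple[str, str], GoldEntry] = field(default_factory=dict)

    def get(self, target_name: str, source_name: str) -> Optional[GoldEntry]:
        return self.entries.get((target_name, source_name))

    def to_tsv(self) -> str:
        lines = ["target\tsource\tsource_attrs\treference_script"]
        for (t, s), e in sorted(self.entries.items()):
            lines.append(
                f"{t}\t{s}\t{';'.join(sorted(e.source_attributes))}\t{e.reference_script}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "GoldStandard":
        gold = cls()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for ln in lines[1:]:
            t, s, attrs, script = ln.split("\t")
            gold.entries[(t, s)] = GoldEntry(
                source_attributes=frozenset(a for a in attrs.split(";") if a),
                reference_script=script,
            )
        return gold


@dataclass
class Fixture:
    """A complete synthetic study: target schema, sources, gold, ontology."""

    target: Schema
    sources: list[Schema]
    gold: GoldStandard
    store: OntologyStore
    obo_text: str = PHENOTYPE_OBO


def phenotype_store() -> OntologyStore:
    return load_ontology(io.StringIO(PHENOTYPE_OBO))


def _cat_entity(name: str, pairs: list[tuple[str, str]]) -> Entity:
    ent = Entity(
        name=name,
        attributes=[
            Attribute(name="code", entity=name),
            Attribute(name="label", entity=name),
        ],
        rows=[{"code": c, "label": l} for c, l in pairs],
    )
    return ent


def _attach_categories(schema: Schema) -> None:
    for attr in schema.iter_attributes():
        if attr.is_categorical and attr.ref_entity:
            ref = schema.entities[attr.ref_entity]
            attr.categories = [
                Category(code=r["code"], label=r["label"]) for r in ref.rows
            ]


def _build_target() -> Schema:
    schema = Schema(name="target")
    ent = Entity(name="targets")
    schema.entities["targets"] = ent

    def add(name, dtype, label, description="", ref=None):
        ent.attributes.append(
            Attribute(
                name=name,
                entity="targets",
                data_type=dtype,
                label=label,
                description=description,
                ref_entity=ref,
            )
        )

    add("stature", "decimal", "Standing height in m", "Measured standing height")
    add("body_weight", "decimal", "Body weight in kg", "Measured body weight")
    add("gender", "categorical", "Gender", "Gender", ref="gender_options")
    add(
        "bmi",
        "decimal",
        "Body Mass Index (kg/m^2)",
        "Weight divided by squared standing height",
    )
    add(
        "potato_freq",
        "categorical",
        "Frequency of potato consumption",
        "How often the participant eats potatoes",
        ref="potato_options",
    )
    add("hypertension", "categorical", "Hypertension", "", ref="yesno_options")

    schema.entities["gender_options"] = _cat_entity(
        "gender_options", [("0", "Male"), ("1", "Female")]
    )
    schema.entities["potato_options"] = _cat_entity(
        "potato_options",
        [
            ("1", "never"),
            ("2", "1-3 times a month"),
            ("3", "2-4 times a week"),
            ("4", "5-7 times a week"),
        ],
    )
    schema.entities["yesno_options"] = _cat_entity(
        "yesno_options", [("0", "No"), ("1", "Yes")]
    )
    _attach_categories(schema)
    return schema


# per-biobank dictionary layouts; data columns reference the base values
_BIOBANKS = [
    {
        "name": "biobank1",
        "id_attr": "PARTICIPANT",
        "attrs": [
            ("HEIGHT", "decimal", "Height in cm", "", None),
            ("WEIGHT", "decimal", "Weight in kg", "", None),
            ("SEX", "categorical", "Sex", "Sex of the participant", "sex_codes"),
            (
                "POTATO",
                "categorical",
                "Potato consumption",
                "How often do you eat potatoes",
                "potato_codes",
            ),
            (
                "BP",
                "categorical",
                "Elevated blood pressure",
                "Has a doctor ever said you have elevated blood pressure",
                "yn_codes",
            ),
            ("AGE", "int", "Age of participant", "", None),
            ("EDU", "string", "Highest education level completed", "", None),
        ],
        "cats": {
            "sex_codes": [("1", "Male"), ("2", "Female")],
            "potato_codes": [
                ("1", "never"),
                ("2", "1-2 times a week"),
                ("3", "3-5 times a week"),
                ("4", "6-7 times a week"),
            ],
            "yn_codes": [("Y", "Yes"), ("N", "No")],
        },
        "height": ("HEIGHT", "cm"),
        "weight": ("WEIGHT", "kg"),
        "gender": ("SEX", {"m": "1", "f": "2"}),
        "potato": ("POTATO", ["1", "2", "3", "4"]),
        "bp": ("BP", {"y": "Y", "n": "N"}),
        "gold": {
            "stature": ("HEIGHT", "$('HEIGHT').div(100).value()"),
            "body_weight": ("WEIGHT", "$('WEIGHT').value()"),
            "gender": ("SEX", "$('SEX').map({'1':'0','2':'1'})"),
            "bmi": (
                "WEIGHT;HEIGHT",
                "$('WEIGHT').div($('HEIGHT').div(100).pow(2)).value()",
            ),
            "potato_freq": (
                "POTATO",
                "$('POTATO').map({'1':'1','2':'2','3':'3','4':'4'})",
            ),
            "hypertension": ("BP", "$('BP').map({'N':'0','Y':'1'})"),
        },
    },
    {
        "name": "biobank2",
        "id_attr": "PATID",
        "attrs": [
            ("LENGT_1", "decimal", "Length (cm)", "", None),
            ("WEIGHT_1", "decimal", "Weight (kg)", "", None),
            (
                "GESLACHT",
                "categorical",
                "Sex of participant",
                "",
                "geslacht_codes",
            ),
            (
                "AARDAPPEL",
                "categorical",
                "Potato consumption frequency",
                "",
                "freq_codes",
            ),
            (
                "HT",
                "categorical",
                "High blood pressure diagnosed",
                "",
                "jn_codes",
            ),
            ("MED1", "string", "Use of cholesterol lowering medication", "", None),
        ],
        "cats": {
            "geslacht_codes": [("M", "Male"), ("F", "Female")],
            "freq_codes": [
                ("0", "never"),
                ("1", "2-4 times per week"),
                ("2", "5-6 times per week"),
                ("3", "daily"),
            ],
            "jn_codes": [("1", "Yes"), ("0", "No")],
        },
        "height": ("LENGT_1", "cm"),
        "weight": ("WEIGHT_1", "kg"),
        "gender": ("GESLACHT", {"m": "M", "f": "F"}),
        "potato": ("AARDAPPEL", ["0", "1", "2", "3"]),
        "bp": ("HT", {"y": "1", "n": "0"}),
        "gold": {
            "stature": ("LENGT_1", "$('LENGT_1').div(100).value()"),
            "body_weight": ("WEIGHT_1", "$('WEIGHT_1').value()"),
            "gender": ("GESLACHT", "$('GESLACHT').map({'F':'1','M':'0'})"),
            "bmi": (
                "WEIGHT_1;LENGT_1",
                "$('WEIGHT_1').div($('LENGT_1').div(100).pow(2)).value()",
            ),
            "potato_freq": (
                "AARDAPPEL",
                "$('AARDAPPEL').map({'0':'1','1':'3','2':'4','3':'4'})",
            ),
            "hypertension": ("HT", "$('HT').map({'0':'0','1':'1'})"),
        },
    },
    {
        "name": "biobank3",
        "id_attr": "ID",
        "attrs": [
            ("BODY_LENGTH", "decimal", "Body length in m", "", None),
            ("BODY_MASS", "decimal", "Body mass in g", "", None),
            ("GENDER", "categorical", "Gender", "", "gender_codes"),
            (
                "POT_FREQ",
                "categorical",
                "Eating potatoes",
                "How frequently does the participant eat potatoes",
                "pot_codes",
            ),
            ("HBP", "categorical", "Hypertension", "", "noyes_codes"),
            ("EMPLOY", "string", "Current employment status", "", None),
        ],
        "cats": {
            "gender_codes": [("0", "Male"), ("1", "Female")],
            "pot_codes": [
                ("1", "never"),
                ("2", "once a week"),
                ("3", "every day"),
            ],
            "noyes_codes": [("0", "No"), ("1", "Yes")],
        },
        "height": ("BODY_LENGTH", "m"),
        "weight": ("BODY_MASS", "g"),
        "gender": ("GENDER", {"m": "0", "f": "1"}),
        "potato": ("POT_FREQ", ["1", "2", "3"]),
        "bp": ("HBP", {"y": "1", "n": "0"}),
        "gold": {
            "stature": ("BODY_LENGTH", "$('BODY_LENGTH').value()"),
            "body_weight": ("BODY_MASS", "$('BODY_MASS').div(1000).value()"),
            "gender": ("GENDER", "$('GENDER').map({'0':'0','1':'1'})"),
            "bmi": (
                "BODY_MASS;BODY_LENGTH",
                "$('BODY_MASS').div(1000).div($('BODY_LENGTH').pow(2)).value()",
            ),
            "potato_freq": ("POT_FREQ", "$('POT_FREQ').map({'1':'1','2':'2','3':'4'})"),
            "hypertension": ("HBP", "$('HBP').map({'0':'0','1':'1'})"),
        },
    },
]


def generate_fixture(seed: int, n_rows: int = 50, n_biobanks: int = 3) -> Fixture:
    """Build the deterministic synthetic study for a given seed.

    Participants get a base height (cm, integer), weight (kg, integer),
    gender, potato-frequency category and blood-pressure status; each
    biobank stores these under its own attribute names, units and codings.
    A few height cells are left missing to exercise null propagation.
    """
    if not 1 <= n_biobanks <= len(_BIOBANKS):
        raise ValueError(f"n_biobanks must be in 1..{len(_BIOBANKS)}")
    rng = np.random.default_rng(seed)
    target = _build_target()

    heights_cm = rng.integers(150, 196, size=n_rows)
    weights_kg = rng.integers(50, 111, size=n_rows)
    genders = rng.choice(["m", "f"], size=n_rows)
    bps = rng.choice(["y", "n"], size=n_rows, p=[0.3, 0.7])
    missing_height = set(
        rng.choice(n_rows, size=max(1, n_rows // 25), replace=False).tolist()
    ) if n_rows >= 2 else set()

    sources: list[Schema] = []
    gold = GoldStandard()
    for spec in _BIOBANKS[:n_biobanks]:
        schema = Schema(name=spec["name"])
        ent = Entity(name=spec["name"])
        schema.entities[spec["name"]] = ent
        ent.attributes.append(Attribute(name=spec["id_attr"], entity=spec["name"], data_type="int"))
        for name, dtype, label, desc, ref in spec["attrs"]:
            ent.attributes.append(
                Attribute(
                    name=name,
                    entity=spec["name"],
                    data_type=dtype,
                    label=label,
                    description=desc,
                    ref_entity=ref,
                )
            )
        for cat_name, pairs in spec["cats"].items():
            schema.entities[cat_name] = _cat_entity(cat_name, pairs)
        _attach_categories(schema)

        h_attr, h_unit = spec["height"]
        w_attr, w_unit = spec["weight"]
        g_attr, g_codes = spec["gender"]
        p_attr, p_codes = spec["potato"]
        b_attr, b_codes = spec["bp"]
        potato_draw = rng.integers(0, len(p_codes), size=n_rows)
        for i in range(n_rows):
            cm = int(heights_cm[i])
            if h_unit == "cm":
                h_val = str(cm)
            else:
                h_val = str(Decimal(cm) / Decimal(100))
            kg = int(weights_kg[i])
            w_val = str(kg) if w_unit == "kg" else str(kg * 1000)
            row = {
                spec["id_attr"]: str(i + 1),
                h_attr: None if i in missing_height else h_val,
                w_attr: w_val,
                g_attr: g_codes[genders[i]],
                p_attr: p_codes[int(potato_draw[i])],
                b_attr: b_codes[bps[i]],
            }
            for name, dtype, label, desc, ref in spec["attrs"]:
                if name not in row:
                    row[name] = None
            ent.rows.append(row)

        for target_name, (attr_names, script) in spec["gold"].items():
            gold.entries[(target_name, spec["name"])] = GoldEntry(
                source_attributes=frozenset(attr_names.split(";")),
                reference_script=script,
            )
        sources.append(schema)

    return Fixture(target=target, sources=sources, gold=gold, store=phenotype_store())


def write_fixture(fixture: Fixture, directory: str | Path, dialect: str = "csv") -> dict[str, Path]:
    """Dump a fixture to disk: EMX workbooks, the ontology and the gold TSV.

    Returns the paths written, keyed by role (``target``, source names,
    ``ontology``, ``gold``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    suffix = ".xlsx" if dialect == "xlsx" else ""
    tpath = directory / f"target{suffix}"
    write_emx(fixture.target, tpath)
    out["target"] = tpath
    for src in fixture.sources:
        spath = directory / f"{src.name}{suffix}"
        write_emx(src, spath)
        out[src.name] = spath
    opath = directory / "phenotypes.obo"
    opath.write_text(fixture.obo_text, encoding="utf-8")
    out["ontology"] = opath
    gpath = directory / "gold.tsv"
    gpath.write_text(fixture.gold.to_tsv(), encoding="utf-8")
    out["gold"] = gpath
    return out
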