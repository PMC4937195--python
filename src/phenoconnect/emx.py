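"""Entity-Attribute (EMX-style) metadata model.

A dataset is exchanged as a workbook: one ``attributes`` sheet describing
every column of every table (entity), plus one data sheet per entity.
Both xlsx workbooks and directories of CSV files (one file per sheet) are
accepted. Category and cross-reference (xref) attributes point at another
entity whose rows carry ``code``/``label`` pairs.

Cell values are kept as strings and typed on access; an empty cell or the
literal ``NA`` is the missing-value sentinel and becomes ``None``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import openpyxl

log = logging.getLogger(__name__)

DATA_TYPES = frozenset(
    {"string", "int", "decimal", "categorical", "xref", "date", "bool", "text"}
)

#: Cell spellings that denote a missing value.
MISSING_TOKENS = frozenset({"", "NA"})

#: Fixed column dialect of the ``attributes`` sheet; extra columns are
#: ignored with a logged warning.
ATTRIBUTE_COLUMNS = ("name", "entity", "dataType", "label", "description", "refEntity")


class EmxError(Exception):
    """Base class for EMX reading/validation problems."""


class EmxFormatError(EmxError):
    """The workbook does not have the expected shape (e.g. no attributes sheet)."""


class EmxValidationError(EmxError):
    """The metadata violates a model invariant (bad type, dangling reference)."""


def _null(cell: Optional[str]) -> Optional[str]:
    if cell is None:
        return None
    cell = str(cell)
    return None if cell.strip() in MISSING_TOKENS else cell


@dataclass(frozen=True)
class Category:
    """One allowed value of a categorical attribute: a code and its label."""

    code: str
    label: str


@dataclass
class Attribute:
    """One variable of a target schema or source data dictionary."""

    name: str
    entity: str
    data_type: str = "string"
    label: str = ""
    description: str = ""
    ref_entity: Optional[str] = None
    categories: list[Category] = field(default_factory=list)

    @property
    def is_categorical(self) -> bool:
        return self.data_type in ("categorical", "xref")

    @property
    def category_codes(self) -> list[str]:
        return [c.code for c in self.categories]

    def category_label(self, code: str) -> Optional[str]:
        for c in self.categories:
            if c.code == code:
                return c.label
        return None


@dataclass
class Entity:
    """A table: ordered attributes (columns) plus data rows.

    Row cells are strings or ``None`` (missing), keyed by attribute name.
    """

    name: str
    attributes: list[Attribute] = field(default_factory=list)
    rows: list[dict[str, Optional[str]]] = field(default_factory=list)

    def attribute(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(f"entity {self.name!r} has no attribute {name!r}")

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]


@dataclass
class Schema:
    """A named collection of entities (a target DataSchema or one source)."""

    entities: dict[str, Entity] = field(default_factory=dict)
    name: str = ""

    def entity(self, name: str) -> Entity:
        return self.entities[name]

    def iter_attributes(self) -> Iterable[Attribute]:
        for ent in self.entities.values():
            yield from ent.attributes

    @property
    def lookup_entity_names(self) -> set[str]:
        """Entities that only serve as category/xref code lists."""
        return {a.ref_entity for a in self.iter_attributes() if a.ref_entity}

    def iter_data_attributes(self) -> Iterable[Attribute]:
        """Attributes of proper data entities (code/label lookup sheets excluded)."""
        lookups = self.lookup_entity_names
        for ent in self.entities.values():
            if ent.name in lookups:
                continue
            yield from ent.attributes


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_schema`."""

    entity: str
    attribute: str
    row: Optional[int]
    message: str


# ---------------------------------------------------------------------------
# reading


def _read_sheets(path: Path) -> dict[str, list[list[Optional[str]]]]:
    """Return sheet name -> list of rows (cells as str/None) for either dialect."""
    sheets: dict[str, list[list[Optional[str]]]] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.csv")):
            with open(f, newline="", encoding="utf-8") as fh:
                sheets[f.stem] = [list(r) for r in csv.reader(fh)]
    elif path.suffix.lower() == ".xlsx":
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        for ws in wb.worksheets:
            rows = []
            for r in ws.iter_rows(values_only=True):
                rows.append([None if v is None else str(v) for v in r])
            sheets[ws.title] = rows
        wb.close()
    else:
        raise EmxFormatError(f"unsupported path (need .xlsx or CSV directory): {path}")
    return sheets


def _sheet_records(rows: list[list[Optional[str]]]) -> list[dict[str, Optional[str]]]:
    if not rows:
        return []
    header = [("" if h is None else str(h).strip()) for h in rows[0]]
    out = []
    for r in rows[1:]:
        if all(_null(c) is None for c in r):
            continue
        rec = {}
        for i, col in enumerate(header):
            if not col:
                continue
            rec[col] = _null(r[i]) if i < len(r) else None
        out.append(rec)
    return out


def read_emx(path: str | Path, name: str = "") -> Schema:
    """Load and validate a workbook (xlsx) or CSV directory into a :class:`Schema`.

    Raises
    ------
    EmxFormatError
        if no ``attributes`` sheet is present.
    EmxValidationError
        on an unknown data type or an unresolvable category/xref reference.
    """
    path = Path(path)
    if not path.exists():
        raise EmxFormatError(f"no such path: {path}")
    sheets = _read_sheets(path)
    if "attributes" not in sheets:
        raise EmxFormatError(f"workbook {path} has no 'attributes' sheet")

    meta = _sheet_records(sheets["attributes"])
    known = set(ATTRIBUTE_COLUMNS)
    if meta:
        extra = set(meta[0]) - known
        if extra:
            log.warning("ignoring unknown attributes-sheet columns: %s", sorted(extra))

    schema = Schema(name=name or path.stem)
    for i, rec in enumerate(meta, start=2):
        attr_name = rec.get("name")
        ent_name = rec.get("entity")
        if not attr_name or not ent_name:
            raise EmxValidationError(
                f"attributes sheet row {i}: 'name' and 'entity' are required"
            )
        dtype = rec.get("dataType") or "string"
        if dtype not in DATA_TYPES:
            raise EmxValidationError(
                f"attributes sheet row {i}: unknown dataType {dtype!r} "
                f"for attribute {attr_name!r}"
            )
        ent = schema.entities.setdefault(ent_name, Entity(name=ent_name))
        if attr_name in ent.attribute_names:
            raise EmxValidationError(
                f"attributes sheet row {i}: duplicate attribute "
                f"{attr_name!r} in entity {ent_name!r}"
            )
        ent.attributes.append(
            Attribute(
                name=attr_name,
                entity=ent_name,
                data_type=dtype,
                label=rec.get("label") or "",
                description=rec.get("description") or "",
                ref_entity=rec.get("refEntity"),
            )
        )

    # data sheets
    for sheet_name, rows in sheets.items():
        if sheet_name == "attributes":
            continue
        recs = _sheet_records(rows)
        ent = schema.entities.get(sheet_name)
        if ent is None:
            # Tolerate bare code/label lookup sheets that carry no metadata.
            if recs and set(recs[0]) <= {"code", "label"}:
                ent = Entity(
                    name=sheet_name,
                    attributes=[
                        Attribute(name="code", entity=sheet_name),
                        Attribute(name="label", entity=sheet_name),
                    ],
                )
                schema.entities[sheet_name] = ent
                log.warning(
                    "sheet %r has no metadata; treated as code/label lookup",
                    sheet_name,
                )
            else:
                raise EmxValidationError(
                    f"data sheet {sheet_name!r} has no attributes-sheet metadata"
                )
        ent.rows = recs

    _resolve_references(schema)
    return schema


def _resolve_references(schema: Schema) -> None:
    for attr in schema.iter_attributes():
        if not attr.is_categorical:
            continue
        if not attr.ref_entity:
            raise EmxValidationError(
                f"{attr.entity}.{attr.name}: {attr.data_type} attribute "
                "lacks a refEntity"
            )
        ref = schema.entities.get(attr.ref_entity)
        if ref is None:
            raise EmxValidationError(
                f"{attr.entity}.{attr.name}: refEntity {attr.ref_entity!r} "
                "does not resolve to an entity"
            )
        cats = []
        for row in ref.rows:
            code = row.get("code")
            if code is None:
                continue
            cats.append(Category(code=code, label=row.get("label") or code))
        attr.categories = cats


# ---------------------------------------------------------------------------
# writing


def _schema_sheets(schema: Schema) -> dict[str, list[list[str]]]:
    sheets: dict[str, list[list[str]]] = {}
    meta_rows: list[list[str]] = [list(ATTRIBUTE_COLUMNS)]
    for ent in schema.entities.values():
        for a in ent.attributes:
            meta_rows.append(
                [a.name, a.entity, a.data_type, a.label, a.description, a.ref_entity or ""]
            )
    sheets["attributes"] = meta_rows
    for ent in schema.entities.values():
        cols = ent.attribute_names
        rows = [cols[:]]
        for rec in ent.rows:
            rows.append(["" if rec.get(c) is None else rec[c] for c in cols])
        sheets[ent.name] = rows
    return sheets


def write_emx(schema: Schema, path: str | Path) -> None:
    """Write *schema* to ``path`` as xlsx (if suffix is ``.xlsx``) or a CSV directory.

    ``read_emx(write_emx(s))`` is the identity on valid schemas, cell-exact.
    """
    path = Path(path)
    sheets = _schema_sheets(schema)
    if path.suffix.lower() == ".xlsx":
        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for sheet_name, rows in sheets.items():
            ws = wb.create_sheet(title=sheet_name)
            for r in rows:
                ws.append(r)
        wb.save(path)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for sheet_name, rows in sheets.items():
            with open(path / f"{sheet_name}.csv", "w", newline="", encoding="utf-8") as fh:
                csv.writer(fh, quoting=csv.QUOTE_MINIMAL).writerows(rows)


# ---------------------------------------------------------------------------
# validation


def validate_schema(schema: Schema) -> list[Violation]:
    """Check every model invariant; violations are returned, never raised."""
    out: list[Violation] = []
    for ent in schema.entities.values():
        seen: set[str] = set()
        for a in ent.attributes:
            if a.name in seen:
                out.append(Violation(ent.name, a.name, None, "duplicate attribute name"))
            seen.add(a.name)
            if a.data_type not in DATA_TYPES:
                out.append(
                    Violation(ent.name, a.name, None, f"unknown dataType {a.data_type!r}")
                )
            if a.is_categorical:
                if not a.categories:
                    out.append(
                        Violation(ent.name, a.name, None, "categorical without categories")
                    )
                codes = a.category_codes
                if len(codes) != len(set(codes)):
                    out.append(
                        Violation(ent.name, a.name, None, "duplicate category codes")
                    )
                if a.ref_entity and a.ref_entity not in schema.entities:
                    out.append(
                        Violation(
                            ent.name, a.name, None, f"dangling refEntity {a.ref_entity!r}"
                        )
                    )
        names = set(seen)
        for i, row in enumerate(ent.rows):
            for key, val in row.items():
                if key not in names:
                    out.append(
                        Violation(ent.name, key, i, "row key is not a declared attribute")
                    )
                    continue
                if val is None:
                    continue
                a = ent.attribute(key)
                if a.is_categorical and val not in a.category_codes:
                    out.append(
                        Violation(
                            ent.name,
                            key,
                            i,
                            f"value {val!r} is not one of the category codes",
                        )
                    )
    return out
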