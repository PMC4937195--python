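"""Execute a mapping project's algorithms over source rows.

Each non-missing cell's script is evaluated row by row against the source
dataset; results land in a derived entity shaped like the target schema.
Evaluation errors (unknown attribute, non-numeric operand) are counted as
per-attribute failures and logged per row, with the cell value set to
missing. A ``null`` produced from missing input data is *not* a failure —
only runtime errors are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import dsl
from .emx import Attribute, Entity, Schema, write_emx
from .generate import MappingProject
from .units import UnitEngine

log = logging.getLogger(__name__)


@dataclass
class RowError:
    row_index: int
    attribute: str
    message: str


@dataclass
class IntegrationResult:
    """The derived target-schema dataset for one source, plus failure accounting."""

    derived: Entity
    failures: dict[str, int] = field(default_factory=dict)
    errors: list[RowError] = field(default_factory=list)
    source_name: str = ""

    @property
    def n_rows(self) -> int:
        return len(self.derived.rows)

    @property
    def total_failures(self) -> int:
        return sum(self.failures.values())


def _data_entity(schema: Schema, needed: set[str]) -> Entity:
    """The source entity holding the referenced attributes (falls back to the
    largest data-bearing entity)."""
    lookups = schema.lookup_entity_names
    proper = [e for e in schema.entities.values() if e.name not in lookups]
    for ent in proper:
        if needed and needed <= set(ent.attribute_names):
            return ent
    candidates = [e for e in proper if e.rows] or [e for e in schema.entities.values() if e.rows]
    if not candidates:
        raise ValueError(f"source schema {schema.name!r} has no data rows")
    return max(candidates, key=lambda e: (len(e.rows), len(e.attributes)))


def apply_project(
    project: MappingProject,
    source_data: Schema,
    unit_engine: Optional[UnitEngine] = None,
) -> IntegrationResult:
    """Run every executable cell of *project* for one source schema.

    Returns the derived entity (one output row per source row) with
    per-attribute failure counts and a per-row error log.
    """
    if unit_engine is None:
        unit_engine = UnitEngine()
    cells = [
        c
        for c in project.cells_for_source(source_data.name)
        if c.state != "missing" and c.script is not None
    ]
    if not cells:
        log.warning("project has no executable algorithms for source %r", source_data.name)

    refs: set[str] = set()
    for c in cells:
        refs |= set(c.script.referenced_attributes)
    entity = _data_entity(source_data, refs) if cells else _data_entity(source_data, set())

    target_attrs: list[Attribute] = [
        a
        for a in project.target_schema.iter_attributes()
        if any(c.target_name == a.name for c in cells)
    ]
    derived = Entity(
        name="derived",
        attributes=[
            Attribute(
                name=a.name,
                entity="derived",
                data_type="string" if a.is_categorical else a.data_type,
                label=a.label,
                description=a.description,
            )
            for a in target_attrs
        ],
    )
    failures = {a.name: 0 for a in target_attrs}
    errors: list[RowError] = []
    scripts = {c.target_name: c.script for c in cells}

    for i, row in enumerate(entity.rows):
        out: dict[str, Optional[str]] = {}
        for a in target_attrs:
            script = scripts[a.name]
            try:
                value = dsl.evaluate(script, row, entity, unit_engine)
                out[a.name] = dsl.render_value(value)
            except dsl.DslEvalError as exc:
                failures[a.name] += 1
                errors.append(RowError(i, a.name, str(exc)))
                out[a.name] = None
        derived.rows.append(out)

    return IntegrationResult(
        derived=derived, failures=failures, errors=errors, source_name=source_data.name
    )


def preview(
    algorithm,
    source_entity: Entity,
    n: int = 10,
    unit_engine: Optional[UnitEngine] = None,
) -> tuple[list[Optional[str]], int]:
    """First-*n* converted values plus the failure count over those rows.

    Values are identical to what :func:`apply_project` would produce for
    the same rows.
    """
    if unit_engine is None:
        unit_engine = UnitEngine()
    script = algorithm.script if hasattr(algorithm, "script") else algorithm
    values: list[Optional[str]] = []
    n_failures = 0
    for row in source_entity.rows[:n]:
        try:
            values.append(
                dsl.render_value(dsl.evaluate(script, row, source_entity, unit_engine))
            )
        except dsl.DslEvalError:
            n_failures += 1
            values.append(None)
    return values, n_failures


def export_result(result: IntegrationResult, path: str | Path, format: str = "csv") -> None:
    """Write the derived dataset as an EMX workbook (xlsx) or CSV set.

    Missing values are exported as empty cells; re-reading the export
    reproduces the derived entity cell-exactly.
    """
    if format not in ("csv", "xlsx"):
        raise ValueError(f"unknown export format {format!r}")
    path = Path(path)
    schema = Schema(name="derived", entities={"derived": result.derived})
    if format == "xlsx" and path.suffix.lower() != ".xlsx":
        path = path.with_suffix(".xlsx")
    write_emx(schema, path)
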