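"""Assemble complete transformation algorithms per target attribute.

For every target attribute the generator: (I) looks for an applicable
algorithm template (e.g. BMI), (II) retrieves ranked source candidates via
ontology-expanded search, (III) aligns units toward the target's (or the
template slot's) expected unit, and (IV) fills template slots with the
best lexically matching candidates. Where no template applies it falls
back, in order, to a categorical ``map()`` algorithm, a unit-conversion
algorithm, or a bare rename.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import dsl
from .categories import (
    MatchRule,
    default_rules,
    generate_map_snippet,
    match_categories,
    ngram_similarity,
)
from .emx import Attribute, Schema
from .ontology import OntologyStore
from .search import MatchCandidate, SearchIndex, classify_confidence, index_source, shortlist
from .text import tokenize
from .units import IncompatibleUnitsError, UnitEngine, UnitError

log = logging.getLogger(__name__)

#: Minimum n-gram similarity for a candidate to fill a template slot.
SLOT_TRIGGER_THRESHOLD = 0.5


class TemplateFillError(Exception):
    """A template slot could not be filled from the candidate list."""


@dataclass(frozen=True)
class TemplateSlot:
    name: str
    unit: Optional[str]  # expected unit text, e.g. "kg" or "m"
    synonyms: tuple[str, ...]


@dataclass(frozen=True)
class AlgorithmTemplate:
    """A reusable algorithm skeleton with named slots."""

    name: str
    triggers: tuple[str, ...]
    slots: tuple[TemplateSlot, ...]
    body: str
    conditional: bool = False

    def __post_init__(self):
        names = {s.name for s in self.slots}
        import string

        placeholders = {
            f for _, f, _, _ in string.Formatter().parse(self.body) if f
        }
        if not placeholders <= names:
            raise ValueError(
                f"template {self.name!r}: placeholders {placeholders - names} "
                "have no slot"
            )


def load_templates(path: str | Path) -> list[AlgorithmTemplate]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    out = []
    for name, rec in (doc.get("templates") or {}).items():
        slots = tuple(
            TemplateSlot(
                name=slot_name,
                unit=spec.get("unit"),
                synonyms=tuple(spec.get("synonyms", ())) or (slot_name,),
            )
            for slot_name, spec in rec.get("slots", {}).items()
        )
        out.append(
            AlgorithmTemplate(
                name=name,
                triggers=tuple(rec.get("triggers", ())),
                slots=slots,
                body=rec["body"],
                conditional=bool(rec.get("conditional", False)),
            )
        )
    return out


def default_templates() -> list[AlgorithmTemplate]:
    from .units import _data_path

    return load_templates(_data_path("templates.yml"))


@dataclass
class GeneratedAlgorithm:
    """A DSL script plus the provenance of how it was generated."""

    target_attribute: Attribute
    script: dsl.DslScript
    provenance: str  # "template" | "category_map" | "unit_conversion" | "rename"
    used_candidates: list[MatchCandidate] = field(default_factory=list)
    confidence: str = "low"  # "high" | "low"
    template_name: Optional[str] = None

    @property
    def text(self) -> str:
        return self.script.canonical


# ---------------------------------------------------------------------------
# templates


def _slot_score(slot: TemplateSlot, candidate: MatchCandidate) -> float:
    """Best n-gram similarity between the slot's names and the candidate's
    label (whole label and individual words)."""
    label = candidate.source_attribute.label or candidate.source_attribute.name
    probes = [label] + tokenize(label)
    return max(
        (ngram_similarity(p, syn) for p in probes for syn in slot.synonyms),
        default=0.0,
    )


def _trigger_matches(template: AlgorithmTemplate, target: Attribute) -> bool:
    target_tokens = set(tokenize(target.label) or tokenize(target.name))
    for trig in template.triggers:
        trig_tokens = set(tokenize(trig))
        if trig_tokens and trig_tokens <= target_tokens:
            return True
    return False


def find_template(
    target: Attribute,
    catalogue: list[AlgorithmTemplate],
    candidates: list[MatchCandidate],
) -> Optional[AlgorithmTemplate]:
    """Propose a template when the target label matches a trigger or at
    least one candidate lexically matches one of its slots."""
    for tpl in catalogue:
        if _trigger_matches(tpl, target):
            return tpl
        for slot in tpl.slots:
            for cand in candidates:
                if _slot_score(slot, cand) >= SLOT_TRIGGER_THRESHOLD:
                    return tpl
    return None


def fill_template(
    template: AlgorithmTemplate,
    candidates: list[MatchCandidate],
    unit_engine: UnitEngine,
) -> GeneratedAlgorithm:
    """Fill every slot with its best-matching candidate and insert unit
    conversions toward each slot's expected unit.

    Slots must receive distinct candidates; assignment is greedy by
    similarity. An unfillable slot raises :class:`TemplateFillError` and the
    caller falls back to the simpler generators.
    """
    scored = sorted(
        (
            (_slot_score(slot, cand), slot.name, cand)
            for slot in template.slots
            for cand in candidates
        ),
        key=lambda t: (-t[0], t[1], t[2].source_attribute.name),
    )
    assignment: dict[str, MatchCandidate] = {}
    used: set[str] = set()
    for score, slot_name, cand in scored:
        if score < SLOT_TRIGGER_THRESHOLD:
            break
        if slot_name in assignment or cand.source_attribute.name in used:
            continue
        assignment[slot_name] = cand
        used.add(cand.source_attribute.name)
    missing = [s.name for s in template.slots if s.name not in assignment]
    if missing:
        raise TemplateFillError(
            f"template {template.name!r}: no candidate fills slot(s) {missing}"
        )

    exprs: dict[str, str] = {}
    for slot in template.slots:
        cand = assignment[slot.name]
        attr = cand.source_attribute
        expr = f"$('{attr.name}')"
        if slot.unit:
            expected = unit_engine.parse_composite(slot.unit)
            detected = unit_engine.detect_unit(attr)
            if detected.unit is not None:
                try:
                    plan = unit_engine.align_units(expected, detected.unit)
                except IncompatibleUnitsError as exc:
                    raise TemplateFillError(
                        f"slot {slot.name!r}: candidate {attr.name!r} has an "
                        f"incompatible unit ({detected.unit})"
                    ) from exc
                for step in plan.steps:
                    expr += unit_engine.conversion_calls(
                        step.from_symbol, step.to_symbol, style="formula"
                    )
        exprs[slot.name] = expr

    text = template.body.format(**exprs)
    script = dsl.parse(text, allow_conditional=template.conditional)
    return GeneratedAlgorithm(
        target_attribute=None,  # filled by the caller
        script=script,
        provenance="template",
        used_candidates=[assignment[s.name] for s in template.slots],
        template_name=template.name,
    )


# ---------------------------------------------------------------------------
# per-target generation


def generate_algorithm(
    target: Attribute,
    source_schema: Schema,
    index: Optional[SearchIndex] = None,
    store: Optional[OntologyStore] = None,
    catalogue: Optional[list[AlgorithmTemplate]] = None,
    rules: Optional[list[MatchRule]] = None,
    unit_engine: Optional[UnitEngine] = None,
    k: int = 20,
    snippet_style: str = "formula",
) -> Optional[GeneratedAlgorithm]:
    """Generate the transformation algorithm for one target attribute.

    Pipeline: shortlist candidates; try a template; otherwise use the top
    candidate with a category map (categorical target), a unit conversion
    (numeric target with differing units) or a bare rename. Returns None
    when no candidate is found at all.
    """
    if index is None:
        index = index_source(source_schema)
    if unit_engine is None:
        unit_engine = UnitEngine()
    if catalogue is None:
        catalogue = default_templates()
    if rules is None:
        rules = default_rules()

    candidates = shortlist(target, index, store, k)
    if not candidates:
        return None
    confidence = classify_confidence(candidates, target)
    confidence = "high" if confidence == "high" else "low"

    # templates are *proposed* to users on a mere slot match (find_template),
    # but the automatic pipeline only commits to one when the target itself
    # triggers it — otherwise every plain height target would become a BMI
    tpl = next((t for t in catalogue if _trigger_matches(t, target)), None)
    if tpl is not None:
        try:
            algo = fill_template(tpl, candidates, unit_engine)
            algo.target_attribute = target
            algo.confidence = confidence
            return algo
        except TemplateFillError as exc:
            log.debug("template fallback for %s: %s", target.name, exc)

    best = candidates[0]
    src = best.source_attribute

    if target.is_categorical and src.is_categorical and src.categories:
        cmap = match_categories(target.categories, src.categories, rules)
        if cmap.pairs:
            script = dsl.parse(generate_map_snippet(cmap, src.name))
            return GeneratedAlgorithm(
                target_attribute=target,
                script=script,
                provenance="category_map",
                used_candidates=[best],
                confidence=confidence,
            )

    # numeric (or fallback) path: unit alignment, else rename
    provenance = "rename"
    calls = ""
    try:
        t_det = unit_engine.detect_unit(target)
        s_det = unit_engine.detect_unit(src)
        if t_det.unit is not None and s_det.unit is not None:
            plan = unit_engine.align_units(t_det.unit, s_det.unit)
            if not plan.is_identity:
                if (
                    snippet_style == "chain"
                    and len(plan.steps) == 1
                    and s_det.unit.is_atomic
                ):
                    step = plan.steps[0]
                    calls = unit_engine.conversion_calls(
                        step.from_symbol, step.to_symbol, style="chain"
                    )
                else:
                    calls = _factor_calls(plan.value_factor)
                provenance = "unit_conversion"
    except UnitError as exc:
        log.warning("unit alignment failed for %s: %s", target.name, exc)

    script = dsl.parse(f"$('{src.name}'){calls}.value()")
    return GeneratedAlgorithm(
        target_attribute=target,
        script=script,
        provenance=provenance,
        used_candidates=[best],
        confidence=confidence,
    )


def _factor_calls(factor) -> str:
    if factor == 1:
        return ""
    if factor.denominator == 1:
        return f".times({factor.numerator})"
    if factor.numerator == 1:
        return f".div({factor.denominator})"
    return f".times({float(factor):.10g})"


# ---------------------------------------------------------------------------
# mapping projects


CELL_STATES = ("generated-high", "generated-low", "curated", "missing")


@dataclass
class MappingCell:
    """One (target attribute x source) cell of the project overview."""

    target_name: str
    source_name: str
    algorithm: Optional[GeneratedAlgorithm] = None
    state: str = "missing"
    script_text: Optional[str] = None  # curated override text

    @property
    def script(self) -> Optional[dsl.DslScript]:
        if self.script_text is not None:
            return dsl.parse(self.script_text, allow_conditional=True)
        if self.algorithm is not None:
            return self.algorithm.script
        return None


@dataclass
class MappingProject:
    """All cells of a harmonization project: targets x sources."""

    target_schema: Schema
    source_names: list[str] = field(default_factory=list)
    cells: dict[tuple[str, str], MappingCell] = field(default_factory=dict)

    def cell(self, target_name: str, source_name: str) -> MappingCell:
        return self.cells[(target_name, source_name)]

    def curate(self, target_name: str, source_name: str, script_text: str) -> None:
        """Replace a cell's algorithm with a hand-written script."""
        dsl.parse(script_text, allow_conditional=True)  # validate early
        cell = self.cells[(target_name, source_name)]
        cell.script_text = script_text
        cell.state = "curated"

    def cells_for_source(self, source_name: str) -> list[MappingCell]:
        return [c for c in self.cells.values() if c.source_name == source_name]

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "target": self.target_schema.name,
            "sources": self.source_names,
            "cells": [
                {
                    "target": c.target_name,
                    "source": c.source_name,
                    "state": c.state,
                    "script": (
                        c.script_text
                        if c.script_text is not None
                        else (c.algorithm.text if c.algorithm else None)
                    ),
                    "provenance": c.algorithm.provenance if c.algorithm else None,
                }
                for c in self.cells.values()
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str, target_schema: Schema) -> "MappingProject":
        doc = json.loads(text)
        proj = cls(target_schema=target_schema, source_names=list(doc.get("sources", [])))
        for rec in doc.get("cells", []):
            cell = MappingCell(
                target_name=rec["target"],
                source_name=rec["source"],
                state=rec.get("state", "missing"),
                script_text=rec.get("script"),
            )
            proj.cells[(cell.target_name, cell.source_name)] = cell
        return proj


def generate_project(
    target_schema: Schema,
    sources: list[Schema],
    store: Optional[OntologyStore] = None,
    catalogue: Optional[list[AlgorithmTemplate]] = None,
    rules: Optional[list[MatchRule]] = None,
    unit_engine: Optional[UnitEngine] = None,
    k: int = 20,
    project: Optional[MappingProject] = None,
) -> MappingProject:
    """Generate (or re-generate) one cell per target attribute per source.

    Curated cells are never overwritten. Cell states are colour-codeable as
    generated-high / generated-low / curated / missing.
    """
    if unit_engine is None:
        unit_engine = UnitEngine()
    if project is None:
        project = MappingProject(target_schema=target_schema)
    project.source_names = [s.name for s in sources]
    for source in sources:
        index = index_source(source)
        for target in target_schema.iter_data_attributes():
            key = (target.name, source.name)
            existing = project.cells.get(key)
            if existing is not None and existing.state == "curated":
                continue
            algo = generate_algorithm(
                target,
                source,
                index=index,
                store=store,
                catalogue=catalogue,
                rules=rules,
                unit_engine=unit_engine,
                k=k,
            )
            if algo is None:
                project.cells[key] = MappingCell(
                    target_name=target.name, source_name=source.name, state="missing"
                )
            else:
                project.cells[key] = MappingCell(
                    target_name=target.name,
                    source_name=source.name,
                    algorithm=algo,
                    state=f"generated-{algo.confidence}",
                )
    return project
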