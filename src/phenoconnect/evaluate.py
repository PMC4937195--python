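"""Score generated matches and algorithms against a gold standard.

Search quality per target: ``perfect`` when a human-matched source
attribute is ranked first, ``good`` when every human-matched attribute
appears in the top 20 suggestions, otherwise ``bad``. Algorithm quality:
``perfect`` when the generated script is textually identical or
functionally equivalent to the reference (same values on every data row),
``good`` when it is almost right (at least half of a categorical map's
reference pairs present with none contradicted, or the right source
attributes chosen but the conversion wrong), otherwise ``bad``. The report
cross-tabulates the two as percentages; the "useful" total sums the cells
where the human only needs minor input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional

import pandas as pd

from . import dsl
from .emx import Entity, Schema
from .generate import GeneratedAlgorithm, MappingProject
from .ontology import OntologyStore
from .search import MatchCandidate, index_source, shortlist
from .synth import GoldStandard
from .units import UnitEngine

SEARCH_CLASSES = ("perfect", "good", "bad")
ALGO_CLASSES = ("perfect", "good", "bad")

#: (search, algorithm) cells counted as useful: both at least good, plus the
#: off-diagonal (bad search, perfect algorithm) and (perfect search, bad
#: algorithm) corners.
USEFUL_CELLS = frozenset(
    {
        ("perfect", "perfect"),
        ("perfect", "good"),
        ("good", "perfect"),
        ("good", "good"),
        ("bad", "perfect"),
        ("perfect", "bad"),
    }
)


def classify_search(candidates: list[MatchCandidate], gold_attributes: frozenset[str]) -> str:
    """perfect / good / bad for one shortlist against the gold attribute set."""
    if not gold_attributes:
        raise ValueError("gold attribute set is empty")
    names_in_order = [c.source_attribute.name for c in candidates]
    if names_in_order and names_in_order[0] in gold_attributes:
        return "perfect"
    top20 = set(names_in_order[:20])
    if gold_attributes <= top20:
        return "good"
    return "bad"


def functionally_equivalent(
    a: dsl.DslScript,
    b: dsl.DslScript,
    data: Entity,
    unit_engine: Optional[UnitEngine] = None,
    rel_tol: float = 1e-9,
) -> bool:
    """True iff both scripts yield the same value on every row of *data*.

    Decimal values compare within ``rel_tol`` (absolute 1e-12 near zero);
    strings and nulls compare exactly. A row where exactly one script
    raises an evaluation error breaks equivalence.
    """
    if unit_engine is None:
        unit_engine = UnitEngine()
    for row in data.rows:
        try:
            va = dsl.evaluate(a, row, data, unit_engine)
        except dsl.DslEvalError:
            va = None
        try:
            vb = dsl.evaluate(b, row, data, unit_engine)
        except dsl.DslEvalError:
            vb = None
        if (va is None) != (vb is None):
            return False
        if va is None:
            continue
        x, y = va.value, vb.value
        if (x is None) != (y is None):
            return False
        if x is None:
            continue
        if isinstance(x, Decimal) and isinstance(y, Decimal):
            if not math.isclose(float(x), float(y), rel_tol=rel_tol, abs_tol=1e-12):
                return False
        elif x != y:
            return False
    return True


def _map_pairs(script: dsl.DslScript) -> Optional[dict[str, str]]:
    """The pairs of a single trailing map() call, or None if not a map script."""
    node = script.ast
    if isinstance(node, dsl.Call) and node.method == "value":
        node = node.receiver
    if (
        isinstance(node, dsl.Call)
        and node.method == "map"
        and node.args
        and isinstance(node.args[0], dsl.MapLiteral)
    ):
        return dict(node.args[0].pairs)
    return None


def classify_algorithm(
    generated: Optional[GeneratedAlgorithm],
    reference_script: str,
    data: Entity,
    unit_engine: Optional[UnitEngine] = None,
) -> str:
    """perfect / good / bad for one generated algorithm against its reference."""
    if generated is None:
        return "bad"
    gen = generated.script if isinstance(generated, GeneratedAlgorithm) else generated
    ref = dsl.parse(reference_script, allow_conditional=True)
    if gen.canonical == ref.canonical:
        return "perfect"
    if functionally_equivalent(gen, ref, data, unit_engine):
        return "perfect"

    gen_pairs, ref_pairs = _map_pairs(gen), _map_pairs(ref)
    if gen_pairs is not None and ref_pairs is not None:
        if gen.referenced_attributes == ref.referenced_attributes:
            agreeing = sum(
                1 for k, v in ref_pairs.items() if gen_pairs.get(k) == v
            )
            contradicted = any(
                k in gen_pairs and gen_pairs[k] != v for k, v in ref_pairs.items()
            )
            if not contradicted and agreeing * 2 >= len(ref_pairs):
                return "good"
        return "bad"
    # numeric: right attributes, wrong/missing conversion
    if gen.referenced_attributes == ref.referenced_attributes:
        return "good"
    return "bad"


@dataclass
class EvaluationReport:
    """Cross-tab of search x algorithm quality over all evaluated cells."""

    per_cell: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.per_cell)

    def percentage_table(self) -> pd.DataFrame:
        """Rows: search class; columns: algorithm class; values: % of cells."""
        table = pd.DataFrame(
            0.0, index=list(SEARCH_CLASSES), columns=list(ALGO_CLASSES)
        )
        if not self.per_cell:
            return table
        for s_cls, a_cls in self.per_cell.values():
            table.loc[s_cls, a_cls] += 1
        return table * 100.0 / self.n_cells

    @property
    def useful_percentage(self) -> float:
        if not self.per_cell:
            return 0.0
        n = sum(1 for cell in self.per_cell.values() if cell in USEFUL_CELLS)
        return 100.0 * n / self.n_cells

    def summary(self) -> str:
        table = self.percentage_table().round(1)
        return (
            f"{table.to_string()}\n"
            f"useful: {self.useful_percentage:.1f}% of {self.n_cells} cells"
        )


def evaluate_project(
    project: MappingProject,
    gold: GoldStandard,
    sources: list[Schema],
    store: Optional[OntologyStore] = None,
    unit_engine: Optional[UnitEngine] = None,
    k: int = 20,
) -> EvaluationReport:
    """Classify every gold-covered (target x source) cell of a project.

    Search classification re-runs the shortlist per target; algorithm
    classification executes generated and reference scripts on the source
    data.
    """
    if unit_engine is None:
        unit_engine = UnitEngine()
    report = EvaluationReport()
    source_by_name = {s.name: s for s in sources}
    target_attrs = {a.name: a for a in project.target_schema.iter_attributes()}
    for (target_name, source_name), entry in gold.entries.items():
        source = source_by_name.get(source_name)
        if source is None or target_name not in target_attrs:
            continue
        index = index_source(source)
        candidates = shortlist(target_attrs[target_name], index, store, k)
        s_cls = classify_search(candidates, entry.source_attributes)

        cell = project.cells.get((target_name, source_name))
        data = _main_entity(source)
        algo = cell.algorithm if cell is not None else None
        if algo is None and cell is not None and cell.script_text:
            algo = cell.script  # curated cells are judged on their script
        a_cls = classify_algorithm(algo, entry.reference_script, data, unit_engine)
        report.per_cell[(target_name, source_name)] = (s_cls, a_cls)
    return report


def _main_entity(source: Schema) -> Entity:
    data_entities = [e for e in source.entities.values() if e.rows]
    return max(data_entities, key=lambda e: len(e.attributes))
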