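"""Categorical value matching: produce source-code -> target-code maps.

Three strategies are combined, strongest first:

1. **Hard rules** — a small, user-overridable table of label patterns
   (e.g. source "Never" maps to target "No") that would defeat purely
   lexical matching.
2. **Frequency quantification** — categories on consumption/activity scales
   ("2-4 times a week") are parsed into an amount and a time unit,
   normalised to a rate per day, and each source category is matched to the
   target category with the nearest rate. Many-to-one matches are allowed:
   divergent scales rarely align one-to-one.
3. **Lexical n-gram matching** — for everything else, each source label is
   matched to the target label with the best Dice-coefficient similarity
   over padded character bigrams.

The resulting map renders as a ``map({...})`` DSL snippet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .emx import Category

#: Days per time unit for rate normalisation (calendar averages).
DAYS_PER_UNIT = {"day": 1.0, "week": 7.0, "month": 30.44, "year": 365.25}


class CategoryMatchError(Exception):
    pass


class RuleConfigurationError(CategoryMatchError):
    """Two rules of equal priority claim the same source category."""


@dataclass(frozen=True)
class FrequencyAmount:
    """A quantified frequency category: amount per time unit."""

    amount: float
    time_unit: str

    @property
    def rate_per_day(self) -> float:
        return self.amount / DAYS_PER_UNIT[self.time_unit]


@dataclass(frozen=True)
class MappedPair:
    source_code: str
    target_code: str
    provenance: str  # "lexical" | "frequency" | "rule"
    similarity: Optional[float] = None  # lexical only


@dataclass
class CategoryMap:
    """Source-code -> target-code assignment with per-pair provenance."""

    pairs: list[MappedPair] = field(default_factory=list)
    #: source codes a rule explicitly sends to missing
    null_mapped: list[str] = field(default_factory=list)
    #: source codes no strategy could place
    unmapped: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, str]:
        return {p.source_code: p.target_code for p in self.pairs}

    def provenance_of(self, source_code: str) -> Optional[str]:
        for p in self.pairs:
            if p.source_code == source_code:
                return p.provenance
        return None


@dataclass(frozen=True)
class MatchRule:
    """A pre-defined category-matching rule over labels (regex, full match)."""

    source_pattern: str
    target_pattern: Optional[str]  # None drops the source code to missing
    priority: int = 0

    def matches_source(self, label: str) -> bool:
        return re.fullmatch(self.source_pattern, label.strip(), re.I) is not None

    def matches_target(self, label: str) -> bool:
        return (
            self.target_pattern is not None
            and re.fullmatch(self.target_pattern, label.strip(), re.I) is not None
        )


def load_rules(path: str | Path) -> list[MatchRule]:
    """Load a YAML rule table (``rules: [{source, target, priority}]``)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    out = []
    for rec in doc.get("rules", []):
        out.append(
            MatchRule(
                source_pattern=rec["source"],
                target_pattern=rec.get("target"),
                priority=int(rec.get("priority", 0)),
            )
        )
    return out


def default_rules() -> list[MatchRule]:
    from .units import _data_path

    return load_rules(_data_path("category_rules.yml"))


# ---------------------------------------------------------------------------
# lexical n-gram matching


_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)


def _normalize(s: str) -> str:
    return " ".join(_PUNCT_RE.sub(" ", s.casefold()).split())


def _bigrams(s: str) -> set[str]:
    padded = f" {s} "
    return {padded[i : i + 2] for i in range(len(padded) - 1)}


def ngram_similarity(a: str, b: str) -> float:
    """Dice coefficient over padded character bigrams of normalised strings.

    Symmetric, in [0, 1]; 1 for strings equal after lowercasing and
    punctuation stripping; 0 when either side is empty and the other not.
    """
    na, nb = _normalize(a), _normalize(b)
    if na == nb:
        return 1.0
    if not na or not nb:
        return 0.0
    ga, gb = _bigrams(na), _bigrams(nb)
    return 2.0 * len(ga & gb) / (len(ga) + len(gb))


def match_lexical(
    target_cats: list[Category], source_cats: list[Category]
) -> CategoryMap:
    """Assign each source category to its argmax-similarity target category.

    Many-to-one is allowed; ties break toward the lowest target code so the
    result is deterministic.
    """
    if not target_cats or not source_cats:
        raise CategoryMatchError("both category lists must be non-empty")
    out = CategoryMap()
    for src in source_cats:
        best: Optional[Category] = None
        best_sim = -1.0
        for tgt in target_cats:
            sim = ngram_similarity(src.label, tgt.label)
            if sim > best_sim or (sim == best_sim and tgt.code < best.code):
                best, best_sim = tgt, sim
        out.pairs.append(
            MappedPair(
                source_code=src.code,
                target_code=best.code,
                provenance="lexical",
                similarity=best_sim,
            )
        )
    return out


# ---------------------------------------------------------------------------
# frequency matching


_RANGE_RE = re.compile(
    r"(\d+(?:\.\d+)?)\s*[-–—]\s*(\d+(?:\.\d+)?)\s*(?:times?|x)?\s*(?:a|per|every)?\s*"
    r"(day|week|month|year)s?",
    re.I,
)
_SIMPLE_RE = re.compile(
    r"(\d+(?:\.\d+)?)\s*(?:times?|x)?\s*(?:a|per|every)?\s*(day|week|month|year)s?",
    re.I,
)
_WORD_RE = re.compile(
    r"\b(once|twice)\s+(?:a|per|every)\s+(day|week|month|year)\b", re.I
)
_BARE_RE = re.compile(r"\b(daily|weekly|monthly|yearly|annually)\b", re.I)
_EVERY_RE = re.compile(r"\bevery\s+(day|week|month|year)\b", re.I)

_BARE_UNIT = {
    "daily": "day",
    "weekly": "week",
    "monthly": "month",
    "yearly": "year",
    "annually": "year",
}


def parse_frequency(label: str) -> Optional[FrequencyAmount]:
    """Extract (amount, time unit) from a frequency-scale category label.

    Recognises "N times a/per U", "N-M times a U" (amount is the range
    mean), "once/twice a U", "every U" and bare "daily/weekly/...";
    returns None for anything else.
    """
    m = _RANGE_RE.search(label)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return FrequencyAmount(amount=(lo + hi) / 2.0, time_unit=m.group(3).lower())
    m = _WORD_RE.search(label)
    if m:
        amount = 1.0 if m.group(1).lower() == "once" else 2.0
        return FrequencyAmount(amount=amount, time_unit=m.group(2).lower())
    m = _SIMPLE_RE.search(label)
    if m:
        return FrequencyAmount(amount=float(m.group(1)), time_unit=m.group(2).lower())
    m = _EVERY_RE.search(label)
    if m:
        return FrequencyAmount(amount=1.0, time_unit=m.group(1).lower())
    m = _BARE_RE.search(label)
    if m:
        return FrequencyAmount(amount=1.0, time_unit=_BARE_UNIT[m.group(1).lower()])
    return None


def match_frequency(
    target_cats: list[Category], source_cats: list[Category]
) -> tuple[CategoryMap, list[Category]]:
    """Match frequency-parseable source categories to the nearest-rate target.

    Returns the (possibly partial) map plus the source categories that did
    not parse as frequencies and need another strategy. Rate ties break
    toward the lower-rate target (conservative: under-report frequency).
    """
    targets = [(t, parse_frequency(t.label)) for t in target_cats]
    targets = [(t, f) for t, f in targets if f is not None]
    out = CategoryMap()
    leftover: list[Category] = []
    if not targets:
        return out, list(source_cats)
    for src in source_cats:
        f = parse_frequency(src.label)
        if f is None:
            leftover.append(src)
            continue
        best = min(
            targets,
            key=lambda tf: (abs(tf[1].rate_per_day - f.rate_per_day), tf[1].rate_per_day),
        )
        out.pairs.append(
            MappedPair(src.code, best[0].code, provenance="frequency")
        )
    return out, leftover


# ---------------------------------------------------------------------------
# rules


def apply_rules(
    target_cats: list[Category],
    source_cats: list[Category],
    rules: list[MatchRule],
) -> tuple[CategoryMap, list[Category]]:
    """Fix pairs dictated by rules before any other matcher runs.

    Returns the partial map and the source categories left for the other
    strategies. Equal-priority rules that disagree on one source category
    raise :class:`RuleConfigurationError`.
    """
    out = CategoryMap()
    leftover: list[Category] = []
    for src in source_cats:
        applicable = [r for r in rules if r.matches_source(src.label)]
        if not applicable:
            leftover.append(src)
            continue
        top = max(r.priority for r in applicable)
        winners = [r for r in applicable if r.priority == top]
        outcomes = {(r.target_pattern is None, r.target_pattern) for r in winners}
        if len(outcomes) > 1:
            raise RuleConfigurationError(
                f"conflicting equal-priority rules for source label {src.label!r}"
            )
        rule = winners[0]
        if rule.target_pattern is None:
            out.null_mapped.append(src.code)
            continue
        hit = next((t for t in target_cats if rule.matches_target(t.label)), None)
        if hit is None:
            leftover.append(src)  # rule fires but the target side has no partner
            continue
        out.pairs.append(MappedPair(src.code, hit.code, provenance="rule"))
    return out, leftover


# ---------------------------------------------------------------------------
# combined pipeline


def match_categories(
    target_cats: list[Category],
    source_cats: list[Category],
    rules: Optional[list[MatchRule]] = None,
) -> CategoryMap:
    """Full pipeline: rules, then frequency where both sides parse, then
    lexical fallback. Every pair carries exactly one provenance tag."""
    if rules is None:
        rules = default_rules()
    combined, remaining = apply_rules(target_cats, source_cats, rules)
    freq_map, remaining = match_frequency(target_cats, remaining)
    combined.pairs.extend(freq_map.pairs)
    if remaining:
        lex = match_lexical(target_cats, remaining)
        combined.pairs.extend(lex.pairs)
    return combined


def generate_map_snippet(category_map: CategoryMap, source_attr_name: str) -> str:
    """Render a map as a DSL script, pairs ordered by source code ascending.

    An empty map is a generation error — the caller falls back to emitting
    no algorithm at all.
    """
    if not category_map.pairs:
        raise CategoryMatchError("cannot generate a map() snippet from an empty map")
    ordered = sorted(category_map.pairs, key=lambda p: p.source_code)
    inner = ",".join(f"'{p.source_code}':'{p.target_code}'" for p in ordered)
    return f"$('{source_attr_name}').map({{{inner}}})"
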