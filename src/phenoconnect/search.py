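"""Lexical shortlisting of source attributes for each target attribute.

Every source attribute is indexed as a small document (label + description
tokens). A target attribute is turned into an ontology-expanded query
(:func:`phenoconnect.ontology.expand_query`) and scored against the index
with BM25 (k1=1.2, b=0.75). The result is a ranked shortlist with token
highlighting, plus a coverage-based confidence class for the top hit.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .emx import Attribute, Schema
from .ontology import ExpandedQuery, OntologyStore, annotate_attribute, expand_query
from .text import tokenize

BM25_K1 = 1.2
BM25_B = 0.75


@dataclass
class Highlight:
    """One query token found in a candidate's label or description."""

    token: str
    field: str  # "label" | "description"
    start: int
    end: int


@dataclass
class MatchCandidate:
    """A ranked source-attribute candidate for one target attribute."""

    source_attribute: Attribute
    score: float
    rank: int
    highlighted_tokens: list[Highlight] = field(default_factory=list)


@dataclass
class _Doc:
    attribute: Attribute
    tokens: list[str]
    counts: Counter
    label_tokens: frozenset[str]


class SearchIndex:
    """In-memory BM25 index over the attributes of a source schema."""

    def __init__(self) -> None:
        self.docs: list[_Doc] = []
        self.df: Counter = Counter()
        self._avgdl = 0.0

    def add(self, attr: Attribute) -> None:
        toks = tokenize(f"{attr.label} {attr.description}")
        if not toks:
            toks = tokenize(attr.name)
        self.docs.append(
            _Doc(
                attribute=attr,
                tokens=toks,
                counts=Counter(toks),
                label_tokens=frozenset(tokenize(attr.label) or tokenize(attr.name)),
            )
        )
        for t in set(toks):
            self.df[t] += 1
        self._avgdl = sum(len(d.tokens) for d in self.docs) / len(self.docs)

    def __len__(self) -> int:
        return len(self.docs)

    def _idf(self, token: str) -> float:
        n, df = len(self.docs), self.df.get(token, 0)
        return math.log(1.0 + (n - df + 0.5) / (df + 0.5))

    def score(self, query_tokens: list[str], doc: _Doc) -> float:
        s = 0.0
        dl = len(doc.tokens)
        for t in query_tokens:
            tf = doc.counts.get(t, 0)
            if not tf:
                continue
            s += (
                self._idf(t)
                * tf
                * (BM25_K1 + 1)
                / (tf + BM25_K1 * (1 - BM25_B + BM25_B * dl / self._avgdl))
            )
        return s


def index_source(source_schema: Schema) -> SearchIndex:
    """Index every attribute of every entity of a validated source schema."""
    index = SearchIndex()
    for attr in source_schema.iter_attributes():
        index.add(attr)
    return index


def _ranked(
    index: SearchIndex, query: ExpandedQuery, k: int, target_label_tokens: frozenset[str]
) -> list[MatchCandidate]:
    qtokens = query.tokens()
    if not qtokens or not len(index):
        return []
    scored = []
    for doc in index.docs:
        s = index.score(qtokens, doc)
        if s <= 0:
            continue
        exact = doc.label_tokens == target_label_tokens and bool(target_label_tokens)
        # exact label-token matches always outrank everything else;
        # ties broken by attribute name for deterministic output
        scored.append((not exact, -s, doc.attribute.name, s, doc))
    scored.sort(key=lambda t: t[:3])
    out = []
    for rank, (_, _, _, s, doc) in enumerate(scored[:k], start=1):
        cand = MatchCandidate(source_attribute=doc.attribute, score=s, rank=rank)
        highlight(cand, query)
        out.append(cand)
    return out


def shortlist(
    target: Attribute,
    index: SearchIndex,
    store: Optional[OntologyStore] = None,
    k: int = 20,
) -> list[MatchCandidate]:
    """Top-*k* source candidates for a target attribute, best first.

    The query is the target's label/description tokens, expanded with
    synonyms and subclass labels of its ontology annotations when a store
    is given.
    """
    terms = annotate_attribute(target, store) if store is not None else []
    query = build_query(target, store, terms)
    return _ranked(index, query, k, frozenset(tokenize(target.label) or tokenize(target.name)))


def build_query(
    target: Optional[Attribute],
    store: Optional[OntologyStore],
    terms=None,
    max_subclass_depth: int = 3,
) -> ExpandedQuery:
    if store is None:
        q = ExpandedQuery(target_attribute=target)
        if target is not None:
            for tok in tokenize(f"{target.label} {target.description}") or tokenize(
                target.name
            ):
                q.query_terms.append((tok, "original"))
        return q
    if terms is None:
        terms = annotate_attribute(target, store) if target is not None else []
    return expand_query(target, terms, store, max_subclass_depth)


def manual_query(
    query_string: str,
    index: SearchIndex,
    store: Optional[OntologyStore] = None,
    k: int = 20,
) -> list[MatchCandidate]:
    """Free-text search with ``term1 or term2`` OR-semantics.

    Each term is ontology-expanded (when a store is given) before matching,
    exactly as if it were the label of a pseudo target attribute.
    """
    if not query_string or not query_string.strip():
        raise ValueError("query string must be non-empty")
    parts = [p.strip() for p in re.split(r"\bor\b", query_string, flags=re.I)]
    parts = [p for p in parts if p]
    merged = ExpandedQuery(target_attribute=None)
    seen: set[str] = set()
    for part in parts:
        pseudo = Attribute(name=part, entity="_query", label=part)
        terms = annotate_attribute(pseudo, store) if store is not None else []
        sub = build_query(pseudo, store, terms)
        for s, origin in sub.query_terms:
            key = s.casefold()
            if key not in seen:
                seen.add(key)
                merged.query_terms.append((s, origin))
    return _ranked(index, merged, k, frozenset())


def highlight(candidate: MatchCandidate, query: ExpandedQuery) -> MatchCandidate:
    """Mark every query token occurring in the candidate's label/description.

    Spans are character offsets into the exact original strings, so
    ``label[start:end].casefold() == token`` always holds.
    """
    attr = candidate.source_attribute
    qtokens = set(query.tokens())
    found: list[Highlight] = []
    for field_name, text in (("label", attr.label), ("description", attr.description)):
        lowered = text.casefold()
        for m in re.finditer(r"[a-z0-9]+", lowered):
            if m.group(0) in qtokens:
                found.append(Highlight(m.group(0), field_name, m.start(), m.end()))
    candidate.highlighted_tokens = found
    return candidate


def classify_confidence(
    candidates: list[MatchCandidate], target: Attribute
) -> str:
    """``high`` / ``low`` / ``none`` quality flag for a shortlist.

    ``high`` means the rank-1 candidate's label covers every non-stop-word
    token of the target label (a perfect lexical match); anything less is
    ``low``; an empty shortlist is ``none``.
    """
    if not candidates:
        return "none"
    target_tokens = [t for t in tokenize(target.label) or tokenize(target.name)]
    top = candidates[0].source_attribute
    cand_tokens = set(tokenize(top.label)) | set(tokenize(top.description))
    if target_tokens and all(t in cand_tokens for t in target_tokens):
        return "high"
    return "low"
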