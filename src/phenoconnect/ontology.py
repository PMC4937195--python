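"""Ontology store: load OBO-subset vocabularies, annotate attributes, expand queries.

Query expansion follows the subclass direction only: synonyms and descendant
labels of an annotated term are added to the search query, superclass labels
never are (walking up the hierarchy pulls in far too many false positives —
a query for "beer" should not match every alcoholic drink).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import obonet

from .emx import Attribute
from .text import tokenize

_SYNONYM_RE = re.compile(r'"(.*?)"')


class OntologyError(Exception):
    pass


@dataclass(frozen=True)
class OntologyTerm:
    """A concept: identifier, preferred label, synonyms and is_a parents."""

    term_id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()

    @property
    def all_names(self) -> tuple[str, ...]:
        return (self.label, *self.synonyms)


@dataclass
class ExpandedQuery:
    """A target attribute's search query after ontology expansion.

    ``query_terms`` is an ordered list of (string, origin) with origin one of
    ``original`` (attribute label/description tokens), ``synonym`` or
    ``subclass``. Strings are unique; original tokens are always present.
    """

    target_attribute: Optional[Attribute]
    query_terms: list[tuple[str, str]] = field(default_factory=list)

    @property
    def strings(self) -> list[str]:
        return [s for s, _ in self.query_terms]

    def tokens(self) -> list[str]:
        """All query strings broken into search tokens, de-duplicated in order."""
        seen: dict[str, None] = {}
        for s, _ in self.query_terms:
            for t in tokenize(s):
                seen.setdefault(t, None)
        return list(seen)


class OntologyStore:
    """Terms indexed by id and by casefolded label/synonym, with is_a traversal."""

    def __init__(self, terms: dict[str, OntologyTerm]):
        self.terms = terms
        self._by_name: dict[str, list[str]] = {}
        self._children: dict[str, list[str]] = {}
        for t in terms.values():
            for nm in t.all_names:
                self._by_name.setdefault(nm.casefold(), []).append(t.term_id)
            for p in t.parents:
                if p not in terms:
                    raise OntologyError(f"term {t.term_id}: parent {p} does not resolve")
                self._children.setdefault(p, []).append(t.term_id)

    def __len__(self) -> int:
        return len(self.terms)

    def get(self, term_id: str) -> OntologyTerm:
        return self.terms[term_id]

    def lookup(self, name: str) -> list[OntologyTerm]:
        """Terms whose label or any synonym equals *name*, case-insensitively."""
        return [self.terms[i] for i in self._by_name.get(name.casefold(), [])]

    def children(self, term_id: str) -> list[OntologyTerm]:
        return [self.terms[i] for i in self._children.get(term_id, [])]

    def descendants(self, term_id: str, max_depth: Optional[int] = None) -> list[OntologyTerm]:
        """All terms below *term_id* (excluding itself), breadth-first,
        truncated at *max_depth* is_a hops when given."""
        out: list[OntologyTerm] = []
        seen = {term_id}
        frontier = [term_id]
        depth = 0
        while frontier and (max_depth is None or depth < max_depth):
            depth += 1
            nxt: list[str] = []
            for tid in frontier:
                for c in self._children.get(tid, []):
                    if c not in seen:
                        seen.add(c)
                        out.append(self.terms[c])
                        nxt.append(c)
            frontier = nxt
        return out


def load_ontology(path) -> OntologyStore:
    """Parse an OBO flat file (id / name / synonym / is_a subset) into a store.

    Accepts a path or an open file-like object. Raises
    :class:`OntologyError` if the is_a graph contains a cycle, naming the
    terms involved.
    """
    source = path if hasattr(path, "read") else Path(path)
    graph = obonet.read_obo(source, ignore_obsolete=True)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        names = " -> ".join(edge[0] for edge in cycle)
        raise OntologyError(f"cyclic is_a chain: {names}")
    terms: dict[str, OntologyTerm] = {}
    for tid, data in graph.nodes(data=True):
        syns = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw)
            if m:
                syns.append(m.group(1))
        terms[tid] = OntologyTerm(
            term_id=tid,
            label=data.get("name", tid),
            synonyms=tuple(syns),
            parents=tuple(data.get("is_a", [])),
        )
    return OntologyStore(terms)


def annotate_attribute(attr: Attribute, store: OntologyStore) -> list[OntologyTerm]:
    """Find ontology terms matching an attribute's label + description.

    A term matches when its label or a synonym shares tokens with the
    attribute text; terms are scored by token-overlap ratio
    (shared tokens / attribute tokens) and returned best first, ties broken
    by shorter term label then id.
    """
    attr_tokens = set(tokenize(f"{attr.label} {attr.description}" or attr.name))
    if not attr_tokens:
        attr_tokens = set(tokenize(attr.name))
    if not attr_tokens:
        return []
    scored: list[tuple[float, int, str, OntologyTerm]] = []
    for term in store.terms.values():
        best = 0.0
        for name in term.all_names:
            toks = set(tokenize(name))
            if not toks:
                continue
            shared = len(toks & attr_tokens)
            # require the term name to be fully contained in the attribute text
            if shared and shared == len(toks):
                best = max(best, shared / len(attr_tokens))
        if best > 0:
            scored.append((best, len(term.label), term.term_id, term))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [t[-1] for t in scored]


def expand_query(
    target: Optional[Attribute],
    terms: list[OntologyTerm],
    store: OntologyStore,
    max_subclass_depth: int = 3,
) -> ExpandedQuery:
    """Build the expanded query: original tokens + synonyms + descendant labels.

    Superclass (reversed is_a) labels are never added. Duplicate strings are
    dropped, first origin wins, so original tokens always survive expansion.
    """
    q = ExpandedQuery(target_attribute=target)
    seen: set[str] = set()

    def add(s: str, origin: str) -> None:
        key = s.casefold().strip()
        if key and key not in seen:
            seen.add(key)
            q.query_terms.append((s, origin))

    if target is not None:
        for tok in tokenize(f"{target.label} {target.description}") or tokenize(target.name):
            add(tok, "original")
    for term in terms:
        for syn in (term.label, *term.synonyms):
            add(syn, "synonym")
        for desc in store.descendants(term.term_id, max_subclass_depth):
            for name in desc.all_names:
                add(name, "subclass")
    return q
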