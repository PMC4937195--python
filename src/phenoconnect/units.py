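"""Unit detection, composite-unit decomposition and conversion-factor generation.

Measurement units are recognised in attribute *labels* only, by exact
(case-insensitive) token equality against a packaged units ontology
("Height in cm" -> cm); fuzzy matching is deliberately refused to avoid
false positives. Composite units such as ``kg/m^2`` are decomposed into
atomic units with signed exponents and aligned atom-by-atom: the target
attribute's atoms are the standard, and each source atom gets a conversion
factor toward the matching target atom of the same dimension.

Conversion factors come from a packaged, user-overridable rule table
(``from  to  factor`` meaning ``value_to = value_from x factor``, e.g.
``m -> cm`` is 100). Factors are exact :class:`fractions.Fraction` values,
chained transitively within a dimension, so inverse and transitive closure
hold exactly. Only linear multiplicative conversions are supported; affine
scales (Celsius/Fahrenheit) are incompatible by construction.
"""

from __future__ import annotations

import csv
import re
from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Optional

from .emx import Attribute
from .ontology import OntologyStore, load_ontology


class UnitError(Exception):
    pass


class UnknownUnitError(UnitError):
    pass


class IncompatibleUnitsError(UnitError):
    pass


class UnitParseError(UnitError):
    pass


@dataclass(frozen=True)
class Unit:
    """A (possibly composite) unit as sorted (atomic symbol, exponent) pairs."""

    atoms: tuple[tuple[str, int], ...]

    def __post_init__(self):
        merged: dict[str, int] = {}
        for sym, exp in self.atoms:
            merged[sym] = merged.get(sym, 0) + exp
        clean = tuple(sorted((s, e) for s, e in merged.items() if e != 0))
        object.__setattr__(self, "atoms", clean)

    @classmethod
    def atomic(cls, symbol: str) -> "Unit":
        return cls(((symbol, 1),))

    @property
    def is_atomic(self) -> bool:
        return len(self.atoms) == 1 and self.atoms[0][1] == 1

    def __str__(self) -> str:
        return "·".join(
            sym if exp == 1 else f"{sym}^{exp}" for sym, exp in self.atoms
        )


@dataclass(frozen=True)
class ConversionStep:
    """Convert one source atom to the matching target atom."""

    from_symbol: str
    to_symbol: str
    factor: Fraction  # value_to = value_from * factor (for exponent +1)


@dataclass
class ConversionPlan:
    """Result of aligning a source unit with a target unit."""

    steps: list[ConversionStep]
    value_factor: Fraction  # overall multiplier for a raw source value

    @property
    def is_identity(self) -> bool:
        return not self.steps


@dataclass(frozen=True)
class UnitDetection:
    unit: Optional[Unit]
    ambiguous: bool = False
    all_matches: tuple[Unit, ...] = ()


_SUP_RE = [("⁻²", "^-2"), ("⁻³", "^-3"), ("²", "^2"), ("³", "^3")]
_ATOM_RE = re.compile(r"\s*([A-Za-z]+)\s*(?:\^\s*(-?\d+))?\s*")


class ConversionRules:
    """Bidirectional transitive closure over an atomic conversion-rule table."""

    def __init__(self, rows: list[tuple[str, str, Fraction]]):
        self._adj: dict[str, list[tuple[str, Fraction]]] = {}
        for frm, to, factor in rows:
            if factor <= 0:
                raise UnitError(f"conversion factor must be positive: {frm}->{to}")
            self._adj.setdefault(frm, []).append((to, factor))
            self._adj.setdefault(to, []).append((frm, 1 / factor))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConversionRules":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for rec in csv.DictReader(fh, delimiter="\t"):
                rows.append((rec["from"], rec["to"], Fraction(rec["factor"])))
        return cls(rows)

    @property
    def symbols(self) -> set[str]:
        return set(self._adj)

    def factor(self, from_symbol: str, to_symbol: str) -> Fraction:
        """Exact factor with ``value_to = value_from * factor``; transitive."""
        if from_symbol == to_symbol:
            return Fraction(1)
        if from_symbol not in self._adj or to_symbol not in self._adj:
            raise IncompatibleUnitsError(
                f"no conversion between {from_symbol!r} and {to_symbol!r}"
            )
        seen = {from_symbol: Fraction(1)}
        q = deque([from_symbol])
        while q:
            cur = q.popleft()
            for nxt, f in self._adj[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] * f
                    if nxt == to_symbol:
                        return seen[nxt]
                    q.append(nxt)
        raise IncompatibleUnitsError(
            f"units {from_symbol!r} and {to_symbol!r} have different dimensions"
        )

    def dimension(self, symbol: str) -> frozenset[str]:
        """The connected component of a symbol (its compatibility class)."""
        if symbol not in self._adj:
            return frozenset({symbol})
        seen = {symbol}
        q = deque([symbol])
        while q:
            for nxt, _ in self._adj[q.popleft()]:
                if nxt not in seen:
                    seen.add(nxt)
                    q.append(nxt)
        return frozenset(seen)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("phenoconnect").joinpath("data", name)))


class UnitEngine:
    """Units ontology + conversion rules behind one façade.

    The symbol of a unit term is, by packaging convention, its first
    synonym (the name itself when a term has no synonyms).
    """

    def __init__(
        self,
        store: Optional[OntologyStore] = None,
        rules: Optional[ConversionRules] = None,
    ):
        self.store = store or load_ontology(_data_path("units.obo"))
        self.rules = rules or ConversionRules.from_tsv(_data_path("conversion_rules.tsv"))
        self._symbol_by_name: dict[str, str] = {}
        for term in self.store.terms.values():
            symbol = term.synonyms[0] if term.synonyms else term.label
            for nm in term.all_names:
                self._symbol_by_name.setdefault(nm.casefold(), symbol)

    # -- resolution ---------------------------------------------------------

    def resolve_symbol(self, token: str) -> Optional[str]:
        """Canonical atomic symbol for an exact name/synonym match, else None."""
        return self._symbol_by_name.get(token.strip().casefold())

    def parse_composite(self, text: str) -> Unit:
        """Parse ``kg/m^2``-style composite unit text into a :class:`Unit`.

        ``/`` negates all subsequent exponents; ``·`` and ``*`` separate
        factors; unicode superscripts are accepted as ``^n``.
        """
        s = text.strip()
        for sup, repl in _SUP_RE:
            s = s.replace(sup, repl)
        s = s.replace("·", "*").replace("×", "*")
        if not s:
            raise UnitParseError("empty unit expression")
        atoms: list[tuple[str, int]] = []
        sign = 1
        pos = 0
        expect_atom = True
        while pos < len(s):
            if expect_atom:
                m = _ATOM_RE.match(s, pos)
                if not m or not m.group(1):
                    raise UnitParseError(f"cannot parse unit expression {text!r}")
                sym = self.resolve_symbol(m.group(1))
                if sym is None:
                    raise UnitParseError(f"unknown unit {m.group(1)!r} in {text!r}")
                exp = int(m.group(2)) if m.group(2) else 1
                atoms.append((sym, sign * exp))
                pos = m.end()
                expect_atom = False
            else:
                c = s[pos]
                if c == "/":
                    sign = -1
                elif c == "*":
                    pass
                elif c.isspace():
                    pos += 1
                    continue
                else:
                    raise UnitParseError(f"unexpected {c!r} in unit expression {text!r}")
                pos += 1
                expect_atom = True
        if expect_atom:
            raise UnitParseError(f"dangling separator in unit expression {text!r}")
        return Unit(tuple(atoms))

    # -- detection ----------------------------------------------------------

    def detect_unit(self, attr: Attribute) -> UnitDetection:
        """Detect a unit in an attribute's label by exact token matching.

        Parenthesised expressions are tried as composite units first
        ("BMI (kg/m^2)"), then individual whitespace/punctuation tokens as
        atomic units ("Height in cm"). Two distinct matches set the
        ambiguity flag; the first match (left to right) is returned.
        """
        label = attr.label or attr.name
        matches: list[Unit] = []

        def note(u: Unit) -> None:
            if u not in matches:
                matches.append(u)

        remainder = label
        for group in re.findall(r"\(([^)]*)\)", label):
            try:
                note(self.parse_composite(group))
                remainder = remainder.replace(f"({group})", " ")
            except UnitParseError:
                pass
        for token in re.split(r"[\s,;:]+", remainder):
            if not token:
                continue
            bare = token.strip(".")
            sym = self.resolve_symbol(bare)
            if sym is not None:
                note(Unit.atomic(sym))
            elif re.search(r"[/^²³·*]", bare):
                try:
                    note(self.parse_composite(bare))
                except UnitParseError:
                    pass
        if not matches:
            return UnitDetection(None)
        return UnitDetection(
            unit=matches[0], ambiguous=len(matches) > 1, all_matches=tuple(matches)
        )

    # -- conversion ---------------------------------------------------------

    def conversion_factor(self, from_atom: str, to_atom: str) -> Fraction:
        """Atomic factor with ``value_to = value_from * factor`` (m->cm = 100)."""
        for sym in (from_atom, to_atom):
            if sym not in self.rules.symbols and self.resolve_symbol(sym) is None:
                raise UnknownUnitError(f"unknown unit symbol {sym!r}")
        return self.rules.factor(from_atom, to_atom)

    def align_units(
        self, target_unit: Optional[Unit], source_unit: Optional[Unit]
    ) -> ConversionPlan:
        """Per-atom conversion plan from source toward the target's atoms.

        The target's atoms are the standard. When only one side declares a
        unit, the other is assumed equal and no conversion is planned.
        Atoms are matched by dimension; a source dimension with no partner
        in the target raises :class:`IncompatibleUnitsError`.
        """
        if target_unit is None or source_unit is None:
            return ConversionPlan(steps=[], value_factor=Fraction(1))
        target_dims = {self.rules.dimension(sym): sym for sym, _ in target_unit.atoms}
        steps: list[ConversionStep] = []
        value_factor = Fraction(1)
        for sym, exp in source_unit.atoms:
            dim = self.rules.dimension(sym)
            if dim not in target_dims:
                raise IncompatibleUnitsError(
                    f"source unit {sym!r} has no dimension partner in target "
                    f"unit {target_unit}"
                )
            tsym = target_dims[dim]
            if tsym != sym:
                f = self.rules.factor(sym, tsym)
                steps.append(ConversionStep(sym, tsym, f))
                value_factor *= f ** exp
        return ConversionPlan(steps=steps, value_factor=value_factor)

    def value_factor(self, from_text: str, to_text: str) -> Fraction:
        """Overall multiplier taking a value in ``from_text`` units to
        ``to_text`` units (used by the DSL's ``toUnit``)."""
        frm = self.parse_composite(from_text)
        to = self.parse_composite(to_text)
        plan = self.align_units(to, frm)
        # every target dimension must be covered by the source
        src_dims = {self.rules.dimension(sym) for sym, _ in frm.atoms}
        for sym, _ in to.atoms:
            if self.rules.dimension(sym) not in src_dims:
                raise IncompatibleUnitsError(
                    f"cannot convert {from_text!r} to {to_text!r}"
                )
        return plan.value_factor

    # -- snippet generation -------------------------------------------------

    def conversion_calls(self, from_atom: str, to_atom: str, style: str = "formula") -> str:
        """The method-chain fragment (no accessor, no ``.value()``) that
        converts ``from_atom`` to ``to_atom``; empty for identical units."""
        if from_atom == to_atom:
            return ""
        if style == "chain":
            return f".unit('{from_atom}').toUnit('{to_atom}')"
        f = self.conversion_factor(from_atom, to_atom)
        if f.denominator == 1:
            return f".times({f.numerator})"
        if f.numerator == 1:
            return f".div({f.denominator})"
        return f".times({float(f):.10g})"

    def generate_unit_snippet(
        self,
        source_attr_name: str,
        from_atom: str,
        to_atom: str,
        style: str = "formula",
    ) -> str:
        """A complete conversion script for one attribute.

        chain style:   ``$('Height').unit('cm').toUnit('m').value()``
        formula style: ``$('Height').div(100).value()``
        Identical units give the bare rename ``$('Height').value()``.
        """
        if style not in ("chain", "formula"):
            raise ValueError(f"unknown snippet style {style!r}")
        calls = self.conversion_calls(from_atom, to_atom, style)
        return f"$('{source_attr_name}'){calls}.value()"
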