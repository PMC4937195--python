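# Methods

This note documents the models and procedures behind `phenoconnect`, the
parameters that matter, the numerical choices, and what the synthetic test
study does and does not demonstrate.

## Metadata model

Datasets travel as two-table workbooks: an `attributes` sheet (columns
`name, entity, dataType, label, description, refEntity`; unknown extra
columns are ignored with a warning) plus one data sheet per entity. Both
xlsx workbooks and directories of CSV files (UTF-8, comma, quoted) are
accepted, and writing emits the same dialect reading accepts, so
read→write→read is the identity cell-for-cell. Two conventions are fixed
deliberately:

- **Missing values**: an empty cell and the literal `NA` both become an
  internal null — both spellings occur in real spreadsheet exports.
- **Codes are strings**: category codes are never coerced to integers
  (`"01"` must survive a round trip), and all cell values stay strings
  until an algorithm types them on access.

Validation is non-throwing: `validate_schema` returns violation records
(entity, attribute, row, message) so a data manager can fix a workbook in
one pass. A schema that validates cleanly is consumable by every
downstream module without type errors.

## Semantic search

Source attributes are indexed as small documents (label + description,
lowercased, split on non-alphanumerics, ~30 English function words
removed). Target attributes become queries through two steps:

1. **Annotation** — ontology terms whose label or synonym is fully
   contained in the attribute's label/description tokens are attached,
   scored by token-overlap ratio (shared tokens / attribute tokens), ties
   to the shorter term label.
2. **Expansion** — the query is the attribute's own tokens plus the
   synonyms and descendant labels (to `max_subclass_depth`, default 3) of
   its annotated terms. Superclass labels are never added: expanding
   upward floods the shortlist with false positives (a query about beer
   should not match every alcoholic drink). The depth cap keeps expansion
   tractable on large ontologies.

Scoring is BM25 with the conventional k1 = 1.2, b = 0.75; expanded terms
enter the query at the same weight as original tokens. Two deterministic
refinements make results reproducible and pin the obvious case: a source
attribute whose label tokens equal the target's label tokens always ranks
first, and equal scores are ordered by attribute name. The shortlist
length k defaults to 20 — the same window the good/bad evaluation
threshold uses, chosen because real harmonization projects occasionally
need 10+ source attributes per target. Confidence is coverage-based: the
flag is *high* only when the top candidate's label covers every
non-stop-word token of the target label.

## Transformation language

All generated algorithms are expressed in a closed chained-method
language: `$('attr')` accesses a value; `div, times, plus, pow, map, unit,
toUnit, value` transform it. This is a hand-rolled recursive-descent
parser and interpreter, not embedded JavaScript — a closed language is
injection-safe and every construct is testable. Semantics:

- Arithmetic is exact `decimal.Decimal` arithmetic (28-digit context), so
  unit factors like 1/100 introduce no binary-float noise; values render
  with up to 10 significant digits.
- Null is absorbing: any arithmetic or mapping of a missing value is
  missing. Division by zero yields null with a logged warning; an unmapped
  `map()` code yields null. Neither is an error — real data contains
  zeros and stray codes, and a single cell should not abort a run. A
  reference to an attribute absent from the source entity *is* an error
  and is counted as a conversion failure.
- `unit(u).toUnit(v)` multiplies by the exact conversion factor, making
  the chain style provably equivalent to the generated arithmetic style
  (`div(100)`), which the test suite verifies for every compatible pair in
  the rule table.
- Canonical printing uses single straight quotes; typographic quotes are
  accepted on input (labels are routinely pasted from word processors).
  `parse` then print is a fixpoint.
- A conditional form (`cond ? a : b` with `>=, <=, >, <, ==, ||`) exists
  for algorithm templates only (the hypertension template needs a
  cut-off); the automatic generator never synthesizes conditionals, so the
  default parser rejects them.

## Unit harmonization

Units are detected in attribute **labels only** (descriptions are prose
and too noisy), by exact case-insensitive token equality against a
packaged units ontology — fuzzy unit matching is refused outright because
a false unit match silently corrupts every value. Parenthesised
expressions are tried first as composite units (`BMI (kg/m^2)`), then
individual tokens as atomic units. Two distinct matches in one label set
an ambiguity flag for the caller to resolve. By packaging convention a
unit term's symbol is its first synonym (its name when it has none).

Composite units decompose into (symbol, exponent) atoms — `kg/m^2` →
kg¹·m⁻²; `/` negates subsequent exponents and unicode superscripts are
normalised. Alignment treats the **target's atoms as the standard**: each
source atom is matched by dimension (connected component of the rule
table) and converted toward the target atom. When only one side declares a
unit the other is assumed equal and no conversion is inserted — guessing a
conversion would be worse than none, and the preview makes a wrong
assumption visible immediately.

Conversion factors come from a packaged, editable TSV (`from, to, factor`
with `value_to = value_from × factor`; SI length/mass/volume plus mmHg and
day/week/month/year). Factors are `fractions.Fraction`, so inverse
(`f(a,b)·f(b,a) = 1`) and transitive closure hold *exactly*, not to
rounding. Only linear multiplicative conversions are representable;
affine scales (°C ↔ °F) are incompatible by construction since the
language's `div/times` cannot express offsets.

## Category matching

Three strategies run in a fixed order — rules, then frequency, then
lexical — and every mapped pair records which one produced it:

- **Rules** (packaged YAML, user-overridable): case-insensitive
  full-match regexes over labels, e.g. never→no, ever→yes,
  missing/unknown→null (drop). Higher priority wins; equal-priority
  conflicts are a configuration error. Rules exist precisely for pairs
  lexical similarity gets wrong ("Never" is lexically closer to "Never
  married" than to "No").
- **Frequency**: labels like "2–4 times a week" parse into an amount (the
  range mean, 3) and a time unit; rates normalise per day with calendar
  averages day = 1, week = 7, month = 30.44, year = 365.25 (calendar
  averages avoid month-length bias). Each source category maps to the
  target with the nearest rate; many-to-one is allowed because divergent
  scales rarely align one-to-one. Rate ties go to the lower-rate target —
  deterministic and conservative (under-reports frequency). Categories
  that do not parse fall through to the lexical matcher.
- **Lexical**: Dice coefficient over padded character bigrams of
  normalised labels (lowercase, punctuation stripped). Bigrams with
  one-space padding are the conventional n-gram choice and are pinned by
  a brute-force oracle in the tests. Each source category takes its
  argmax-similarity target, ties to the lowest target code.

The combined map renders as a `map({...})` script with pairs in source-code
order; an empty map is a generation error and the caller emits no
algorithm instead.

## Algorithm generation

Per target × source cell: shortlist → template → fallbacks.

- **Templates** (packaged YAML catalogue, user-editable): BMI
  (weight_kg / height_m²) and hypertension (SBP ≥ 140 or DBP ≥ 90). A
  template is *proposed* when the target label matches a trigger or any
  candidate lexically matches a slot (threshold 0.5 bigram-Dice), but the
  automatic pipeline only *commits* to a template whose trigger matches
  the target itself — otherwise every plain height target would become a
  BMI. Slots are filled greedily with distinct candidates by similarity;
  each filled slot gets unit conversions toward its expected unit. Any
  unfillable slot abandons the template and falls back.
- **Fallbacks**, in order: categorical target with categorical top
  candidate → category map; numeric target with units on both sides →
  unit-conversion snippet (or bare rename when units already agree);
  otherwise bare rename `$('X').value()`. No candidates at all → the cell
  stays missing.

Project cells carry a state (generated-high / generated-low / curated /
missing); curated cells survive regeneration unless forced. Projects
persist as JSON (cells, scripts, states).

## Integration

Scripts execute row by row over the source entity that holds their
referenced attributes. Failures are counted per (row × attribute)
*evaluation error* — nulls from missing data are not failures; the
distinction matters because a harmonization run over sparse questionnaire
data would otherwise drown real errors in noise. Preview returns exactly
the full-run prefix. Exports (CSV set or xlsx) write nulls as empty cells
and re-read losslessly.

## Synthetic study and evaluation

`generate_fixture(seed, n_rows=50, n_biobanks=3)` builds the packaged
study: six target variables (height in m, weight in kg, gender, BMI, a
potato-consumption frequency scale, hypertension) against three biobanks
that disagree on names (Height / Length / Body length), units (cm vs m,
kg vs g), codings (1/2 vs M/F vs 0/1) and frequency scales, plus
distractor attributes and a small phenotype ontology. Hypertension shares
no label token with its sources ("Elevated blood pressure", "High blood
pressure diagnosed") and is findable only through synonym expansion —
removing the ontology demotes it to a bad search, which the regression
test pins. Heights are drawn as integer centimetres (150–195) so the
cm-coded biobank is exactly 100× the m-coded one per participant; weights
are integer kilograms (50–110); ~4% of height cells are missing to
exercise null propagation. Defaults (50 rows, 3 biobanks) are small
enough to regenerate in milliseconds yet cover every generator path.

What passing this study shows: the search, expansion, unit, category,
template and integration machinery compose correctly on controlled
divergences. What it does not show: performance on real biobank
dictionaries, whose labels are longer, noisier, multilingual and full of
repeated measurements and negations; the fixture's 100%-useful score is a
regression pin, not a claim about real-world accuracy.

Evaluation classes: search is perfect (a gold attribute at rank 1) /
good (all gold attributes in the top 20) / bad; algorithms are perfect
(canonical-text identical or functionally equivalent on the data, decimals
within 1e-9 relative) / good (no contradicted pair and at least half the
reference map pairs present, or the right source attributes with a wrong
or missing conversion) / bad. The "useful" total counts both-at-least-good
cells plus the (bad search, perfect algorithm) and (perfect search, bad
algorithm) corners, where the remaining human effort is one click or one
small edit.

## Known limitations

- Query expansion is subclass-only by design; targets whose sources sit
  *above* them in the hierarchy are missed, and no semantic-relatedness
  metric compensates.
- Unit detection cannot recover units absent from labels; no inference
  from value distributions is attempted.
- The template catalogue is two entries; there is no learning of new
  templates from curated algorithms.
- One source code maps to at most one target code; free-text value
  recoding is out of scope.
- Repeated measurements (e.g. three blood-pressure readings) are not
  averaged; each is an independent candidate.
- The units ontology and category-rule defaults are compact stand-ins
  meant to be extended per project, not exhaustive references.
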