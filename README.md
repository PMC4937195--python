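# phenoconnect

Semi-automatic harmonization of heterogeneous biobank phenotype data.

Pooled epidemiological analyses need variables from many biobanks, patient
registries and cohorts expressed against one common *target DataSchema*.
In practice every collection names, codes and measures its variables
differently — `Height in cm` vs `Body length in m`, gender coded `1/2` vs
`M/F` vs `0/1`, food-frequency scales that never align one-to-one. Matching
thousands of source attributes to a target schema by hand, and then writing
an extract-transform-load script per match, is the bottleneck of
retrospective data integration. `phenoconnect` automates the bulk of it for
data managers and harmonization teams:

1. **Semantic search** — every source attribute (label + description) is
   indexed; each target attribute becomes a query that is *ontology
   expanded* with synonyms and subclass labels (never superclasses), then
   scored with BM25 (k1 = 1.2, b = 0.75). The result is a ranked shortlist
   with the matching words highlighted and a high/low confidence flag.
2. **Algorithm generation** — per target × source cell the engine emits an
   executable script in a small chained-expression language
   (`$('attr').div(2)`, `map({...})`, `unit('cm').toUnit('m')`):
   - *unit conversion*: units are detected in attribute labels by exact
     token match against a units ontology; composite units such as
     `kg/m²` are decomposed into atomic units (kg, m⁻²) and each source
     atom is converted toward the target's standard atom
     (`value_to = value_from × factor`, e.g. factor(m→cm) = 100);
   - *categorical recoding*: source codes map to target codes by hard
     rules, then frequency quantification ("2–4 times a week" → amount 3
     per week → rate/day) with nearest-rate, many-to-one matching, then
     bigram-Dice lexical similarity as the fallback;
   - *templates*: recurring constructs (BMI = weight_kg / height_m²,
     hypertension from SBP/DBP cut-offs) are filled slot-by-slot from the
     shortlist with per-slot unit conversions inserted.
3. **Integration** — the generated (or hand-curated) scripts run row by row
   over the source data to produce the derived target-schema dataset, with
   per-attribute failure counts; missing inputs propagate as nulls, not
   failures.
4. **Evaluation** — against gold-standard mappings, search results are
   classified perfect (gold at rank 1) / good (all gold in the top 20) /
   bad, and algorithms perfect (textually or functionally equivalent to
   the reference) / good (almost right, e.g. half a category map) / bad;
   the report cross-tabulates both as percentages.

A deterministic synthetic multi-biobank study (three divergent
dictionaries, gold mappings, a small phenotype ontology) ships with the
package for testing and demonstration.

## Worked example

```python
from phenoconnect import (
    generate_fixture, generate_project, apply_project, evaluate_project,
)
from phenoconnect.units import UnitEngine

fx = generate_fixture(seed=42, n_rows=50, n_biobanks=3)
eng = UnitEngine()
project = generate_project(fx.target, fx.sources, store=fx.store, unit_engine=eng)

for t in ("stature", "gender", "bmi"):
    cell = project.cell(t, "biobank1")
    print(f"{t:8s} [{cell.algorithm.provenance}] {cell.algorithm.text}")

result = apply_project(project, fx.sources[0], eng)
print("rows:", result.n_rows, "failed conversions:", result.total_failures)
print("first row:", result.derived.rows[0])

report = evaluate_project(project, fx.gold, fx.sources, store=fx.store, unit_engine=eng)
print(report.summary())
```

prints

```
stature  [unit_conversion] $('HEIGHT').div(100).value()
gender   [category_map] $('SEX').map({'1':'0','2':'1'})
bmi      [template] $('WEIGHT').div($('HEIGHT').div(100).pow(2)).value()
rows: 50 failed conversions: 0
first row: {'stature': '1.54', 'body_weight': '96', 'gender': '1', 'bmi': '40.47900152', 'potato_freq': '2', 'hypertension': '1'}
         perfect  good  bad
perfect    100.0   0.0  0.0
good         0.0   0.0  0.0
bad          0.0   0.0  0.0
useful: 100.0% of 18 cells
```

The three scripts show the three generator paths: biobank1 stores height in
cm while the target wants metres (`div(100)`), codes gender `1/2` against
the target's `0/1` (the `map`), and has no BMI column, so the BMI template
is filled from the matched weight and height attributes with the cm→m
conversion inserted. The evaluation classifies all 18 gold-covered cells
(6 targets × 3 biobanks) as perfect search with a perfect algorithm.

The same flow is available from the shell:

```bash
phenoconnect fixture --seed 42 -o fx
phenoconnect generate fx/target fx/biobank1 fx/biobank2 fx/biobank3 \
    --ontology fx/phenotypes.obo -o project.json
phenoconnect apply project.json fx/target fx/biobank1 -o derived
phenoconnect evaluate project.json fx/target fx/biobank1 fx/biobank2 fx/biobank3 \
    --gold fx/gold.tsv --ontology fx/phenotypes.obo
```

## Layout

- `phenoconnect.emx` — the two-table workbook model (attributes metadata +
  data sheets), xlsx and CSV-set dialects, validation
- `phenoconnect.ontology` — OBO-subset loading, attribute annotation,
  query expansion
- `phenoconnect.search` — BM25 shortlist, manual `term1 or term2` queries,
  highlighting, confidence
- `phenoconnect.dsl` — parser and interpreter for the transformation
  language
- `phenoconnect.units` — unit detection, composite decomposition,
  conversion factors, snippet generation
- `phenoconnect.categories` — rules / frequency / n-gram category matching
- `phenoconnect.generate` — templates, per-target generation, mapping
  projects
- `phenoconnect.integrate` — project execution, preview, export
- `phenoconnect.synth`, `phenoconnect.evaluate` — synthetic studies and
  gold-standard scoring
- `phenoconnect.cli` — the `phenoconnect` command

See `docs/methods.md` for the underlying models, parameter choices and
limitations.
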