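# clamlkit

A toolkit for auditing the hierarchy of ClaML-encoded health
classifications (the WHO-family XML exchange format, e.g. ICF and ICD):

- **claml_io** — parse/serialize ClaML into a typed classification model;
  code-shape semantics (chapter / block / category / subcategory),
  residual-class ("Other specified" / "Unspecified") detection, flat TSV
  debugging view.
- **relationships** — a six-way typology over parent-child links
  (Subsumption, SubProcess, Agent, Patient, Instrument, Complexity),
  annotation TSV I/O, rule-based suggestions from lexical cues, and
  per-chapter/per-level tabulation. Blocks are transparent: a
  chapter → block → category chain counts as one top-level edge.
- **stats** — summary statistics over a count table: top-level
  subsumption %, lower-level non-subsumption % (overall and per chapter,
  half-away-from-zero integer rounding), majority and all-subsumption
  chapter sets; TSV/Markdown/JSON rendering with exact fractions.
- **owl_export** — deterministic OWL rendering (RDF/XML and Turtle) with
  rubrics as annotations; annotated exports either record proposed
  relations non-destructively or, in strict mode, replace
  non-subsumption subclass axioms with existential restrictions.
- **sumo_mapping** — curated code → upper-ontology mapping tables,
  per-level coverage reports, and SKOS-style match annotations.
- **fixtures** — a deterministic synthetic ClaML/annotation generator
  plus packaged reference data for the ICF Activities and Participation
  component (chapter list, relationship count table, SUMO mapping
  entries, a Discussion subtree excerpt).
- **rdf** — the minimal triple model backing the OWL layer: writers and
  *independent* parsers for both dialects, blank-node-aware isomorphism.

## CLI

```sh
clamlkit convert icf.xml --dialect turtle            # ClaML -> OWL
clamlkit convert icf.xml --annotations edges.tsv --strict-relations
clamlkit stats --counts counts.tsv --format json     # table + summary
clamlkit stats --annotations edges.tsv
clamlkit suggest icf.xml                             # proposed annotation TSV
clamlkit coverage --mappings map.tsv --levels chapters.tsv
clamlkit validate icf.xml                            # issue list, exit 1 if any
clamlkit synth --chapters 3 --seed 7                 # synthetic ClaML
```

Machine output goes to stdout (or `-o FILE`); logs go to stderr.
Exit codes: 0 success, 1 validation/input failure, 2 usage/parameter
error. A YAML file passed via `--config` can pre-set any subcommand flag
(explicit flags win).

### File formats

- annotation TSV: `parent_code  child_code  relation  [note]`
- long count TSV: `chapter  level  relation  count`
- mapping TSV: `source_code  target_concept  [match_kind]  [note]`
- level totals TSV: `level  total`

All formats accept `#` comment lines and are UTF-8.

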