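# diseasechain

A library and CLI for modelling diseases as causal chains of abnormal
states. A disease is a set of state references into a global pool of
directed causal links; its chain is the induced subgraph on those
states, aggregated over its super-diseases. On top of that model the
package provides:

- **Subsumption-aware chain inclusion** (`chain_included_in`): an
  injective node map under the state is-a hierarchy, with links matched
  either by direct links (`strict`) or by directed paths (`path`, the
  default — authored chains may elide intermediates, written as
  "unknown" placeholder nodes).
- **Disease is-a inference** (`infer_isa_hierarchy`): one disease is a
  super-class of another iff its chain is included in the other's;
  results come with transitive reduction, equivalence and
  declared-vs-inferred reporting.
- **Core-chain extraction** (`core_causal_chain`): the part of a
  disease's chain covered by every subclass chain, by per-element
  filtering.
- **Traversal** (`upstream_closure` / `downstream_closure`,
  `general_graph`, `diseases_containing`): possible causes and
  consequences over the bottom-up union of all authored chains.
- **Interoperable state forms** (`states`): quantitative ↔ qualitative
  ↔ property conversion driven by a user-supplied rule table
  (e.g. blood pressure 180 mmHg ↔ blood pressure high ↔ hypertension
  true), three-layer level checks, and exact-string-match candidate
  detection against external vocabularies.
- **RDF layer** (`rdf_io`): lossless, byte-stable Turtle round-trips
  (`hasCause`/`hasResult` inverse pairs materialized,
  `hasCoreState`/`hasDerivedState`, `subDiseaseOf`/`subStateOf`), and
  nine named query patterns implemented twice — natively and as SPARQL
  texts executable by any conformant engine.
- **Fixtures and a generator** (`synthetic_data`): the worked diabetes
  family and stenosis hierarchy are packaged as TSV/Turtle, and a
  seeded generator produces random ontologies with planted is-a ground
  truth for recovery testing.

A copy of rdflib (BSD-3; plus its `pyparsing` dependency declared in
`pyproject.toml`) is vendored under `src/rdflib` so the RDF layer works
in offline environments.

## CLI

Every operation is exposed through the `diseasechain` command. The
ontology input is a directory of three TSV tables (`states.tsv`,
`links.tsv`, `diseases.tsv`) or a Turtle file; the packaged fixtures
are available via `--fixture`.

```sh
diseasechain validate --fixture diabetes
diseasechain query core_states --disease type_I_diabetes --fixture diabetes
diseasechain query general_chain --state deficiency_of_insulin --fixture diabetes --engine sparql
diseasechain infer-isa --fixture diabetes
diseasechain core-chain diabetes --fixture diabetes --format dot
diseasechain trace down deficiency_of_insulin --fixture diabetes
diseasechain diseases-of deficiency_of_insulin --fixture diabetes
diseasechain interop --form "qt:blood||pressure|180|mmHg" --form "prop:hypertension|true"
diseasechain map-terms --fixture stenosis -o candidates.tsv
diseasechain summarize-mapping --fixture stenosis --candidates candidates.tsv
diseasechain generate --seed 1 --n-diseases 30 --out-dir out/
diseasechain convert --fixture diabetes --to turtle -o diabetes.ttl
```

Exit codes: 0 success, 1 validation findings / negative result, 2 usage
error. `--config config.yaml` supplies defaults; explicit flags win.

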