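# kbseed

**kbseed** builds small, self-contained biomedical knowledge bases — *seeds*
— from heterogeneous sources, declaratively. A seed's configuration names
the external sources (CSV files, XML documents, SQL query results, SPARQL
endpoints), says where in each source the values live, and which RDF
predicates those values should populate. The engine does the rest:
extract, transform into a model-independent record layer, and load as
triples. The resulting store is exposed through a triple-pattern REST
grammar, a read-only SPARQL endpoint and dereferenceable LinkedData views,
and several seeds can be queried jointly through SPARQL `SERVICE`
federation.

It is aimed at bioinformatics developers who need an *ad hoc* integrated
knowledge base — say, a rare-disease portal linking disease numbers to
genes, proteins, structures and literature — without writing a bespoke ETL
pipeline or standing up heavyweight triple-store infrastructure.

## The model

Data are organised as a three-level tree:

```
Seed ──includes──▶ Entity ──isEntityOf──▶ Concept ──isConceptOf──▶ Item
                   (Protein)              (UniProt)                (P51587)
```

* an **Entity** is a broad category ("Protein", "Disease", "Gene");
* a **Concept** is a source-specific type under one entity ("UniProt",
  "OMIM", "HGNC");
* an **Item** is one record of a concept, minted as
  `<namespace><lowercase(concept)>_<percent-encoded id>` — e.g.
  `seed:uniprot_P51587`, `seed:omim_114480`, `seed:hgnc_HGNC%3A1101`.

Registered inverse pairs (`includes`/`isIncludedIn`,
`isEntityOf`/`hasEntity`, `isConceptOf`/`hasConcept`) and the symmetric
`isAssociatedTo` are materialised in both directions at write time, so the
plain triple-pattern API sees them without a reasoner.

Each concept is fed by **Resources**. A resource names its connector kind
(`csv` | `xml` | `sql` | `sparql`), an endpoint URI, a method, and a set of
**selectors** — a location in the source (column index, XPath, column
name, or variable name) paired with the predicate CURIEs its values
populate; exactly one selector is the *key* and yields the item
identifier. The three methods are:

* `cache` — create new items from scratch (the default);
* `complete` — append properties to items that already exist in the
  concept named by `extends`, either one fetch per item (a `#replace#`
  token in the endpoint is substituted with each identifier) or one fetch
  joined on the key value;
* `map` — link existing items of two concepts with `isAssociatedTo`,
  creating nothing else.

Because `complete` and `map` depend on previously loaded items, resources
form a dependency graph; builds run in topological order with `(order,
key)` tie-breaking.

## A worked example

```python
from kbseed import KnowledgeBase, build_seed, minimal_gene_model

# genes.csv:  hgnc_id,approved_symbol \n HGNC:1101,BRCA2 \n ...
model = minimal_gene_model("genes.csv", namespace="http://example.org/genes/")
kb = KnowledgeBase.for_model(model)
report = build_seed(model, kb)
```

With three data rows this prints (see `examples/01_load_gene_list.py`):

```
rows ingested     : 3
items created     : 3
statements in store: 51 (30 from the configuration tree)

statements about the first gene:
  http://example.org/genes/symbol  ->  BRCA2
  http://kbseed.dev/ontology#hasConcept  ->  http://example.org/genes/concept_HGNC
  http://purl.org/dc/elements/1.1/identifier  ->  HGNC:1101
  http://purl.org/dc/elements/1.1/source  ->  HGNC:1101
  ...rdf-syntax-ns#type  ->  http://kbseed.dev/ontology#Item
  ...rdf-schema#label  ->  HGNC HGNC:1101
```

Column 0 was declared with *two* properties (`dc:source`,
`dc:identifier`), so each row yields two property statements sharing one
subject and one object — plus four structural triples per item (type,
concept membership both ways, label). The colon in `HGNC:1101` is
percent-encoded in the item URI but untouched in literal values.

The other examples build on this: `02_explore_api.py` reads the same item
through the REST triple grammar
(`/api/triple/{sub}/{pred}/{obj}/{format}` with positional wildcards
`sub|s`, `pred|p`, `obj|o` and formats `csv|js|xml|rdf|html`), the SPARQL
endpoint and the LinkedData view; `03_federation.py` answers one question
across three live endpoints with a three-`SERVICE` query;
`04_integration_chain.py` builds the full eleven-concept rare-disease
chain over all four connector kinds and prints the per-resource report.

A thin CLI wraps the same functions:

```bash
kbseed fixtures --out bundle/            # generate an offline source bundle
kbseed build --config config.json --setup setup.ttl --out seed.ttl
kbseed query --store seed.ttl --sparql query.rq --output csv
kbseed serve --store seed.ttl --port 8080
```

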