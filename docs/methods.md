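# Methods

This note records how kbseed models, builds and serves a knowledge seed,
the choices made where the design was genuinely open, and what the
synthetic fixtures do and do not establish.

## Configuration model and vocabulary

A seed is configured by two artifacts: a JSON properties document (name,
version, description, environment, instance namespace, CURIE prefixes,
ontology imports) and an RDF setup graph (RDF/XML or Turtle in; Turtle
out by default) declaring entities, concepts, resources, bridges and
selectors as individuals of the internal vocabulary
(`http://kbseed.dev/ontology#`, prefix `kb`).

The vocabulary defines ten classes (`Seed`, `Entity`, `Concept`, `Item`,
`Resource`, the four connector specialisations `CSV`/`XML`/`SQL`/`SPARQL`,
and `Bridge`) and the predicates that wire them. Three inverse pairs are
*registered*: `includes`/`isIncludedIn`, `isEntityOf`/`hasEntity`,
`isConceptOf`/`hasConcept` (plus `hasResource`/`isResourceOf`);
`isAssociatedTo` is symmetric. All mirrored directions are materialised at
write time rather than inferred at query time, because the triple-pattern
REST grammar matches stored triples only and no reasoner is part of the
stack. Two predicates were added where the tree needed links the core set
does not name: `hasBridge` (concept → bridge) and `pattern` (a bridge's
URL template); `sourceQuery` holds the SQL/SPARQL query text of a
resource, and `order`/`isKey` make resource priority and key-selector
designation explicit in the graph. The model deliberately preserves any
unknown extra predicate on any individual verbatim (an open `extra` map),
since downstream applications are expected to annotate the tree with
their own terms.

**Key-selector designation.** The setup dialect never forces an explicit
key marker: when no selector carries `kb:isKey true`, the selector whose
properties include `dc:identifier` becomes the key. This matches the
common configuration where the identifier column is mapped to
`dc:identifier` anyway.

**Selector ordering.** RDF graphs are unordered, so selector list order is
made explicit with an integer `kb:order` per selector individual; absent
orders fall back to local-name sort. Property lists within a selector are
sets in RDF and are therefore normalised (sorted) on parse; round-trip
identity holds up to that normalisation.

## Dependency ordering

Resources run in topological order of a dependency graph; ties are broken
by `(order, key)` ascending (order defaults to 0). The predecessors of a
resource extending concept K are the resources *of* concept K whose method
is not `map`: a cache resource creates K's items and a complete resource
enriches them, but a map resource only links existing items and can never
make an item appear. Excluding maps as feeders matters — two map
resources that share a source concept would otherwise each require the
other to run first, a guaranteed false cycle. A map resource additionally
runs after the feeders of its own source concept, since both link ends
must exist before linking. Genuine cycles (e.g. two complete resources
extending each other's concepts) are detected and reported with the cycle
members.

## Connectors and the record layer

Every connector reduces its source to the same intermediate form: an
ordered list of records, each mapping selector position to a list of typed
values (`literal`/`uri`). This is the abstraction layer that makes the
triplification method independent of the source kind, and it is tested as
such: the same logical table loaded as CSV, XML, SQL and SPARQL yields
value-identical record sets.

* **CSV** — RFC-4180-style, comma-separated, double-quote quoting, UTF-8
  with BOM stripped; selector queries are 0-based column indices. A first
  header row is skipped when the resource carries the open property
  `kb:header "true"` (gene-list exports typically have one). Rows
  narrower than the largest requested index are skipped and reported in a
  skip list — record count plus skip count always equals source row
  count.
* **XML** — XPath 1.0 over lxml. The record node set is selected by the
  open property `kb:recordPath`; absent, the document root is the single
  record. Selector XPaths are evaluated relative to each record node and
  may yield several values in document order. Element results contribute
  their text content.
* **SQL** — a connection URI (`sqlite://<path>`; the `jdbc:` prefix is
  tolerated) plus a `kb:sourceQuery`; selectors name result columns. SQL
  `NULL` becomes an empty value list, never the string `"None"`.
* **SPARQL** — a `kb:sourceQuery` SELECT sent to the endpoint over the
  standard protocol (form-encoded POST, results as SPARQL-results-JSON);
  selectors name result variables. Unbound variables yield empty lists;
  URI bindings keep their term kind, so triplification can replicate
  object properties instead of flattening them to literals.

HTTP fetches use a per-build cache (URI → content) so that per-item
completion fetches are replayable; there are no retries; timeouts are
configurable (default 15 s). Declared `Content-Length` is checked against
the bytes read — a mismatch raises rather than silently truncating.

## Triplification

Each record with a nonempty key value becomes an item map: identifier
plus a predicate→values multimap built as the cross-product of every
selector's properties and values. Writing an item adds four structural
triples — `rdf:type kb:Item`, `kb:hasConcept` (with its materialised
`kb:isConceptOf` mirror) and `rdfs:label` — plus one triple per
(predicate, value) pair. The label rule is *concept label + space +
identifier* unless a selector maps `rdfs:label` explicitly, in which case
the explicit value wins. Objects are plain literals for CSV/XML/SQL
values unless the target predicate is a registered object property; SPARQL
values keep their original term kind. The store has set semantics, so
re-triplifying an item (or rebuilding a seed) adds nothing: builds are
idempotent up to graph isomorphism.

Item URIs are minted as `namespace + lowercase(concept) + "_" +
percent-encoded(identifier)` (unreserved characters kept, everything else
encoded, so `HGNC:1101` → `hgnc_HGNC%3A1101`). Encoding is injective for
a fixed concept, but lowercasing concept keys is not; a per-build minting
registry raises on any collision instead of silently merging.

For `complete` without a `#replace#` token, the single fetched record set
is joined to existing items by key-selector value equality — this is what
lets one file complete many items. With the token, one fetch per item is
made and every record of that fetch appends to that item. Completion
never creates items. For `map`, the key selector identifies the source
item and the target is the non-key selector whose properties carry the
reserved `kb:isAssociatedTo` marker; records referencing a missing item on
either end are logged skips. Resource-level failures never abort a build:
the failed resource is marked in the report and the rest proceed; the
build's `ok` flag reflects any failure.

## Access layer

Four read paths see one store and are tested to agree statement-for-
statement:

* the triple-pattern grammar `{sub}/{pred}/{obj}/{format}` with positional
  wildcards (`sub`/`s`, `pred`/`p`, `obj`/`o` — both spellings accepted,
  but only in their own position) and formats `csv`, `js`
  (SPARQL-results-JSON), `xml`/`rdf` (RDF/XML), `html` (a minimal table);
* the read-only SPARQL endpoint (`query` + `output` parameters; update
  forms are rejected before execution; absent `output` defaults to
  SPARQL-results-XML — a convention this package fixes, since either
  default is defensible);
* LinkedData views (`/resource/{localname}`, content-negotiated RDF/HTML),
  limited to statements where the resource is the *subject*; inbound
  references are reachable via an object-bound triple pattern instead;
* bridges, which substitute `#replace#` in a per-concept URL template.

The HTTP façade is a threading standard-library server: adequate for
embedded use, test endpoints and small deployments; it makes no
performance claims.

## Federation

A federated SELECT is executed by nested-loop binding propagation in
SERVICE-clause order: each clause is sent to its endpoint as a standalone
sub-SELECT with a `VALUES` block injecting the bindings accumulated so far
over the shared variables, and solutions are joined back in. Plain
patterns outside SERVICE run on the local store in sequence. This is
deliberately non-optimising — clause order is execution order, which is
the intended authoring model for few-endpoint chains — and it is verified
against the oracle of running the de-federated query over the union of
all endpoint graphs. Blank nodes cannot be transported between endpoints
and are dropped from `VALUES`; unreachable endpoints raise naming the
endpoint rather than returning silent partial results.

## Synthetic fixtures

The fixture generator produces a deterministic synthetic world (same spec
and seed → byte-identical files): diseases with 6-digit numbers, genes as
`HGNC:<n>` ids with symbols, proteins as `[OPQ][0-9A-Z]{5}` accessions,
and per-protein cross-references in PDB/PROSITE/InterPro/PharmGKB/MeSH
shapes. Identifier shapes are realistic so URI sanitisation paths are
exercised; all values are invented. Defaults — 4 diseases, 1–3 genes
each, 1–2 proteins per gene, 1–3 cross-references per protein and target
— are sized so every concept receives items and every join fires while a
full build stays under a second.

The flagship bundle chains eleven concepts (OMIM-, Orphanet-, HGNC-,
Entrez-, UniProt-, PDB-, PROSITE-, InterPro-, PharmGKB-, PubMed- and
MeSH-style) across all four connector kinds and all three methods,
including a per-item XML completion and a loopback HTTP SPARQL source.
Its manifest predicts per-resource record counts, per-concept item counts
and per-map link counts by closed-form bookkeeping over the generated
world, and builds are checked against it exactly. A separate federation
fixture replicates the three-endpoint topology (labels / gene→protein
links / protein→structure+descriptor links).

What passing these fixtures shows: the declarative pipeline is internally
consistent — connectors are interchangeable, counts obey the statement
law, builds are idempotent and ordered correctly, interfaces agree, and
federation equals union-graph semantics. What it does not show: behaviour
against the real services' quirks (rate limits, malformed exports,
encoding surprises, schema drift) or storage performance at
millions-of-triples scale; both are out of scope here.

## Numerical and degenerate-input choices

Empty CSV cells, SQL NULLs and unbound SPARQL variables all yield empty
value lists (and an empty key value skips the record, counted). Empty
sources build cleanly to zero items. A model with zero resources still
writes the configuration tree (seed, entities, concepts, inverse links)
into the store. Ties everywhere are broken deterministically: resource
order by `(order, key)`, selector order by explicit index, generated
identifiers by a seeded RNG. Timeouts, the CSV dialect and the XML record
path are per-resource configuration, not globals.
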