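"""Integration engine: turn record sets into triples.

Each record with a nonempty key value becomes (or enriches) an *item*, the
leaf of the Entity→Concept→Item tree.  Items get a deterministic URI minted
from their concept and identifier, a small set of structural triples (type,
concept membership both ways, label) and one property triple per
(predicate, value) pair the selectors produced.  Three methods drive how a
resource contributes:

``cache``
    create new items from scratch (the default);
``complete``
    append properties to items that already exist in the extended concept,
    either via one per-item fetch (``#replace#`` in the endpoint) or by
    joining a single fetch on the key-selector value;
``map``
    link existing items of two concepts with ``isAssociatedTo``, creating
    no items and no literal properties.
"""

from __future__ import annotations

import json
import time
import urllib.parse
from dataclasses import dataclass, field

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS

from .connectors import (
    CsvDialect,
    FetchSpec,
    fetch,
    resolve_endpoint,
    select_records,
)
from .errors import BuildError, KbseedError, ValidationError
from .model import (
    REPLACE_TOKEN,
    ResourceDef,
    SeedModel,
    build_dependency_order,
    validate_model,
)
from .records import RecordSet, Term
from .setup_io import resolve_curie, setup_graph
from .vocab import VOCAB, Vocabulary

#: structural triples written per new item: type, hasConcept, isConceptOf, label
STRUCTURAL_TRIPLES_PER_ITEM = 4


class KnowledgeBase:
    """The seed triple store: an rdflib graph with set semantics plus
    write-time materialization of registered inverse and symmetric
    predicates, so the plain triple-pattern API sees both directions."""

    def __init__(self, instance_ns: str = "http://localhost/seed/",
                 prefixes: dict[str, str] | None = None,
                 vocab: Vocabulary = VOCAB,
                 graph: Graph | None = None):
        self.vocab = vocab
        self.instance_ns = instance_ns
        self.prefixes = dict(prefixes or {})
        self.graph = graph if graph is not None else Graph()
        self.graph.bind("seed", instance_ns, replace=True)
        self.graph.bind("kb", str(vocab.namespace), replace=True)
        for pfx, uri in self.prefixes.items():
            self.graph.bind(pfx, uri, replace=True)

    @classmethod
    def for_model(cls, model: SeedModel, vocab: Vocabulary = VOCAB) -> "KnowledgeBase":
        return cls(instance_ns=model.config.base_namespace,
                   prefixes=model.prefix_map(), vocab=vocab)

    @classmethod
    def wrap(cls, graph: Graph, instance_ns: str = "http://localhost/seed/",
             vocab: Vocabulary = VOCAB) -> "KnowledgeBase":
        return cls(instance_ns=instance_ns, vocab=vocab, graph=graph)

    def __len__(self) -> int:
        return len(self.graph)

    def add(self, subject: URIRef, predicate: URIRef, obj) -> int:
        """Insert a statement (and its mirror for inverse/symmetric
        predicates); return the number of statements actually new."""
        added = 0
        for triple in self._expand(subject, predicate, obj):
            if triple not in self.graph:
                self.graph.add(triple)
                added += 1
        return added

    def _expand(self, s, p, o):
        yield (s, p, o)
        if isinstance(o, URIRef):
            inv = self.vocab.inverse_of(p)
            if inv is not None:
                yield (o, inv, s)
            if p in self.vocab.symmetric:
                yield (o, p, s)

    def triples(self, pattern):
        return self.graph.triples(pattern)

    def query(self, sparql: str, **kw):
        return self.graph.query(sparql, **kw)

    def serialize(self, format: str = "turtle") -> str:
        fmt = {"turtle": "turtle", "ttl": "turtle",
               "rdfxml": "pretty-xml", "xml": "pretty-xml"}[format]
        return self.graph.serialize(format=fmt)


def mint_item_uri(concept_key: str, item_id: str, namespace: str) -> str:
    """Deterministic item URI: ``namespace + lowercase(concept) + "_" +
    percent-encoded(identifier)``.

    >>> mint_item_uri("UniProt", "P51587", "http://x/")
    'http://x/uniprot_P51587'
    """
    if not item_id:
        raise BuildError("cannot mint a URI for an empty item identifier")
    return namespace + concept_key.lower() + "_" + urllib.parse.quote(
        item_id, safe="")


def item_id_from_uri(uri: str, concept_key: str, namespace: str) -> str:
    """Recover the identifier a minted item URI encodes."""
    prefix = namespace + concept_key.lower() + "_"
    if not uri.startswith(prefix):
        raise BuildError(f"{uri} is not an item URI of concept {concept_key!r}")
    return urllib.parse.unquote(uri[len(prefix):])


@dataclass
class ItemMap:
    """The model-independent network built for one new item before
    statement generation: identifier plus a predicate→values multimap."""

    identifier: str
    concept_key: str
    properties: dict[str, list[Term]] = field(default_factory=dict)

    def add(self, predicate_curie: str, term: Term) -> None:
        self.properties.setdefault(predicate_curie, []).append(term)

    @property
    def pair_count(self) -> int:
        return sum(len(v) for v in self.properties.values())


@dataclass
class ReportFragment:
    resource: str
    method: str
    records_seen: int = 0
    items_created: int = 0
    statements_added: int = 0
    links_created: int = 0
    skips: int = 0
    errors: list[str] = field(default_factory=list)
    failed: bool = False


@dataclass
class BuildReport:
    order: list[str] = field(default_factory=list)
    fragments: list[ReportFragment] = field(default_factory=list)
    structural_statements: int = 0
    seconds: float = 0.0

    @property
    def total_statements(self) -> int:
        return self.structural_statements + sum(
            f.statements_added for f in self.fragments)

    @property
    def total_items(self) -> int:
        return sum(f.items_created for f in self.fragments)

    @property
    def ok(self) -> bool:
        return not any(f.failed for f in self.fragments)

    def to_json(self) -> str:
        return json.dumps({
            "order": self.order,
            "ok": self.ok,
            "structural_statements": self.structural_statements,
            "total_statements": self.total_statements,
            "total_items": self.total_items,
            "seconds": round(self.seconds, 3),
            "resources": [vars(f) for f in self.fragments],
        }, indent=2)


def make_item_maps(records: RecordSet, resource: ResourceDef
                   ) -> tuple[list[ItemMap], int]:
    """Build one :class:`ItemMap` per record with a nonempty key value.

    Every selector contributes the cross-product of its properties and its
    values; records lacking a key value are counted as skips.  Returns
    ``(item_maps, skipped)``.
    """
    key_idx = next((i for i, s in enumerate(resource.selectors) if s.is_key),
                   None)
    if key_idx is None:
        raise BuildError(f"resource {resource.key!r} has no key selector")
    items: list[ItemMap] = []
    skipped = 0
    for record in records.records:
        key_values = record.get(key_idx, [])
        if not key_values:
            skipped += 1
            continue
        item = ItemMap(identifier=key_values[0].text,
                       concept_key=resource.concept_key)
        for i, sel in enumerate(resource.selectors):
            for prop in sel.properties:
                for term in record.get(i, []):
                    item.add(prop, term)
        items.append(item)
    return items, skipped


def _object_node(term: Term, predicate: URIRef, vocab: Vocabulary):
    if term.kind == "uri" or predicate in vocab.object_properties:
        return URIRef(term.text)
    return Literal(term.text)


def triplify(item: ItemMap, model: SeedModel, kb: KnowledgeBase,
             minted: dict[str, tuple[str, str]] | None = None) -> int:
    """Write one item's structural and property statements; return the
    number of statements actually new (set semantics)."""
    vocab = kb.vocab
    ns = model.config.base_namespace
    concept = model.concepts.get(item.concept_key)
    if concept is None:
        raise BuildError(f"unknown concept {item.concept_key!r}")
    subject = URIRef(mint_item_uri(item.concept_key, item.identifier, ns))
    if minted is not None:
        prior = minted.get(str(subject))
        if prior is not None and prior != (item.concept_key, item.identifier):
            raise BuildError(
                f"URI collision: {subject} minted for both {prior} and "
                f"{(item.concept_key, item.identifier)}")
        minted[str(subject)] = (item.concept_key, item.identifier)
    concept_uri = URIRef(ns + "concept_" + item.concept_key)
    prefixes = model.prefix_map()

    added = kb.add(subject, RDF.type, vocab.classes["Item"])
    added += kb.add(subject, vocab.predicates["hasConcept"], concept_uri)
    if "rdfs:label" not in item.properties:
        label = (concept.label or concept.key) + " " + item.identifier
        added += kb.add(subject, RDFS.label, Literal(label))
    for curie, terms in item.properties.items():
        try:
            predicate = resolve_curie(curie, prefixes)
        except KbseedError as exc:
            raise BuildError(
                f"unresolvable predicate {curie!r} on item "
                f"{item.identifier!r}: {exc}") from exc
        for term in terms:
            added += kb.add(subject, predicate, _object_node(term, predicate, vocab))
    return added


@dataclass
class BuildContext:
    """Per-run state shared by the method runners."""

    fetch_cache: dict = field(default_factory=dict)
    services: dict = field(default_factory=dict)
    minted: dict[str, tuple[str, str]] = field(default_factory=dict)
    timeout: float = 15.0


def _fetch_records(resource: ResourceDef, uri: str, ctx: BuildContext
                   ) -> RecordSet:
    spec = FetchSpec(uri=uri, kind=resource.kind,
                     query_text=resource.query_text or None)
    raw = fetch(spec, cache=ctx.fetch_cache, services=ctx.services,
                timeout=ctx.timeout)
    dialect = CsvDialect(header=resource.has_header)
    return select_records(resource.kind, raw, resource.selectors,
                          dialect=dialect, record_path=resource.record_path,
                          source_uri=uri)


def _item_exists(kb: KnowledgeBase, uri: URIRef) -> bool:
    return (uri, RDF.type, kb.vocab.classes["Item"]) in kb.graph


def _concept_items(kb: KnowledgeBase, model: SeedModel, concept_key: str
                   ) -> list[URIRef]:
    concept_uri = URIRef(model.config.base_namespace + "concept_" + concept_key)
    return sorted(kb.graph.subjects(kb.vocab.predicates["hasConcept"],
                                    concept_uri, unique=True), key=str)


def run_cache(resource: ResourceDef, model: SeedModel, kb: KnowledgeBase,
              ctx: BuildContext | None = None) -> ReportFragment:
    """Load new items from scratch: fetch → select → item maps → triplify."""
    ctx = ctx or BuildContext()
    frag = ReportFragment(resource=resource.key, method="cache")
    records = _fetch_records(resource, resource.endpoint, ctx)
    frag.records_seen = len(records)
    frag.skips += len(records.skips)
    items, skipped = make_item_maps(records, resource)
    frag.skips += skipped
    ns = model.config.base_namespace
    for item in items:
        uri = URIRef(mint_item_uri(item.concept_key, item.identifier, ns))
        new_item = not _item_exists(kb, uri)
        frag.statements_added += triplify(item, model, kb, minted=ctx.minted)
        if new_item:
            frag.items_created += 1
    return frag


def run_complete(resource: ResourceDef, model: SeedModel, kb: KnowledgeBase,
                 ctx: BuildContext | None = None) -> ReportFragment:
    """Append property statements to existing items of the extended concept;
    never creates items."""
    ctx = ctx or BuildContext()
    frag = ReportFragment(resource=resource.key, method="complete")
    assert resource.extends_key, "complete resource without extends"
    items = _concept_items(kb, model, resource.extends_key)
    ns = model.config.base_namespace
    prefixes = model.prefix_map()

    if REPLACE_TOKEN in resource.endpoint:
        # one fetch per existing item
        for item_uri in items:
            item_id = item_id_from_uri(str(item_uri), resource.extends_key, ns)
            uri = resolve_endpoint(resource.endpoint, item_id)
            try:
                records = _fetch_records(resource, uri, ctx)
            except KbseedError as exc:
                frag.errors.append(f"{item_id}: {exc}")
                frag.skips += 1
                continue
            frag.records_seen += len(records)
            frag.skips += len(records.skips)
            for record in records.records:
                frag.statements_added += _append_record(
                    record, resource, item_uri, kb, prefixes)
    else:
        # single fetch, joined to items by key-selector value
        records = _fetch_records(resource, resource.endpoint, ctx)
        frag.records_seen = len(records)
        frag.skips += len(records.skips)
        key_idx = next((i for i, s in enumerate(resource.selectors)
                        if s.is_key), None)
        if key_idx is None:
            raise BuildError(f"resource {resource.key!r} has no key selector")
        by_id: dict[str, list[dict]] = {}
        for record in records.records:
            values = record.get(key_idx, [])
            if not values:
                frag.skips += 1
                continue
            by_id.setdefault(values[0].text, []).append(record)
        for item_uri in items:
            item_id = item_id_from_uri(str(item_uri), resource.extends_key, ns)
            for record in by_id.get(item_id, []):
                frag.statements_added += _append_record(
                    record, resource, item_uri, kb, prefixes)
    return frag


def _append_record(record: dict[int, list[Term]], resource: ResourceDef,
                   subject: URIRef, kb: KnowledgeBase,
                   prefixes: dict[str, str]) -> int:
    added = 0
    for i, sel in enumerate(resource.selectors):
        for prop in sel.properties:
            predicate = resolve_curie(prop, prefixes)
            for term in record.get(i, []):
                added += kb.add(subject, predicate,
                                _object_node(term, predicate, kb.vocab))
    return added


def run_map(resource: ResourceDef, model: SeedModel, kb: KnowledgeBase,
            ctx: BuildContext | None = None) -> ReportFragment:
    """Link existing items of the resource's concept to existing items of
    the extended concept with ``isAssociatedTo`` (materialised both ways)."""
    ctx = ctx or BuildContext()
    frag = ReportFragment(resource=resource.key, method="map")
    assert resource.extends_key, "map resource without extends"
    prefixes = model.prefix_map()
    assoc = kb.vocab.predicates["isAssociatedTo"]
    key_idx = next((i for i, s in enumerate(resource.selectors) if s.is_key),
                   None)
    if key_idx is None:
        raise BuildError(f"resource {resource.key!r} has no key selector")
    target_idx = None
    for i, sel in enumerate(resource.selectors):
        if sel.is_key:
            continue
        if any(resolve_curie(p, prefixes) == assoc for p in sel.properties):
            target_idx = i
    if target_idx is None:
        raise BuildError(
            f"map resource {resource.key!r} has no target selector (a "
            "non-key selector carrying the isAssociatedTo marker)")

    records = _fetch_records(resource, resource.endpoint, ctx)
    frag.records_seen = len(records)
    frag.skips += len(records.skips)
    ns = model.config.base_namespace
    for record in records.records:
        src_vals = record.get(key_idx, [])
        tgt_vals = record.get(target_idx, [])
        if not src_vals or not tgt_vals:
            frag.skips += 1
            continue
        src = URIRef(mint_item_uri(resource.concept_key, src_vals[0].text, ns))
        for tgt_term in tgt_vals:
            tgt = URIRef(mint_item_uri(resource.extends_key, tgt_term.text, ns))
            if not _item_exists(kb, src) or not _item_exists(kb, tgt):
                frag.skips += 1
                frag.errors.append(
                    f"link {src_vals[0].text!r} -> {tgt_term.text!r} "
                    "references a missing item")
                continue
            added = kb.add(src, assoc, tgt)
            frag.statements_added += added
            if added:
                frag.links_created += 1
    return frag


_RUNNERS = {"cache": run_cache, "complete": run_complete, "map": run_map}


def write_structure(model: SeedModel, kb: KnowledgeBase) -> int:
    """Write the seed/entity/concept/resource configuration triples into the
    store (with inverse materialization); returns new-statement count."""
    added = 0
    for s, p, o in setup_graph(model, kb.vocab):
        added += kb.add(s, p, o)
    return added


def build_seed(model: SeedModel, kb: KnowledgeBase,
               ctx: BuildContext | None = None) -> BuildReport:
    """Run every resource in dependency order against *kb*.

    Structural triples (the configuration tree itself) are written before
    any resource runs.  A resource failure marks its fragment failed and the
    build continues with the remaining resources.
    """
    t0 = time.perf_counter()
    ctx = ctx or BuildContext()
    problems = [v for v in validate_model(model) if v.severity == "error"]
    if problems:
        raise ValidationError(
            "model is invalid:\n" + "\n".join(str(v) for v in problems))
    report = BuildReport(order=build_dependency_order(model))
    report.structural_statements = write_structure(model, kb)
    for key in report.order:
        resource = model.resources[key]
        runner = _RUNNERS[resource.method]
        try:
            frag = runner(resource, model, kb, ctx)
        except KbseedError as exc:
            frag = ReportFragment(resource=key, method=resource.method,
                                  failed=True, errors=[str(exc)])
        report.fragments.append(frag)
    report.seconds = time.perf_counter() - t0
    return report


def audit_concept_membership(kb: KnowledgeBase) -> list[str]:
    """Check that every Item has exactly one ``hasConcept`` and that the
    concept mirrors it with ``isConceptOf``; returns violation messages."""
    problems: list[str] = []
    has_concept = kb.vocab.predicates["hasConcept"]
    is_concept_of = kb.vocab.predicates["isConceptOf"]
    for item in kb.graph.subjects(RDF.type, kb.vocab.classes["Item"], unique=True):
        concepts = list(kb.graph.objects(item, has_concept))
        if len(concepts) != 1:
            problems.append(f"{item} has {len(concepts)} concepts")
            continue
        if (concepts[0], is_concept_of, item) not in kb.graph:
            problems.append(f"{concepts[0]} does not mirror isConceptOf {item}")
    return problems
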