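"""Parse and serialize the setup graph (entities, concepts, resources,
bridges) between RDF documents and :class:`~kbseed.model.SeedModel`.

RDF/XML and Turtle are accepted on input; output defaults to Turtle.
``parse_setup(serialize_model(m), m.config)`` is the identity on valid
models, key by key.
"""

from __future__ import annotations

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DC, RDF, RDFS, XSD

from .errors import SetupError
from .model import (
    BridgeDef,
    ConceptDef,
    EntityDef,
    ResourceDef,
    SeedConfig,
    SeedModel,
    Selector,
    apply_key_selector_default,
)
from .vocab import VOCAB, Vocabulary

_TYPE_PREFIXES = {
    "Entity": "entity_",
    "Concept": "concept_",
    "Resource": "resource_",
    "Bridge": "bridge_",
}

#: predicates handled structurally during parse (everything else is "extra")
_KNOWN_PREDICATES = {
    RDF.type,
    RDFS.label,
    DC.publisher,
}


def resolve_curie(token: str, prefixes: dict[str, str]) -> URIRef:
    """Resolve a CURIE or absolute URI (optionally ``<>``-wrapped) to a URIRef."""
    if token.startswith("<") and token.endswith(">"):
        return URIRef(token[1:-1])
    if "://" in token or token.startswith("urn:"):
        return URIRef(token)
    if ":" in token:
        pfx, local = token.split(":", 1)
        if pfx in prefixes:
            return URIRef(prefixes[pfx] + local)
        raise SetupError(f"unknown CURIE prefix {pfx!r} in {token!r}")
    raise SetupError(f"not a CURIE or absolute URI: {token!r}")


def contract_uri(uri: URIRef, prefixes: dict[str, str]) -> str:
    """Contract a URI to a CURIE when a prefix matches (longest wins)."""
    best: tuple[int, str] | None = None
    for pfx, ns in prefixes.items():
        if str(uri).startswith(ns) and (best is None or len(ns) > best[0]):
            best = (len(ns), f"{pfx}:{str(uri)[len(ns):]}")
    return best[1] if best else str(uri)


def _local_name(uri: URIRef, namespace: str) -> str:
    s = str(uri)
    if s.startswith(namespace):
        return s[len(namespace):]
    # fall back to fragment / last path segment
    for sep in ("#", "/"):
        if sep in s:
            return s.rsplit(sep, 1)[1]
    return s


def _strip(local: str, kind: str) -> str:
    prefix = _TYPE_PREFIXES.get(kind, "")
    return local[len(prefix):] if prefix and local.startswith(prefix) else local


def _object_text(graph: Graph, subject, predicate) -> str:
    value = graph.value(subject, predicate)
    return str(value) if value is not None else ""


def parse_setup(setup_document: str, config: SeedConfig,
                vocab: Vocabulary = VOCAB) -> SeedModel:
    """Parse a setup document into a :class:`SeedModel`.

    Individuals typed by a class that lives in the internal ontology
    namespace but is not part of the vocabulary raise :class:`SetupError`.
    Dangling cross-references are kept verbatim in the model so that
    ``validate_model`` can report them; nothing is silently dropped.
    """
    graph = Graph()
    fmt = "xml" if setup_document.lstrip().startswith("<") else "turtle"
    try:
        graph.parse(data=setup_document, format=fmt)
    except Exception as exc:  # rdflib raises several parser exception types
        raise SetupError(f"malformed {fmt} setup document: {exc}") from exc

    ns = config.base_namespace
    model = SeedModel(config=config)
    prefixes = model.prefix_map()
    class_uris = {uri: name for name, uri in vocab.classes.items()}
    known_class_uris = set(class_uris)

    # reject individuals typed by an unknown class of the internal namespace
    for s, o in graph.subject_objects(RDF.type):
        if str(o).startswith(str(vocab.namespace)) and o not in known_class_uris:
            raise SetupError(f"individual {s} typed by unknown class {o}")

    selectors_by_uri: dict[URIRef, Selector] = {}
    selector_order: dict[URIRef, int] = {}
    kind_class_uris = set(vocab.kind_classes.values())

    for s in set(graph.subjects(RDF.type, None)):
        types = set(graph.objects(s, RDF.type))
        if types & kind_class_uris and vocab.classes["Resource"] not in types:
            # connector-kind individual that is not a Resource => selector
            props = [contract_uri(o, prefixes) if isinstance(o, URIRef)
                     else str(o)
                     for o in graph.objects(s, vocab.predicates["property"])]
            props.sort()
            is_key = str(graph.value(s, vocab.predicates["isKey"]) or "") == "true"
            sel = Selector(
                query=_object_text(graph, s, vocab.predicates["query"]),
                properties=props,
                is_key=is_key,
                key=_local_name(s, ns),
            )
            selectors_by_uri[s] = sel
            order_val = graph.value(s, vocab.predicates["order"])
            selector_order[s] = int(order_val) if order_val is not None else 0

    def extras_for(s, skip: set) -> dict[str, list[str]]:
        extra: dict[str, list[str]] = {}
        for p, o in graph.predicate_objects(s):
            if p in skip or p in _KNOWN_PREDICATES or p in vocab.predicates.values():
                continue
            curie = contract_uri(p, prefixes)
            text = f"<{o}>" if isinstance(o, URIRef) else str(o)
            extra.setdefault(curie, []).append(text)
        for vals in extra.values():
            vals.sort()
        return extra

    for s in graph.subjects(RDF.type, vocab.classes["Entity"]):
        key = _strip(_local_name(s, ns), "Entity")
        model.entities[key] = EntityDef(
            key=key,
            label=_object_text(graph, s, RDFS.label),
            concept_keys=sorted(
                _strip(_local_name(o, ns), "Concept")
                for o in graph.objects(s, vocab.predicates["isEntityOf"])
            ),
            extra=extras_for(s, set()),
        )

    for s in graph.subjects(RDF.type, vocab.classes["Concept"]):
        key = _strip(_local_name(s, ns), "Concept")
        entity = graph.value(s, vocab.predicates["hasEntity"])
        model.concepts[key] = ConceptDef(
            key=key,
            entity_key=_strip(_local_name(entity, ns), "Entity") if entity else "",
            label=_object_text(graph, s, RDFS.label),
            resource_refs=sorted(
                _strip(_local_name(o, ns), "Resource")
                for o in graph.objects(s, vocab.predicates["hasResource"])
            ),
            bridge_refs=sorted(
                _strip(_local_name(o, ns), "Bridge")
                for o in graph.objects(s, vocab.predicates["hasBridge"])
            ),
            extra=extras_for(s, set()),
        )

    for s in graph.subjects(RDF.type, vocab.classes["Resource"]):
        key = _strip(_local_name(s, ns), "Resource")
        kind = ""
        for token, cls in vocab.kind_classes.items():
            if (s, RDF.type, cls) in graph:
                kind = token
        sel_uris = list(graph.objects(s, vocab.predicates["loadsFrom"]))
        sel_uris.sort(key=lambda u: (selector_order.get(u, 0), str(u)))
        selectors = [selectors_by_uri[u] for u in sel_uris if u in selectors_by_uri]
        extends = graph.value(s, vocab.predicates["extends"])
        order_val = graph.value(s, vocab.predicates["order"])
        # concept link: prefer explicit isResourceOf, else the concept that
        # lists this resource via hasResource
        concept = graph.value(s, vocab.predicates["isResourceOf"])
        if concept is None:
            concept = graph.value(None, vocab.predicates["hasResource"], s)
        res = ResourceDef(
            key=key,
            kind=kind,
            concept_key=_strip(_local_name(concept, ns), "Concept") if concept else "",
            endpoint=_object_text(graph, s, vocab.predicates["endpoint"]),
            method=_object_text(graph, s, vocab.predicates["method"]) or "cache",
            connector_hint=_object_text(graph, s, DC.publisher),
            extends_key=_strip(_local_name(extends, ns), "Concept") if extends else None,
            selectors=selectors,
            order=int(order_val) if order_val is not None else 0,
            query_text=_object_text(graph, s, vocab.predicates["sourceQuery"]),
            extra=extras_for(s, set()),
        )
        apply_key_selector_default(res)
        model.resources[key] = res

    for s in graph.subjects(RDF.type, vocab.classes["Bridge"]):
        key = _strip(_local_name(s, ns), "Bridge")
        concept = graph.value(None, vocab.predicates["hasBridge"], s)
        model.bridges[key] = BridgeDef(
            key=key,
            concept_key=_strip(_local_name(concept, ns), "Concept") if concept else "",
            pattern=_object_text(graph, s, vocab.predicates["pattern"]),
            extra_properties=extras_for(s, set()),
        )

    return model


def setup_graph(model: SeedModel, vocab: Vocabulary = VOCAB) -> Graph:
    """Build the RDF graph for a model's setup (single direction, no
    inverse materialization — that happens at knowledge-base write time)."""
    g = Graph()
    ns = model.config.base_namespace
    prefixes = model.prefix_map()
    for pfx, uri in prefixes.items():
        g.bind(pfx, uri, replace=True)
    P = vocab.predicates
    C = vocab.classes

    def uri(kind: str, key: str) -> URIRef:
        return URIRef(ns + _TYPE_PREFIXES[kind.capitalize()] + key)

    def add_extras(s: URIRef, extra: dict[str, list[str]]) -> None:
        for curie, values in extra.items():
            p = resolve_curie(curie, prefixes)
            for v in values:
                if v.startswith("<") and v.endswith(">"):
                    g.add((s, p, URIRef(v[1:-1])))
                else:
                    g.add((s, p, Literal(v)))

    seed_uri = URIRef(ns + "seed")
    g.add((seed_uri, RDF.type, C["Seed"]))
    g.add((seed_uri, RDFS.label, Literal(model.config.name)))

    for ent in model.entities.values():
        s = uri("entity", ent.key)
        g.add((seed_uri, P["includes"], s))
        g.add((s, RDF.type, C["Entity"]))
        if ent.label:
            g.add((s, RDFS.label, Literal(ent.label)))
        for ck in ent.concept_keys:
            g.add((s, P["isEntityOf"], uri("concept", ck)))
        add_extras(s, ent.extra)

    for con in model.concepts.values():
        s = uri("concept", con.key)
        g.add((s, RDF.type, C["Concept"]))
        if con.label:
            g.add((s, RDFS.label, Literal(con.label)))
        if con.entity_key:
            g.add((s, P["hasEntity"], uri("entity", con.entity_key)))
        for rk in con.resource_refs:
            g.add((s, P["hasResource"], uri("resource", rk)))
        for bk in con.bridge_refs:
            g.add((s, P["hasBridge"], uri("bridge", bk)))
        add_extras(s, con.extra)

    for res in model.resources.values():
        s = uri("resource", res.key)
        g.add((s, RDF.type, C["Resource"]))
        if res.kind:
            g.add((s, RDF.type, vocab.kind_classes[res.kind]))
        g.add((s, P["method"], Literal(res.method)))
        if res.endpoint:
            g.add((s, P["endpoint"], Literal(res.endpoint)))
        if res.connector_hint:
            g.add((s, DC.publisher, Literal(res.connector_hint)))
        if res.extends_key:
            g.add((s, P["extends"], uri("concept", res.extends_key)))
        if res.order:
            g.add((s, P["order"], Literal(res.order, datatype=XSD.integer)))
        if res.query_text:
            g.add((s, P["sourceQuery"], Literal(res.query_text)))
        for i, sel in enumerate(res.selectors):
            local = sel.key or f"selector_{res.key}_{i}"
            sel.key = local
            su = URIRef(ns + local)
            g.add((s, P["loadsFrom"], su))
            g.add((su, RDF.type, vocab.kind_classes[res.kind or "csv"]))
            g.add((su, P["query"], Literal(sel.query)))
            g.add((su, P["order"], Literal(i, datatype=XSD.integer)))
            if sel.is_key:
                g.add((su, P["isKey"], Literal("true")))
            for prop in sel.properties:
                g.add((su, P["property"], resolve_curie(prop, prefixes)))
        add_extras(s, res.extra)

    for br in model.bridges.values():
        s = uri("bridge", br.key)
        g.add((s, RDF.type, C["Bridge"]))
        if br.pattern:
            g.add((s, P["pattern"], Literal(br.pattern)))
        add_extras(s, br.extra_properties)

    return g


def serialize_model(model: SeedModel, format: str = "turtle",
                    vocab: Vocabulary = VOCAB) -> str:
    """Serialize a model's setup graph as ``turtle`` (default) or ``rdfxml``."""
    fmt = {"turtle": "turtle", "ttl": "turtle", "rdfxml": "pretty-xml",
           "xml": "pretty-xml"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown serialization format {format!r}")
    return setup_graph(model, vocab).serialize(format=fmt)
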