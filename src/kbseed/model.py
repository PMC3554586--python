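"""Parsed seed configuration model: entities, concepts, resources, bridges.

The model mirrors the setup graph: a seed declares entities, each entity
groups concepts, each concept is fed by resources (one per external source)
and decorated by bridges.  ``validate_model`` checks the structural
invariants; ``build_dependency_order`` computes the order in which resources
must run so that ``complete`` and ``map`` resources find the items they
extend already in the store.
"""

from __future__ import annotations

import heapq
import json
import re
from dataclasses import dataclass, field
from typing import Iterable

from .errors import CycleError, ValidationError
from .vocab import ONTOLOGY_NS

KINDS = ("csv", "xml", "sql", "sparql")
METHODS = ("cache", "complete", "map")

_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:")

#: Token substituted with an item identifier in endpoint/bridge templates.
REPLACE_TOKEN = "#replace#"


@dataclass
class SeedConfig:
    """Instance-level properties, read from the JSON properties file."""

    name: str
    version: str = "0.0"
    description: str = ""
    environment: str = "development"
    base_namespace: str = "http://localhost/seed/"
    prefixes: dict[str, str] = field(default_factory=dict)
    ontology_imports: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("seed name must be nonempty")
        for pfx, uri in self.prefixes.items():
            if not _URI_RE.match(uri):
                raise ValidationError(
                    f"prefix {pfx!r} maps to a non-absolute URI: {uri!r}"
                )


def load_config(text: str) -> SeedConfig:
    """Parse the JSON instance-properties document (``config.js``)."""
    data = json.loads(text)
    return SeedConfig(
        name=data.get("name", ""),
        version=str(data.get("version", "0.0")),
        description=data.get("description", ""),
        environment=data.get("environment", "development"),
        base_namespace=data.get("namespace", data.get("base_namespace", "http://localhost/seed/")),
        prefixes=dict(data.get("prefixes", {})),
        ontology_imports=list(data.get("ontologies", data.get("ontology_imports", []))),
    )


@dataclass
class EntityDef:
    key: str
    label: str = ""
    concept_keys: list[str] = field(default_factory=list)
    extra: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class ConceptDef:
    key: str
    entity_key: str
    label: str = ""
    resource_refs: list[str] = field(default_factory=list)
    bridge_refs: list[str] = field(default_factory=list)
    extra: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class Selector:
    """One location-in-source and the predicates its values populate.

    ``query`` is a 0-based column index for CSV, an XPath for XML, a result
    column name for SQL and a variable name for SPARQL.  The selector with
    ``is_key`` yields the item identifier.
    """

    query: str
    properties: list[str]
    is_key: bool = False
    key: str = ""  # individual local name, minted if absent


@dataclass
class ResourceDef:
    """Configuration of one external source feeding one concept."""

    key: str
    kind: str  # csv | xml | sql | sparql
    concept_key: str
    endpoint: str = ""
    method: str = "cache"
    connector_hint: str = ""  # dc:publisher value
    extends_key: str | None = None
    selectors: list[Selector] = field(default_factory=list)
    order: int = 0
    query_text: str = ""  # SQL/SPARQL source query
    extra: dict[str, list[str]] = field(default_factory=dict)

    @property
    def key_selector(self) -> Selector | None:
        for sel in self.selectors:
            if sel.is_key:
                return sel
        return None

    @property
    def has_header(self) -> bool:
        """CSV open property ``kb:header`` — first row is a header row."""
        vals = self.extra.get("kb:header", [])
        return bool(vals) and vals[0].lower() in ("true", "1", "yes")

    @property
    def record_path(self) -> str | None:
        """XML open property ``kb:recordPath`` — XPath selecting record nodes."""
        vals = self.extra.get("kb:recordPath", [])
        return vals[0] if vals else None


@dataclass
class BridgeDef:
    """Per-concept URL template; ``#replace#`` is filled with item ids."""

    key: str
    concept_key: str
    pattern: str = ""
    extra_properties: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SeedModel:
    config: SeedConfig
    entities: dict[str, EntityDef] = field(default_factory=dict)
    concepts: dict[str, ConceptDef] = field(default_factory=dict)
    resources: dict[str, ResourceDef] = field(default_factory=dict)
    bridges: dict[str, BridgeDef] = field(default_factory=dict)

    def prefix_map(self) -> dict[str, str]:
        """CURIE prefix map including the default ``seed`` instance prefix."""
        prefixes = {
            "seed": self.config.base_namespace,
            "kb": str(ONTOLOGY_NS),
            "dc": "http://purl.org/dc/elements/1.1/",
            "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
            "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
        }
        prefixes.update(self.config.prefixes)
        return prefixes


@dataclass
class Violation:
    """One invariant violation: data, not an exception."""

    subject: str
    rule: str
    message: str
    severity: str = "error"  # error | warning

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.severity}] {self.subject}: {self.rule} — {self.message}"


def apply_key_selector_default(resource: ResourceDef) -> None:
    """Designate the key selector when none is flagged explicitly.

    The selector whose properties include ``dc:identifier`` becomes the key
    selector by default (that is the selector that carries the primary
    identifier in typical gene-list configurations).
    """
    if any(s.is_key for s in resource.selectors):
        return
    for sel in resource.selectors:
        if any(p.split("/")[-1].endswith("identifier") or p == "dc:identifier"
               for p in sel.properties):
            sel.is_key = True
            return


def validate_model(model: SeedModel) -> list[Violation]:
    """Check every structural invariant; violations are returned, not raised."""
    out: list[Violation] = []

    for ent in model.entities.values():
        for ck in ent.concept_keys:
            if ck not in model.concepts:
                out.append(Violation(ent.key, "entity-concept-ref",
                                     f"entity lists unknown concept {ck!r}"))
            elif model.concepts[ck].entity_key != ent.key:
                out.append(Violation(ent.key, "entity-concept-symmetry",
                                     f"concept {ck!r} does not point back to this entity"))

    for con in model.concepts.values():
        if not con.entity_key:
            out.append(Violation(con.key, "concept-entity-cardinality",
                                 "concept must have exactly one entity"))
        elif con.entity_key not in model.entities:
            out.append(Violation(con.key, "concept-entity-ref",
                                 f"concept names unknown entity {con.entity_key!r}"))
        elif con.key not in model.entities[con.entity_key].concept_keys:
            out.append(Violation(con.key, "concept-entity-symmetry",
                                 f"entity {con.entity_key!r} does not list this concept"))
        for rk in con.resource_refs:
            if rk not in model.resources:
                out.append(Violation(con.key, "concept-resource-ref",
                                     f"concept lists unknown resource {rk!r}"))
        for bk in con.bridge_refs:
            if bk not in model.bridges:
                out.append(Violation(con.key, "concept-bridge-ref",
                                     f"concept lists unknown bridge {bk!r}"))

    seen_endpoints: dict[tuple[str, str], set[str]] = {}
    for res in model.resources.values():
        if res.kind not in KINDS:
            out.append(Violation(res.key, "resource-kind",
                                 f"unknown connector kind {res.kind!r}"))
        if res.method not in METHODS:
            out.append(Violation(res.key, "resource-method",
                                 f"method must be one of {METHODS}, got {res.method!r}"))
        if res.method in ("complete", "map") and not res.extends_key:
            out.append(Violation(res.key, "extends-required",
                                 f"method {res.method!r} requires an extended concept"))
        if res.method == "cache" and res.extends_key:
            out.append(Violation(res.key, "extends-forbidden",
                                 "cache resources must not declare an extended concept"))
        if res.concept_key not in model.concepts:
            out.append(Violation(res.key, "resource-concept-ref",
                                 f"resource names unknown concept {res.concept_key!r}"))
        if res.extends_key and res.extends_key not in model.concepts:
            out.append(Violation(res.key, "resource-extends-ref",
                                 f"resource extends unknown concept {res.extends_key!r}"))
        n_key = sum(1 for s in res.selectors if s.is_key)
        if n_key != 1:
            out.append(Violation(res.key, "key-selector-cardinality",
                                 f"expected exactly 1 key selector, found {n_key}"))
        for i, sel in enumerate(res.selectors):
            if not sel.properties:
                out.append(Violation(res.key, "selector-properties",
                                     f"selector #{i} has an empty property list"))
            if res.kind == "csv":
                try:
                    if int(sel.query) < 0:
                        raise ValueError
                except (TypeError, ValueError):
                    out.append(Violation(res.key, "csv-column-index",
                                         f"selector #{i} query {sel.query!r} is not a "
                                         "non-negative column index"))
        if res.kind in ("sql", "sparql") and not res.query_text:
            out.append(Violation(res.key, "source-query-required",
                                 f"{res.kind} resources need a source query"))
        # mixed methods against the same endpoint on one concept: warn only
        ep_key = (res.concept_key, res.endpoint)
        seen_endpoints.setdefault(ep_key, set()).add(res.method)

    for (concept_key, endpoint), methods in seen_endpoints.items():
        if endpoint and len(methods) > 1:
            out.append(Violation(concept_key, "mixed-method-endpoint",
                                 f"concept has resources with methods {sorted(methods)} "
                                 f"against the same endpoint {endpoint!r}",
                                 severity="warning"))

    for br in model.bridges.values():
        if br.concept_key not in model.concepts:
            out.append(Violation(br.key, "bridge-concept-ref",
                                 f"bridge names unknown concept {br.concept_key!r}"))
    return out


def dependency_edges(model: SeedModel) -> dict[str, set[str]]:
    """Map resource key -> set of resource keys that must run before it.

    A resource that extends concept K runs after every resource that feeds
    K; a map resource additionally runs after the feeders of its own
    (source) concept, since both link ends must already exist.  Feeders of a
    concept are the non-map resources attached to it (cache creates its
    items, complete enriches them).  Map resources feed nothing — they only
    link existing items — so they are never predecessors; otherwise two
    maps sharing a concept would deadlock.
    """

    def feeds(res: ResourceDef, concept: str) -> bool:
        return res.method != "map" and res.concept_key == concept

    edges: dict[str, set[str]] = {k: set() for k in model.resources}
    for res in model.resources.values():
        feeder_concepts = set()
        if res.extends_key:
            feeder_concepts.add(res.extends_key)
        if res.method == "map":
            feeder_concepts.add(res.concept_key)
        for other in model.resources.values():
            if other.key != res.key and any(
                    feeds(other, c) for c in feeder_concepts):
                edges[res.key].add(other.key)
    return edges


def build_dependency_order(model: SeedModel) -> list[str]:
    """Topologically order resources; ties broken by (order, key) ascending.

    Raises :class:`CycleError` listing the members of any dependency cycle.
    """
    edges = dependency_edges(model)
    indegree = {k: len(v) for k, v in edges.items()}
    dependents: dict[str, set[str]] = {k: set() for k in edges}
    for k, preds in edges.items():
        for p in preds:
            dependents[p].add(k)

    heap = [(model.resources[k].order, k) for k, d in indegree.items() if d == 0]
    heapq.heapify(heap)
    out: list[str] = []
    while heap:
        _, k = heapq.heappop(heap)
        out.append(k)
        for dep in dependents[k]:
            indegree[dep] -= 1
            if indegree[dep] == 0:
                heapq.heappush(heap, (model.resources[dep].order, dep))
    if len(out) != len(edges):
        cycle = _find_cycle(edges, {k for k in edges if k not in out})
        raise CycleError(cycle)
    return out


def _find_cycle(edges: dict[str, set[str]], remaining: Iterable[str]) -> list[str]:
    remaining = set(remaining)
    start = min(remaining)
    path: list[str] = []
    seen: dict[str, int] = {}
    node = start
    while node not in seen:
        seen[node] = len(path)
        path.append(node)
        node = min(p for p in edges[node] if p in remaining)
    return path[seen[node]:]
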