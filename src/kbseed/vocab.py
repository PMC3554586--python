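"""Internal ontology vocabulary.

The knowledge base is organised as a tree: a Seed includes Entities (broad
categories such as "Protein"), an Entity groups Concepts (source-specific
types such as "UniProt"), and a Concept aggregates Items (individual records
such as "P51587").  Resources describe how to load items for a concept from
an external source, and Bridges describe how to build outbound URLs for
items.  This module defines the classes and predicates of that model and the
inverse pairs that are materialised at write time.
"""

from __future__ import annotations

from rdflib import Namespace, URIRef
from rdflib.namespace import DC, RDF, RDFS

#: Base namespace of the internal ontology.
ONTOLOGY_NS = Namespace("http://kbseed.dev/ontology#")

CLASS_NAMES = (
    "Seed",
    "Entity",
    "Concept",
    "Item",
    "Resource",
    "CSV",
    "XML",
    "SQL",
    "SPARQL",
    "Bridge",
)

PREDICATE_NAMES = (
    "includes",
    "isIncludedIn",
    "isEntityOf",
    "hasEntity",
    "isConceptOf",
    "hasConcept",
    "isAssociatedTo",
    "hasResource",
    "isResourceOf",
    "hasBridge",
    "loadsFrom",
    "extends",
    "method",
    "endpoint",
    "query",
    "property",
    "order",
    "isKey",
    "pattern",
    "sourceQuery",
)


class Vocabulary:
    """Classes, predicates and inverse pairs of the internal ontology.

    Imported terms (``dc:publisher``, ``dc:source``, ``dc:identifier``,
    ``rdfs:label``) are exposed alongside the native ones so that selector
    property CURIEs resolve uniformly.
    """

    def __init__(self, namespace: str | Namespace = ONTOLOGY_NS):
        self.namespace = Namespace(str(namespace))
        self.classes: dict[str, URIRef] = {n: self.namespace[n] for n in CLASS_NAMES}
        self.predicates: dict[str, URIRef] = {
            n: self.namespace[n] for n in PREDICATE_NAMES
        }
        # imported terms
        self.predicates["dc:publisher"] = DC.publisher
        self.predicates["dc:source"] = DC.source
        self.predicates["dc:identifier"] = DC.identifier
        self.predicates["rdfs:label"] = RDFS.label
        # registered inverse pairs, materialised both ways at write time
        self.inverse_pairs: tuple[tuple[URIRef, URIRef], ...] = (
            (self.predicates["includes"], self.predicates["isIncludedIn"]),
            (self.predicates["isEntityOf"], self.predicates["hasEntity"]),
            (self.predicates["isConceptOf"], self.predicates["hasConcept"]),
            (self.predicates["hasResource"], self.predicates["isResourceOf"]),
        )
        self._inverse: dict[URIRef, URIRef] = {}
        for a, b in self.inverse_pairs:
            self._inverse[a] = b
            self._inverse[b] = a
        #: symmetric predicates: adding (s,p,o) also adds (o,p,s)
        self.symmetric: frozenset[URIRef] = frozenset(
            {self.predicates["isAssociatedTo"]}
        )
        #: predicates whose objects are resources, never literals
        self.object_properties: frozenset[URIRef] = frozenset(
            set(self._inverse) | set(self.symmetric)
        )

    def inverse_of(self, predicate: URIRef) -> URIRef | None:
        """Return the registered inverse of *predicate*, or None."""
        return self._inverse.get(predicate)

    def term(self, name: str) -> URIRef:
        """Look up a class or predicate by bare name (classes first)."""
        if name in self.classes:
            return self.classes[name]
        if name in self.predicates:
            return self.predicates[name]
        raise KeyError(name)

    @property
    def kind_classes(self) -> dict[str, URIRef]:
        """Connector-kind specialisations of Resource, keyed by lowercase token."""
        return {k.lower(): self.classes[k] for k in ("CSV", "XML", "SQL", "SPARQL")}


#: Module-level default vocabulary instance.
VOCAB = Vocabulary()

RDF_TYPE = RDF.type
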