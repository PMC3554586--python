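"""Knowledge-base access layer: triple-pattern queries, the SPARQL
endpoint, LinkedData views and bridge URL resolution.

The triple-pattern service is the simplest entry point: a pattern is three
positional tokens (subject, predicate, object), each either a CURIE/URI/
literal or the positional wildcard for that slot (``sub``/``s``, ``pred``/
``p``, ``obj``/``o``), plus an output-format token.
"""

from __future__ import annotations

import csv
import html
import io
import json
import re
import urllib.parse
from dataclasses import dataclass

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDFS

from .engine import KnowledgeBase
from .errors import ClientError, SetupError
from .model import BridgeDef, REPLACE_TOKEN
from .records import Term
from .setup_io import resolve_curie
from .sparql_client import term_of

FORMAT_TOKENS = ("csv", "js", "xml", "rdf", "html")

_WILDCARDS = ({"sub", "s"}, {"pred", "p"}, {"obj", "o"})
_POSITION_NAMES = ("subject", "predicate", "object")


@dataclass
class TriplePattern:
    """A subject/predicate/object pattern; ``None`` marks a wildcard."""

    subject: URIRef | None
    predicate: URIRef | None
    object: URIRef | Literal | None

    def as_tuple(self):
        return (self.subject, self.predicate, self.object)


def _parse_term(token: str, position: int, prefixes: dict[str, str],
                allow_literal: bool):
    for pos, wild in enumerate(_WILDCARDS):
        if token in wild:
            if pos != position:
                raise ClientError(
                    f"wildcard {token!r} is only valid in "
                    f"{_POSITION_NAMES[pos]} position")
            return None
    if token.startswith("<") and token.endswith(">"):
        return URIRef(token[1:-1])
    if "://" in token or token.startswith("urn:"):
        return URIRef(token)
    if ":" in token:
        try:
            return resolve_curie(token, prefixes)
        except SetupError as exc:
            raise ClientError(str(exc)) from exc
    if allow_literal:
        return Literal(token)
    raise ClientError(
        f"{_POSITION_NAMES[position]} token {token!r} is neither a CURIE, "
        "a URI nor a positional wildcard")


def parse_pattern(sub: str, pred: str, obj: str,
                  prefixes: dict[str, str]) -> TriplePattern:
    return TriplePattern(
        subject=_parse_term(sub, 0, prefixes, allow_literal=False),
        predicate=_parse_term(pred, 1, prefixes, allow_literal=False),
        object=_parse_term(obj, 2, prefixes, allow_literal=True),
    )


def check_format(token: str) -> str:
    if token not in FORMAT_TOKENS:
        raise ClientError(
            f"unknown output format {token!r}; expected one of {FORMAT_TOKENS}")
    return token


def parse_triple_route(path: str, route_prefix: str = "/api/triple"
                       ) -> tuple[tuple[str, str, str], str]:
    """Split a REST path into raw pattern tokens and a validated format.

    Wrong segment count is a routing (404-class) error; a bad format token
    is a client (400-class) error.
    """
    clean = path.split("?", 1)[0]
    if not clean.startswith(route_prefix):
        raise ClientError(f"not a triple route: {path!r}", status=404)
    rest = clean[len(route_prefix):].strip("/")
    segments = [urllib.parse.unquote(s) for s in rest.split("/")] if rest else []
    if len(segments) != 4:
        raise ClientError(
            f"triple route needs exactly 4 segments "
            f"(sub/pred/obj/format), got {len(segments)}", status=404)
    sub, pred, obj, fmt = segments
    return (sub, pred, obj), check_format(fmt)


def _term_string(node) -> str:
    return str(node)


def _bindings_json(matches) -> str:
    bindings = []
    for s, p, o in matches:
        def enc(node):
            t = term_of(node)
            entry = {"type": t.kind if t.kind != "literal" else "literal",
                     "value": t.text}
            return entry
        bindings.append({"s": enc(s), "p": enc(p), "o": enc(o)})
    return json.dumps({"head": {"vars": ["s", "p", "o"]},
                       "results": {"bindings": bindings}}, indent=1)


def _matches_csv(matches) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["s", "p", "o"])
    for s, p, o in matches:
        writer.writerow([_term_string(s), _term_string(p), _term_string(o)])
    return buf.getvalue()


def _matches_graph(matches, kb: KnowledgeBase) -> Graph:
    g = Graph()
    for pfx, uri in kb.graph.namespaces():
        g.bind(pfx, uri, replace=True)
    for triple in matches:
        g.add(triple)
    return g


def _html_table(rows: list[tuple[str, ...]], headers: tuple[str, ...],
                title: str) -> str:
    head = "".join(f"<th>{html.escape(h)}</th>" for h in headers)
    body = "".join(
        "<tr>" + "".join(f"<td>{html.escape(c)}</td>" for c in row) + "</tr>"
        for row in rows)
    return ("<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{html.escape(title)}</title></head><body>"
            f"<h1>{html.escape(title)}</h1>"
            f"<table><thead><tr>{head}</tr></thead>"
            f"<tbody>{body}</tbody></table></body></html>")


def get_triple(pattern: TriplePattern, format: str, kb: KnowledgeBase) -> str:
    """Return every statement matching *pattern*, serialized as requested.

    An empty match yields an empty-but-valid document of the same format.
    """
    check_format(format)
    matches = sorted(kb.triples(pattern.as_tuple()))
    if format == "csv":
        return _matches_csv(matches)
    if format == "js":
        return _bindings_json(matches)
    if format in ("xml", "rdf"):
        return _matches_graph(matches, kb).serialize(format="pretty-xml")
    return _html_table([(str(s), str(p), str(o)) for s, p, o in matches],
                       ("subject", "predicate", "object"), "Triple matches")


_UPDATE_RE = re.compile(
    r"^\s*(?:(?:PREFIX\s+\S+\s+<[^>]*>|BASE\s+<[^>]*>)\s*)*"
    r"(INSERT|DELETE|LOAD|CLEAR|CREATE|DROP|COPY|MOVE|ADD|WITH)\b",
    re.IGNORECASE)


def sparql_endpoint(query: str, output: str | None, kb: KnowledgeBase) -> tuple[str, str]:
    """Execute a read-only SPARQL query; returns ``(document, media_type)``.

    ``output`` follows the REST format tokens; when absent, SELECT/ASK
    results default to SPARQL-results-XML and graphs to RDF/XML.
    """
    if _UPDATE_RE.match(query):
        raise ClientError("update forms are not accepted by this endpoint")
    token = check_format(output) if output else "xml"
    try:
        result = kb.query(query)
    except Exception as exc:
        raise ClientError(f"query parse/execution error: {exc}") from exc

    if result.type in ("SELECT", "ASK"):
        if token == "csv":
            return result.serialize(format="csv").decode("utf-8"), "text/csv"
        if token == "js":
            return (result.serialize(format="json").decode("utf-8"),
                    "application/sparql-results+json")
        if token == "xml":
            return (result.serialize(format="xml").decode("utf-8"),
                    "application/sparql-results+xml")
        if token == "html" and result.type == "SELECT":
            vars_ = [str(v) for v in (result.vars or [])]
            rows = [tuple(str(row.asdict().get(v, "")) for v in vars_)
                    for row in result]
            return (_html_table(rows, tuple(vars_), "Query results"),
                    "text/html")
        raise ClientError(
            f"output {token!r} is not available for {result.type} queries")
    # CONSTRUCT / DESCRIBE
    if token in ("xml", "rdf"):
        return (result.serialize(format="pretty-xml").decode("utf-8"),
                "application/rdf+xml")
    raise ClientError(
        f"output {token!r} is not available for {result.type} queries")


def linked_data_view(resource_local_name: str, mode: str, kb: KnowledgeBase
                     ) -> tuple[str, int]:
    """Dereference an instance-namespace resource.

    ``rdf`` mode returns the statements where the resource is the subject as
    RDF/XML; ``html`` mode renders the same statements as a summary table.
    Unknown resources produce an empty description with a 404-class status.
    """
    if mode not in ("rdf", "html"):
        raise ClientError(f"unknown LinkedData mode {mode!r}")
    subject = URIRef(kb.instance_ns + resource_local_name)
    matches = sorted(kb.triples((subject, None, None)))
    status = 200 if matches else 404
    if mode == "rdf":
        return _matches_graph(matches, kb).serialize(format="pretty-xml"), status
    label = next((str(o) for s, p, o in matches if p == RDFS.label),
                 resource_local_name)
    doc = _html_table([(str(p), str(o)) for _, p, o in matches],
                      ("predicate", "object"), label)
    return doc, status


def resolve_bridge(bridge: BridgeDef, item_id: str) -> str:
    """Substitute every ``#replace#`` token in the bridge pattern with the
    item identifier."""
    if not item_id:
        raise ClientError("item identifier must be nonempty")
    return bridge.pattern.replace(REPLACE_TOKEN, item_id)
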