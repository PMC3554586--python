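"""Minimal SPARQL protocol client and local-query adapter.

Speaks the standard SPARQL 1.1 protocol over HTTP (form-encoded POST,
results requested as SPARQL-results-JSON) and converts both remote and
in-process rdflib results into :class:`~kbseed.records.SparqlResults`.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request

from rdflib import BNode, Graph, Literal, URIRef

from .errors import FetchError
from .records import SparqlResults, Term

DEFAULT_TIMEOUT = 15.0


def _term_from_json(binding: dict) -> Term:
    kind = {"uri": "uri", "literal": "literal", "typed-literal": "literal",
            "bnode": "bnode"}.get(binding.get("type", "literal"), "literal")
    return Term(binding.get("value", ""), kind)


def parse_results_json(text: str) -> SparqlResults:
    """Parse a SPARQL-results-JSON document (SELECT or ASK)."""
    data = json.loads(text)
    if "boolean" in data:
        return SparqlResults(boolean=bool(data["boolean"]))
    out = SparqlResults(vars=list(data.get("head", {}).get("vars", [])))
    for sol in data.get("results", {}).get("bindings", []):
        out.rows.append({v: _term_from_json(b) for v, b in sol.items()})
    return out


def sparql_select(endpoint: str, query: str,
                  timeout: float = DEFAULT_TIMEOUT) -> SparqlResults:
    """Run a SELECT/ASK query against a remote endpoint over HTTP."""
    body = urllib.parse.urlencode({"query": query, "output": "js"}).encode()
    req = urllib.request.Request(
        endpoint,
        data=body,
        headers={
            "Accept": "application/sparql-results+json",
            "Content-Type": "application/x-www-form-urlencoded",
        },
    )
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            status = getattr(resp, "status", 200)
            payload = resp.read().decode("utf-8")
    except urllib.error.HTTPError as exc:
        raise FetchError(endpoint, f"SPARQL endpoint answered {exc.code}",
                         status=exc.code) from exc
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(endpoint, f"SPARQL endpoint unreachable: {exc}") from exc
    if status < 200 or status >= 300:
        raise FetchError(endpoint, f"SPARQL endpoint answered {status}",
                         status=status)
    try:
        return parse_results_json(payload)
    except (ValueError, KeyError) as exc:
        raise FetchError(endpoint, f"unparseable SPARQL results: {exc}") from exc


def term_of(node) -> Term:
    if isinstance(node, URIRef):
        return Term(str(node), "uri")
    if isinstance(node, BNode):
        return Term(str(node), "bnode")
    if isinstance(node, Literal):
        return Term(str(node), "literal")
    raise TypeError(f"unexpected RDF node {node!r}")


def graph_select(graph: Graph, query: str,
                 init_ns: dict | None = None) -> SparqlResults:
    """Run a SELECT/ASK query against an in-process graph."""
    result = graph.query(query, initNs=init_ns or {})
    if result.type == "ASK":
        return SparqlResults(boolean=bool(result))
    out = SparqlResults(vars=[str(v) for v in (result.vars or [])])
    for row in result:
        out.rows.append({k: term_of(v) for k, v in row.asdict().items()
                         if v is not None})
    return out
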