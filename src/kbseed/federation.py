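"""Federated SPARQL execution across several endpoints.

A federated query is a SELECT whose WHERE block is a sequence of
``SERVICE <endpoint> { ... }`` clauses (possibly interleaved with plain
local patterns).  Execution is a nested-loop binding propagation in clause
order: each clause runs as a standalone sub-SELECT at its endpoint, with
the bindings accumulated so far injected as a VALUES block over the shared
variables, and the solutions are joined back in.  This is deliberately
non-optimizing — clause order is execution order — which is sufficient for
the few-endpoint, few-thousand-triple knowledge networks it targets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdflib import Graph

from .errors import FederationError, FetchError
from .records import SparqlResults, Term
from .sparql_client import graph_select, sparql_select

_PROLOGUE_RE = re.compile(
    r"^\s*((?:(?:PREFIX\s+\S+\s+<[^>]*>|BASE\s+<[^>]*>)\s*)*)",
    re.IGNORECASE)
_SELECT_RE = re.compile(
    r"SELECT\s+(DISTINCT\s+)?(.*?)\s*WHERE\s*\{", re.IGNORECASE | re.DOTALL)
_SERVICE_RE = re.compile(r"SERVICE\s+(SILENT\s+)?(<[^>]*>|[\w.-]+:?[\w.-]*)\s*\{",
                         re.IGNORECASE)
_VAR_RE = re.compile(r"\?([A-Za-z_][A-Za-z0-9_]*)")


@dataclass
class Segment:
    kind: str  # "service" | "local"
    endpoint: str | None
    block: str


def _matching_brace(text: str, open_pos: int) -> int:
    """Index of the brace matching ``text[open_pos] == '{'``; respects
    quoted strings and IRI brackets."""
    depth = 0
    i = open_pos
    n = len(text)
    while i < n:
        c = text[i]
        if c in "\"'":
            quote = c
            i += 1
            while i < n and text[i] != quote:
                i += 2 if text[i] == "\\" else 1
            i += 1
            continue
        if c == "<":
            end = text.find(">", i)
            i = (end if end != -1 else n) + 1
            continue
        if c == "{":
            depth += 1
        elif c == "}":
            depth -= 1
            if depth == 0:
                return i
        i += 1
    raise FederationError("unbalanced braces in query body")


def split_query(query: str) -> tuple[str, bool, list[str], list[Segment]]:
    """Split a federated SELECT into (prologue, distinct, projection,
    ordered segments)."""
    prologue = _PROLOGUE_RE.match(query).group(1)
    m = _SELECT_RE.search(query)
    if not m:
        raise FederationError("only SELECT queries can be federated")
    distinct = bool(m.group(1))
    projection = _VAR_RE.findall(m.group(2)) if "*" not in m.group(2) else []
    body_open = m.end() - 1
    body_close = _matching_brace(query, body_open)
    body = query[body_open + 1:body_close]

    segments: list[Segment] = []
    pos = 0
    local_buf: list[str] = []
    while True:
        sm = _SERVICE_RE.search(body, pos)
        if not sm:
            local_buf.append(body[pos:])
            break
        local_buf.append(body[pos:sm.start()])
        open_pos = sm.end() - 1
        close_pos = _matching_brace(body, open_pos)
        target = sm.group(2)
        if target.startswith("<"):
            target = target[1:-1]
        local_text = "".join(local_buf).strip()
        if local_text:
            segments.append(Segment("local", None, local_text))
        local_buf = []
        segments.append(Segment("service", target,
                                body[open_pos + 1:close_pos]))
        pos = close_pos + 1
    tail = "".join(local_buf).strip()
    if tail:
        segments.append(Segment("local", None, tail))
    return prologue, distinct, projection, segments


def _values_term(term: Term) -> str | None:
    if term.kind == "uri":
        return f"<{term.text}>"
    if term.kind == "literal":
        escaped = term.text.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    return None  # blank nodes cannot be transported across endpoints


def _values_clause(shared: list[str],
                   bindings: list[dict[str, Term]]) -> str:
    combos: list[tuple] = []
    seen = set()
    for row in bindings:
        combo = tuple(_values_term(row[v]) for v in shared)
        if None in combo or combo in seen:
            continue
        seen.add(combo)
        combos.append(combo)
    rows = " ".join("(" + " ".join(c) + ")" for c in combos)
    heads = " ".join("?" + v for v in shared)
    return f"VALUES ({heads}) {{ {rows} }}"


def _run_segment(segment: Segment, prologue: str,
                 bindings: list[dict[str, Term]],
                 registry: dict[str, str],
                 graphs: dict[str, Graph],
                 kb) -> list[dict[str, Term]]:
    block_vars = set(_VAR_RE.findall(segment.block))
    bound_vars = set().union(*(row.keys() for row in bindings)) if bindings else set()
    shared = sorted(block_vars & bound_vars)

    inner = segment.block
    if shared:
        inner = _values_clause(shared, bindings) + "\n" + inner
    sub = f"{prologue}\nSELECT * WHERE {{ {inner} }}"

    if segment.kind == "local":
        if kb is None:
            raise FederationError(
                "query contains non-SERVICE patterns but no local store "
                "was provided")
        results = graph_select(getattr(kb, "graph", kb), sub)
    else:
        target = registry.get(segment.endpoint, segment.endpoint)
        if target in graphs:
            results = graph_select(graphs[target], sub)
        else:
            try:
                results = sparql_select(target, sub)
            except FetchError as exc:
                raise FederationError(
                    f"SERVICE endpoint {target!r} failed: {exc}") from exc

    joined: list[dict[str, Term]] = []
    for brow in bindings:
        for rrow in results.rows:
            if all(v not in rrow or brow[v] == rrow[v] for v in shared):
                merged = dict(brow)
                merged.update(rrow)
                joined.append(merged)
    return joined


def federated_query(query: str,
                    endpoint_registry: dict[str, str] | None = None,
                    kb=None,
                    local_graphs: dict[str, Graph] | None = None
                    ) -> SparqlResults:
    """Execute a federated SELECT, propagating bindings between SERVICE
    clauses in order.

    ``endpoint_registry`` maps labels (or URIs) to endpoint URIs;
    ``local_graphs`` optionally maps endpoint URIs to in-process graphs so
    tests can run without sockets.  A query with no SERVICE clause is
    executed wholesale on *kb*.
    """
    registry = dict(endpoint_registry or {})
    graphs = dict(local_graphs or {})
    prologue, distinct, projection, segments = split_query(query)

    if not any(s.kind == "service" for s in segments):
        if kb is None:
            raise FederationError("no SERVICE clauses and no local store")
        return graph_select(getattr(kb, "graph", kb), query)

    bindings: list[dict[str, Term]] = [{}]
    for segment in segments:
        bindings = _run_segment(segment, prologue, bindings, registry,
                                graphs, kb)
        if not bindings:
            break

    all_vars: list[str] = []
    for row in bindings:
        for v in row:
            if v not in all_vars:
                all_vars.append(v)
    out_vars = projection or sorted(all_vars)
    out = SparqlResults(vars=list(out_vars))
    seen = set()
    for row in bindings:
        sol = {v: row[v] for v in out_vars if v in row}
        if distinct:
            key = tuple(sorted(sol.items()))
            if key in seen:
                continue
            seen.add(key)
        out.rows.append(sol)
    return out
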