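"""Connectors: fetch raw content from a resource URI and evaluate selectors
against it, producing model-independent :class:`~kbseed.records.RecordSet`s.

Four source kinds are supported, one per selector dialect:

=======  ==========================  ==============================
kind     selector query              source
=======  ==========================  ==============================
csv      0-based column index        CSV text (RFC-4180 style)
xml      XPath 1.0 expression        XML document
sql      result column name          SQL query over a connection URI
sparql   result variable name        SPARQL SELECT over HTTP
=======  ==========================  ==============================

Whatever the kind, the output is value-identical for the same logical data:
the record set is the abstraction layer between sources and triples.
"""

from __future__ import annotations

import codecs
import csv
import io
import sqlite3
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .errors import ConfigurationError, FetchError
from .model import REPLACE_TOKEN, Selector
from .records import RecordSet, ResultTable, SkipRecord, SparqlResults, Term
from .sparql_client import sparql_select

DEFAULT_TIMEOUT = 15.0


@dataclass
class FetchSpec:
    """A fully resolved fetch: URI (no residual ``#replace#``), source kind
    and, for sql/sparql, the query to run."""

    uri: str
    kind: str
    query_text: str | None = None

    def __post_init__(self) -> None:
        if REPLACE_TOKEN in self.uri:
            raise ConfigurationError(
                f"unresolved {REPLACE_TOKEN} token in URI {self.uri!r}")


@dataclass
class CsvDialect:
    delimiter: str = ","
    quotechar: str = '"'
    header: bool = False


def resolve_endpoint(template: str, item_id: str) -> str:
    """Substitute ``#replace#`` in an endpoint template with a (percent-
    encoded) item identifier.

    >>> resolve_endpoint("http://example.org/uniprot/#replace#.rdf", "P51587")
    'http://example.org/uniprot/P51587.rdf'
    """
    import urllib.parse
    return template.replace(REPLACE_TOKEN,
                            urllib.parse.quote(item_id, safe=""))


def _strip_bom(text: str) -> str:
    return text.lstrip("\ufeff")


def _read_uri(uri: str, timeout: float) -> str:
    """Read a file/http/https URI as UTF-8 text; verify declared sizes."""
    if "://" not in uri:
        # bare filesystem path convenience
        uri = Path(uri).absolute().as_uri()
    scheme = uri.split(":", 1)[0].lower()
    if scheme not in ("file", "http", "https"):
        raise FetchError(uri, f"unsupported scheme {scheme!r} for text sources")
    try:
        with urllib.request.urlopen(uri, timeout=timeout) as resp:
            status = getattr(resp, "status", None)
            if status is not None and not (200 <= status < 300):
                raise FetchError(uri, f"HTTP status {status}", status=status)
            data = resp.read()
            declared = resp.headers.get("Content-Length") if resp.headers else None
            if declared is not None and int(declared) != len(data):
                raise FetchError(
                    uri, f"truncated read: got {len(data)} of {declared} bytes")
    except urllib.error.HTTPError as exc:
        raise FetchError(uri, f"HTTP status {exc.code}", status=exc.code) from exc
    except (urllib.error.URLError, OSError) as exc:
        raise FetchError(uri, f"unreachable: {exc}") from exc
    if data.startswith(codecs.BOM_UTF8):
        data = data[len(codecs.BOM_UTF8):]
    return data.decode("utf-8")


def _sqlite_path(uri: str) -> str:
    body = uri.split(":", 1)[1] if ":" in uri else uri
    if body.startswith("///"):
        body = body[2:]  # sqlite:///abs/path -> /abs/path
    elif body.startswith("//"):
        body = body[2:]
    return body


def fetch(spec: FetchSpec, cache: dict | None = None,
          services: dict | None = None,
          timeout: float = DEFAULT_TIMEOUT):
    """Fetch raw content for *spec*.

    Returns decoded text for csv/xml, a :class:`ResultTable` for sql and a
    :class:`SparqlResults` for sparql.  ``cache`` (uri -> content) makes
    per-item fetches replayable within one build run; ``services`` maps
    SPARQL endpoint URIs to in-process rdflib graphs, letting tests bypass
    HTTP.
    """
    cache_key = (spec.kind, spec.uri, spec.query_text or "")
    if cache is not None and cache_key in cache:
        return cache[cache_key]

    if spec.kind in ("csv", "xml"):
        content = _read_uri(spec.uri, timeout)
    elif spec.kind == "sql":
        if not spec.query_text:
            raise ConfigurationError(f"sql resource {spec.uri!r} has no query")
        scheme = spec.uri.split(":", 1)[0].lower().removeprefix("jdbc:")
        if "sqlite" not in spec.uri.split("//", 1)[0].lower():
            raise FetchError(spec.uri, f"unsupported SQL connection scheme {scheme!r}")
        path = _sqlite_path(spec.uri.removeprefix("jdbc:"))
        if not Path(path).exists():
            raise FetchError(spec.uri, f"database file not found: {path}")
        con = sqlite3.connect(path)
        try:
            cur = con.execute(spec.query_text)
            columns = [d[0] for d in cur.description]
            rows = [[None if v is None else str(v) for v in row]
                    for row in cur.fetchall()]
        except sqlite3.Error as exc:
            raise FetchError(spec.uri, f"SQL error: {exc}") from exc
        finally:
            con.close()
        content = ResultTable(columns=columns, rows=rows)
    elif spec.kind == "sparql":
        if not spec.query_text:
            raise ConfigurationError(f"sparql resource {spec.uri!r} has no query")
        if services and spec.uri in services:
            from .sparql_client import graph_select
            content = graph_select(services[spec.uri], spec.query_text)
        else:
            content = sparql_select(spec.uri, spec.query_text, timeout=timeout)
    else:
        raise ConfigurationError(f"unknown connector kind {spec.kind!r}")

    if cache is not None:
        cache[cache_key] = content
    return content


def select_csv(content: str, selectors: list[Selector],
               dialect: CsvDialect | None = None,
               source_uri: str = "") -> RecordSet:
    """One record per data row; values are the cells at each selector's
    0-based column index.  Rows narrower than the largest requested index
    are skipped and reported, not silently dropped."""
    dialect = dialect or CsvDialect()
    indices: list[int] = []
    for i, sel in enumerate(selectors):
        try:
            idx = int(sel.query)
            if idx < 0:
                raise ValueError
        except (TypeError, ValueError):
            raise ConfigurationError(
                f"selector #{i} query {sel.query!r} is not a non-negative "
                "column index") from None
        indices.append(idx)

    out = RecordSet(source_uri=source_uri)
    reader = csv.reader(io.StringIO(_strip_bom(content)),
                        delimiter=dialect.delimiter, quotechar=dialect.quotechar)
    rows = [row for row in reader if row]
    if dialect.header and rows:
        rows = rows[1:]
    for rownum, row in enumerate(rows):
        if any(idx >= len(row) for idx in indices):
            out.skips.append(SkipRecord(
                rownum, f"row has {len(row)} columns, selector needs "
                        f"column {max(indices)}"))
            continue
        record = {}
        for i, idx in enumerate(indices):
            cell = row[idx]
            record[i] = [Term(cell)] if cell != "" else []
        out.records.append(record)
    return out


def select_xml(content: str, selectors: list[Selector],
               record_path: str | None = None,
               source_uri: str = "") -> RecordSet:
    """One record per node matched by *record_path* (document root when
    absent); selector XPaths are evaluated relative to each record node and
    may yield several values in document order."""
    try:
        root = etree.fromstring(_strip_bom(content).encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ConfigurationError(f"malformed XML: {exc}") from exc

    compiled = []
    for i, sel in enumerate(selectors):
        try:
            compiled.append(etree.XPath(sel.query))
        except etree.XPathSyntaxError as exc:
            raise ConfigurationError(
                f"selector #{i} ({sel.key or sel.query!r}) has invalid "
                f"XPath: {exc}") from exc

    if record_path:
        try:
            nodes = etree.XPath(record_path)(root)
        except etree.XPathSyntaxError as exc:
            raise ConfigurationError(
                f"invalid record path {record_path!r}: {exc}") from exc
        except etree.XPathEvalError as exc:
            raise ConfigurationError(
                f"record path {record_path!r} failed: {exc}") from exc
        if not isinstance(nodes, list):
            raise ConfigurationError(
                f"record path {record_path!r} does not select nodes")
    else:
        nodes = [root]

    out = RecordSet(source_uri=source_uri)
    for node in nodes:
        record: dict[int, list[Term]] = {}
        for i, xpath in enumerate(compiled):
            try:
                raw = xpath(node)
            except etree.XPathEvalError as exc:
                raise ConfigurationError(
                    f"selector #{i} XPath failed on record node: {exc}") from exc
            values: list[Term] = []
            for item in raw if isinstance(raw, list) else [raw]:
                if isinstance(item, etree._Element):
                    text = "".join(item.itertext())
                else:
                    text = str(item)
                if text != "":
                    values.append(Term(text))
            record[i] = values
        out.records.append(record)
    return out


def select_sql(table: ResultTable, selectors: list[Selector],
               source_uri: str = "") -> RecordSet:
    """One record per row, values taken by column name; NULL cells yield an
    empty value list (never the string ``"None"``)."""
    positions: list[int] = []
    for i, sel in enumerate(selectors):
        if sel.query not in table.columns:
            raise ConfigurationError(
                f"selector #{i} names unknown SQL column {sel.query!r} "
                f"(available: {table.columns})")
        positions.append(table.columns.index(sel.query))

    out = RecordSet(source_uri=source_uri)
    for row in table.rows:
        record = {}
        for i, pos in enumerate(positions):
            cell = row[pos]
            record[i] = [] if cell in (None, "") else [Term(cell)]
        out.records.append(record)
    return out


def select_sparql(results: SparqlResults, selectors: list[Selector],
                  source_uri: str = "") -> RecordSet:
    """One record per solution; unbound variables yield empty value lists;
    URI and literal bindings both keep their term kind."""
    for i, sel in enumerate(selectors):
        if results.vars and sel.query not in results.vars:
            raise ConfigurationError(
                f"selector #{i} names unknown SPARQL variable {sel.query!r} "
                f"(available: {results.vars})")

    out = RecordSet(source_uri=source_uri)
    for sol in results.rows:
        record = {}
        for i, sel in enumerate(selectors):
            term = sol.get(sel.query)
            record[i] = [term] if term is not None and term.text != "" else []
        out.records.append(record)
    return out


def select_records(kind: str, raw, selectors: list[Selector],
                   dialect: CsvDialect | None = None,
                   record_path: str | None = None,
                   source_uri: str = "") -> RecordSet:
    """Dispatch to the kind-specific selector evaluation."""
    if kind == "csv":
        return select_csv(raw, selectors, dialect, source_uri=source_uri)
    if kind == "xml":
        return select_xml(raw, selectors, record_path, source_uri=source_uri)
    if kind == "sql":
        return select_sql(raw, selectors, source_uri=source_uri)
    if kind == "sparql":
        return select_sparql(raw, selectors, source_uri=source_uri)
    raise ConfigurationError(f"unknown connector kind {kind!r}")
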