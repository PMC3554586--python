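"""Thin HTTP façade over the access API, built on the standard library's
threading HTTP server.

Routes
------
``GET /api/triple/{sub}/{pred}/{obj}/{format}``
    triple-pattern query, positional wildcards ``sub``/``pred``/``obj``
    (or ``s``/``p``/``o``);
``GET/POST /sparql?query=...&output=csv|js|xml``
    read-only SPARQL endpoint (results-XML when ``output`` is absent);
``GET /resource/{localname}``
    LinkedData view, content-negotiated RDF/XML vs HTML;
``GET /ontology``
    the internal vocabulary document.
"""

from __future__ import annotations

import threading
import urllib.parse
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from rdflib import Graph, Literal
from rdflib.namespace import OWL, RDF, RDFS

from . import api
from .engine import KnowledgeBase
from .errors import ClientError

_MEDIA_TYPES = {
    "csv": "text/csv; charset=utf-8",
    "js": "application/sparql-results+json",
    "xml": "application/rdf+xml",
    "rdf": "application/rdf+xml",
    "html": "text/html; charset=utf-8",
}


def vocabulary_graph(vocab) -> Graph:
    """A small OWL document describing the internal classes/predicates."""
    g = Graph()
    g.bind("kb", str(vocab.namespace), replace=True)
    from rdflib import URIRef
    ontology = URIRef(str(vocab.namespace).rstrip("#/"))
    g.add((ontology, RDF.type, OWL.Ontology))
    for name, uri in vocab.classes.items():
        g.add((uri, RDF.type, OWL.Class))
        g.add((uri, RDFS.label, Literal(name)))
    for name, uri in vocab.predicates.items():
        if str(uri).startswith(str(vocab.namespace)):
            g.add((uri, RDF.type, RDF.Property))
            g.add((uri, RDFS.label, Literal(name)))
    for a, b in vocab.inverse_pairs:
        g.add((a, OWL.inverseOf, b))
    return g


class SeedServer:
    """An embeddable server for one knowledge base.

    Binds to an ephemeral port by default; use as a context manager or call
    :meth:`start`/:meth:`stop` explicitly.
    """

    def __init__(self, kb: KnowledgeBase, host: str = "127.0.0.1",
                 port: int = 0, prefixes: dict[str, str] | None = None):
        self.kb = kb
        self.prefixes = dict(prefixes or {})
        self.prefixes.setdefault("seed", kb.instance_ns)
        self.prefixes.setdefault("kb", str(kb.vocab.namespace))
        self.prefixes.setdefault("dc", "http://purl.org/dc/elements/1.1/")
        self.prefixes.setdefault("rdfs", "http://www.w3.org/2000/01/rdf-schema#")
        for pfx, uri in kb.graph.namespaces():
            self.prefixes.setdefault(str(pfx), str(uri))
        handler = _make_handler(self)
        self._httpd = ThreadingHTTPServer((host, port), handler)
        self._thread: threading.Thread | None = None

    @property
    def port(self) -> int:
        return self._httpd.server_address[1]

    @property
    def url(self) -> str:
        return f"http://{self._httpd.server_address[0]}:{self.port}"

    @property
    def sparql_url(self) -> str:
        return self.url + "/sparql"

    def start(self) -> "SeedServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever,
                                        daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread:
            self._thread.join(timeout=5)

    def __enter__(self) -> "SeedServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


def _make_handler(server: SeedServer):
    kb = server.kb
    prefixes = server.prefixes

    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # quiet test output
            pass

        def _send(self, status: int, body: str, media_type: str) -> None:
            payload = body.encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", media_type)
            self.send_header("Content-Length", str(len(payload)))
            self.end_headers()
            self.wfile.write(payload)

        def _handle(self, params: dict[str, str]) -> None:
            path = urllib.parse.urlsplit(self.path).path
            try:
                if path.startswith("/api/triple"):
                    tokens, fmt = api.parse_triple_route(path)
                    pattern = api.parse_pattern(*tokens, prefixes=prefixes)
                    doc = api.get_triple(pattern, fmt, kb)
                    self._send(200, doc, _MEDIA_TYPES[fmt])
                elif path == "/sparql":
                    query = params.get("query")
                    if not query:
                        raise ClientError("missing 'query' parameter")
                    output = params.get("output")
                    if output is None and "json" in self.headers.get("Accept", ""):
                        output = "js"
                    doc, media = api.sparql_endpoint(query, output, kb)
                    self._send(200, doc, media)
                elif path.startswith("/resource/"):
                    local = urllib.parse.unquote(path[len("/resource/"):])
                    mode = ("html" if "text/html" in self.headers.get("Accept", "")
                            else "rdf")
                    doc, status = api.linked_data_view(local, mode, kb)
                    self._send(status, doc, _MEDIA_TYPES[mode])
                elif path == "/ontology":
                    doc = vocabulary_graph(kb.vocab).serialize(format="pretty-xml")
                    self._send(200, doc, "application/rdf+xml")
                else:
                    self._send(404, f"no route for {path}\n", "text/plain")
            except ClientError as exc:
                self._send(exc.status, str(exc) + "\n", "text/plain")
            except Exception as exc:  # pragma: no cover - defensive
                self._send(500, f"internal error: {exc}\n", "text/plain")

        def do_GET(self) -> None:
            query = urllib.parse.urlsplit(self.path).query
            params = {k: v[0] for k, v in
                      urllib.parse.parse_qs(query).items()}
            self._handle(params)

        def do_POST(self) -> None:
            length = int(self.headers.get("Content-Length", 0))
            body = self.rfile.read(length).decode("utf-8")
            ctype = self.headers.get("Content-Type", "")
            if "application/sparql-query" in ctype:
                params = {"query": body}
            else:
                params = {k: v[0] for k, v in
                          urllib.parse.parse_qs(body).items()}
            url_params = {k: v[0] for k, v in urllib.parse.parse_qs(
                urllib.parse.urlsplit(self.path).query).items()}
            url_params.update(params)
            self._handle(url_params)

    return Handler
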