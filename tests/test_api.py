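"""Triple-pattern REST semantics, SPARQL endpoint, LinkedData views and
bridge URL resolution — including the cross-interface consistency
property: all three read paths agree on every item's statement set."""

import csv
import io
import json

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from kbseed import (
    BridgeDef,
    ClientError,
    KnowledgeBase,
    get_triple,
    linked_data_view,
    parse_pattern,
    parse_triple_route,
    resolve_bridge,
    sparql_endpoint,
)
from kbseed.sparql_client import parse_results_json
from kbseed.vocab import VOCAB

PREFIXES = {"seed": "http://example.org/rds/",
            "kb": str(VOCAB.namespace),
            "dc": "http://purl.org/dc/elements/1.1/",
            "rdfs": "http://www.w3.org/2000/01/rdf-schema#"}


# ---------------------------------------------------------------------------
# pattern and route parsing
# ---------------------------------------------------------------------------

def test_wildcards_accept_both_spellings():
    for tokens in (("sub", "pred", "obj"), ("s", "p", "o")):
        pattern = parse_pattern(*tokens, prefixes=PREFIXES)
        assert pattern.as_tuple() == (None, None, None)


def test_wildcard_in_wrong_position_is_rejected():
    with pytest.raises(ClientError, match="only valid in predicate"):
        parse_pattern("pred", "p", "o", prefixes=PREFIXES)
    with pytest.raises(ClientError):
        # "p" in subject position is not a wildcard and not a CURIE
        parse_pattern("p", "pred", "obj", prefixes=PREFIXES)


def test_curies_resolve_and_unknown_prefix_is_client_error():
    pattern = parse_pattern("seed:uniprot_P51587", "p", "o",
                            prefixes=PREFIXES)
    assert pattern.subject == URIRef("http://example.org/rds/uniprot_P51587")
    with pytest.raises(ClientError, match="nope"):
        parse_pattern("nope:x", "p", "o", prefixes=PREFIXES)


def test_bare_object_token_is_a_literal():
    pattern = parse_pattern("s", "p", "114480", prefixes=PREFIXES)
    assert pattern.object == Literal("114480")


@pytest.mark.parametrize("path, expect_fmt", [
    ("/api/triple/seed:omim_114480/pred/obj/xml", "xml"),
    ("/api/triple/sub/pred/obj/csv", "csv"),
])
def test_route_parsing_good_paths(path, expect_fmt):
    tokens, fmt = parse_triple_route(path)
    assert fmt == expect_fmt
    assert len(tokens) == 3


def test_route_segment_count_and_format_errors():
    with pytest.raises(ClientError) as err:
        parse_triple_route("/api/triple/a/b")
    assert err.value.status == 404
    with pytest.raises(ClientError) as err:
        parse_triple_route("/api/triple/s/p/o/docx")
    assert err.value.status == 400


# ---------------------------------------------------------------------------
# get_triple and serializations
# ---------------------------------------------------------------------------

def _uniprot_subject(kb):
    for s in sorted(kb.graph.subjects(RDF.type, VOCAB.classes["Item"])):
        if "uniprot_" in str(s):
            return s
    raise AssertionError("no protein item in fixture build")


def _statements_from_csv(doc):
    rows = list(csv.reader(io.StringIO(doc)))[1:]
    return {(s, p, o) for s, p, o in rows}


def _statements_from_js(doc):
    data = json.loads(doc)
    return {(b["s"]["value"], b["p"]["value"], b["o"]["value"])
            for b in data["results"]["bindings"]}


def _statements_from_xml(doc):
    g = Graph()
    g.parse(data=doc, format="xml")
    return {(str(s), str(p), str(o)) for s, p, o in g}


def test_format_round_trip_yields_one_statement_set(built_kb):
    subject = _uniprot_subject(built_kb)
    pattern = parse_pattern(str(subject), "p", "o", prefixes=PREFIXES)
    sets = {
        "csv": _statements_from_csv(get_triple(pattern, "csv", built_kb)),
        "js": _statements_from_js(get_triple(pattern, "js", built_kb)),
        "xml": _statements_from_xml(get_triple(pattern, "xml", built_kb)),
    }
    assert sets["csv"] == sets["js"] == sets["xml"]
    assert len(sets["csv"]) > 0


def test_empty_store_yields_empty_but_valid_documents():
    kb = KnowledgeBase()
    pattern = parse_pattern("sub", "pred", "obj", prefixes=PREFIXES)
    assert _statements_from_js(get_triple(pattern, "js", kb)) == set()
    assert _statements_from_csv(get_triple(pattern, "csv", kb)) == set()


def test_concept_bound_pattern_lists_all_items_of_the_concept(built_kb,
                                                              bundle):
    pattern = parse_pattern("sub", "kb:hasConcept", "seed:concept_OMIM",
                            prefixes=PREFIXES)
    stmts = _statements_from_js(get_triple(pattern, "js", built_kb))
    assert len(stmts) == bundle.manifest["items"]["OMIM"]


# ---------------------------------------------------------------------------
# SPARQL endpoint
# ---------------------------------------------------------------------------

def test_ask_empty_pattern_is_true(built_kb):
    doc, media = sparql_endpoint("ASK {}", "js", built_kb)
    assert parse_results_json(doc).boolean is True
    assert "json" in media


def test_select_agrees_with_triple_pattern_interface(built_kb):
    subject = _uniprot_subject(built_kb)
    doc, _ = sparql_endpoint(
        f"SELECT ?p ?o WHERE {{ <{subject}> ?p ?o }}", "js", built_kb)
    rows = parse_results_json(doc).rows
    via_sparql = {(str(subject), r["p"].text, r["o"].text) for r in rows}
    pattern = parse_pattern(str(subject), "p", "o", prefixes=PREFIXES)
    via_rest = _statements_from_js(get_triple(pattern, "js", built_kb))
    assert via_sparql == via_rest


def test_default_output_is_results_xml(built_kb):
    doc, media = sparql_endpoint("ASK {}", None, built_kb)
    assert media == "application/sparql-results+xml"
    assert "sparql" in doc


def test_update_forms_are_rejected(built_kb):
    with pytest.raises(ClientError, match="update"):
        sparql_endpoint("INSERT DATA { <urn:a> <urn:b> <urn:c> }",
                        "js", built_kb)


def test_parse_error_is_a_client_error(built_kb):
    with pytest.raises(ClientError):
        sparql_endpoint("SELECT WHERE {", "js", built_kb)


def test_construct_returns_rdf(built_kb):
    subject = _uniprot_subject(built_kb)
    doc, media = sparql_endpoint(
        f"CONSTRUCT {{ <{subject}> ?p ?o }} WHERE {{ <{subject}> ?p ?o }}",
        "rdf", built_kb)
    assert media == "application/rdf+xml"
    assert len(_statements_from_xml(doc)) > 0


# ---------------------------------------------------------------------------
# LinkedData views
# ---------------------------------------------------------------------------

def test_linkeddata_rdf_equals_subject_bound_pattern(built_kb):
    subject = _uniprot_subject(built_kb)
    local = str(subject)[len(built_kb.instance_ns):]
    doc, status = linked_data_view(local, "rdf", built_kb)
    assert status == 200
    pattern = parse_pattern(str(subject), "p", "o", prefixes=PREFIXES)
    assert _statements_from_xml(doc) == \
        _statements_from_xml(get_triple(pattern, "xml", built_kb))


def test_linkeddata_html_contains_the_label(built_kb):
    subject = _uniprot_subject(built_kb)
    local = str(subject)[len(built_kb.instance_ns):]
    doc, status = linked_data_view(local, "html", built_kb)
    assert status == 200
    from rdflib.namespace import RDFS
    label = str(built_kb.graph.value(subject, RDFS.label))
    assert label in doc


def test_unknown_resource_is_empty_with_notfound_status(built_kb):
    doc, status = linked_data_view("uniprot_NOPE99", "rdf", built_kb)
    assert status == 404
    assert _statements_from_xml(doc) == set()


# ---------------------------------------------------------------------------
# bridges
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pattern, item_id, expected", [
    ("http://www.uniprot.org/uniprot/#replace#", "P51587",
     "http://www.uniprot.org/uniprot/P51587"),
    ("http://example.org/static", "P51587", "http://example.org/static"),
    ("http://x/#replace#/v/#replace#", "7", "http://x/7/v/7"),
], ids=["single-token", "no-token", "two-tokens"])
def test_bridge_resolution(pattern, item_id, expected):
    bridge = BridgeDef(key="b", concept_key="UniProt", pattern=pattern)
    assert resolve_bridge(bridge, item_id) == expected
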