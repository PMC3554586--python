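"""Explore a built seed through its four read interfaces.

The same statement set is reachable as a triple pattern (REST grammar), a
SPARQL SELECT, a LinkedData view, and a bridge gives the outbound URL for
an item.  All four agree — that is the cross-interface consistency the
access layer guarantees.
"""

import tempfile
from pathlib import Path

from kbseed import (
    BridgeDef,
    KnowledgeBase,
    build_seed,
    get_triple,
    linked_data_view,
    minimal_gene_model,
    parse_pattern,
    resolve_bridge,
    sparql_endpoint,
)

workdir = Path(tempfile.mkdtemp())
csv_path = workdir / "genes.csv"
csv_path.write_text("id,symbol\nHGNC:1101,BRCA2\nHGNC:11998,TP53\n")
model = minimal_gene_model(csv_path, namespace="http://example.org/genes/")
kb = KnowledgeBase.for_model(model)
build_seed(model, kb)

prefixes = {"seed": kb.instance_ns}
# the minted URI percent-encodes the colon in "HGNC:1101"
pattern = parse_pattern("seed:hgnc_HGNC%3A1101", "p", "o",
                        prefixes=prefixes)

print("--- triple pattern, CSV output (subject-bound, wildcards p/o) ---")
print(get_triple(pattern, "csv", kb))

print("--- SPARQL endpoint, JSON output ---")
doc, media = sparql_endpoint(
    "SELECT ?p ?o WHERE { <http://example.org/genes/hgnc_HGNC%3A1101> ?p ?o }",
    "js", kb)
print(media)
print(doc[:300], "...")

print()
print("--- LinkedData view (same statements, RDF/XML then HTML) ---")
rdf_doc, status = linked_data_view("hgnc_HGNC%3A1101", "rdf", kb)
print(f"status={status}, document bytes={len(rdf_doc)}")

print()
print("--- bridge: outbound URL for an item identifier ---")
bridge = BridgeDef(key="genenames", concept_key="HGNC",
                   pattern="https://www.genenames.org/data/"
                           "gene-symbol-report/#!/hgnc_id/#replace#")
print(resolve_bridge(bridge, "HGNC:1101"))
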