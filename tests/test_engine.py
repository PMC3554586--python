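"""Item minting, triplification and the cache/complete/map build methods."""

import pytest
from rdflib import URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import DC, RDF, RDFS

from kbseed import (
    BuildError,
    ConceptDef,
    EntityDef,
    ItemMap,
    KnowledgeBase,
    ResourceDef,
    SeedConfig,
    SeedModel,
    Selector,
    audit_concept_membership,
    build_seed,
    make_item_maps,
    mint_item_uri,
    minimal_gene_model,
    run_cache,
    run_complete,
    run_map,
    triplify,
)
from kbseed.engine import STRUCTURAL_TRIPLES_PER_ITEM, item_id_from_uri
from kbseed.records import RecordSet, Term
from kbseed.vocab import VOCAB

NS = "http://example.org/k/"


# ---------------------------------------------------------------------------
# minting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("concept, item_id, local", [
    ("UniProt", "P51587", "uniprot_P51587"),
    ("OMIM", "114480", "omim_114480"),
    ("HGNC", "HGNC:1101", "hgnc_HGNC%3A1101"),
], ids=["protein-accession", "disease-number", "curie-style-id"])
def test_item_uri_minting(concept, item_id, local):
    uri = mint_item_uri(concept, item_id, NS)
    assert uri == NS + local
    assert item_id_from_uri(uri, concept, NS) == item_id


def test_minting_is_injective_and_collisions_are_caught():
    model = _gene_model()
    model.concepts["AB"] = ConceptDef(key="AB", entity_key="Gene")
    model.concepts["Ab"] = ConceptDef(key="Ab", entity_key="Gene")
    kb = KnowledgeBase(instance_ns=NS)
    minted = {}
    triplify(ItemMap("x", "AB"), model, kb, minted=minted)
    with pytest.raises(BuildError, match="collision"):
        triplify(ItemMap("x", "Ab"), model, kb, minted=minted)


def test_empty_identifier_cannot_be_minted():
    with pytest.raises(BuildError):
        mint_item_uri("HGNC", "", NS)


# ---------------------------------------------------------------------------
# item maps
# ---------------------------------------------------------------------------

def _resource(selectors, **kw) -> ResourceDef:
    kw.setdefault("key", "R")
    kw.setdefault("kind", "csv")
    kw.setdefault("concept_key", "HGNC")
    return ResourceDef(selectors=selectors, **kw)


def test_double_property_selector_shares_one_value():
    res = _resource([Selector(query="0",
                              properties=["dc:source", "dc:identifier"],
                              is_key=True)])
    records = RecordSet(records=[{0: [Term("HGNC:5")]}])
    items, skipped = make_item_maps(records, res)
    assert skipped == 0
    (item,) = items
    assert item.identifier == "HGNC:5"
    assert item.properties == {"dc:source": [Term("HGNC:5")],
                               "dc:identifier": [Term("HGNC:5")]}


def test_record_with_empty_key_is_a_skip():
    res = _resource([Selector(query="0", properties=["dc:identifier"],
                              is_key=True)])
    items, skipped = make_item_maps(RecordSet(records=[{0: []}]), res)
    assert items == [] and skipped == 1


def test_multi_value_selector_cross_product():
    res = _resource([
        Selector(query="0", properties=["dc:identifier"], is_key=True),
        Selector(query="1", properties=["seed:p", "seed:q"]),
    ])
    records = RecordSet(records=[{0: [Term("id1")],
                                  1: [Term("v1"), Term("v2")]}])
    (item,), _ = make_item_maps(records, res)
    pairs = [(p, t.text) for p, ts in item.properties.items() for t in ts]
    assert len([p for p in pairs if p[0] != "dc:identifier"]) == 4  # 2 props x 2 values


# ---------------------------------------------------------------------------
# triplify
# ---------------------------------------------------------------------------

def _gene_model() -> SeedModel:
    model = SeedModel(config=SeedConfig(name="g", base_namespace=NS))
    model.entities["Gene"] = EntityDef(key="Gene", concept_keys=["HGNC"])
    model.concepts["HGNC"] = ConceptDef(key="HGNC", entity_key="Gene",
                                        label="HGNC")
    return model


def test_triplify_emits_paired_statements_with_shared_subject_and_object():
    model = _gene_model()
    kb = KnowledgeBase(instance_ns=NS)
    item = ItemMap("HGNC:5", "HGNC")
    item.add("dc:source", Term("HGNC:5"))
    item.add("dc:identifier", Term("HGNC:5"))
    triplify(item, model, kb)
    subject = URIRef(mint_item_uri("HGNC", "HGNC:5", NS))
    props = [(p, o) for _, p, o in kb.triples((subject, None, None))
             if p in (DC.source, DC.identifier)]
    assert len(props) == 2
    assert len({o for _, o in props}) == 1  # same object both times


def test_triplify_structural_statements_only_for_empty_map():
    model = _gene_model()
    kb = KnowledgeBase(instance_ns=NS)
    added = triplify(ItemMap("HGNC:5", "HGNC"), model, kb)
    assert added == STRUCTURAL_TRIPLES_PER_ITEM
    subject = URIRef(mint_item_uri("HGNC", "HGNC:5", NS))
    assert (subject, RDF.type, VOCAB.classes["Item"]) in kb.graph
    label = kb.graph.value(subject, RDFS.label)
    assert str(label) == "HGNC HGNC:5"  # concept label + identifier
    # concept membership materialised both ways
    concept = URIRef(NS + "concept_HGNC")
    assert (subject, VOCAB.predicates["hasConcept"], concept) in kb.graph
    assert (concept, VOCAB.predicates["isConceptOf"], subject) in kb.graph


def test_retriplifying_the_same_item_adds_nothing():
    model = _gene_model()
    kb = KnowledgeBase(instance_ns=NS)
    item = ItemMap("HGNC:5", "HGNC")
    item.add("dc:identifier", Term("HGNC:5"))
    assert triplify(item, model, kb) > 0
    assert triplify(item, model, kb) == 0


def test_explicit_label_overrides_labelling_rule():
    model = _gene_model()
    kb = KnowledgeBase(instance_ns=NS)
    item = ItemMap("HGNC:5", "HGNC")
    item.add("rdfs:label", Term("BRCA2"))
    triplify(item, model, kb)
    subject = URIRef(mint_item_uri("HGNC", "HGNC:5", NS))
    assert [str(o) for o in kb.graph.objects(subject, RDFS.label)] == ["BRCA2"]


def test_unresolvable_predicate_curie_is_a_build_error():
    model = _gene_model()
    kb = KnowledgeBase(instance_ns=NS)
    item = ItemMap("HGNC:5", "HGNC")
    item.add("mystery:prop", Term("x"))
    with pytest.raises(BuildError, match="mystery"):
        triplify(item, model, kb)


# ---------------------------------------------------------------------------
# cache / complete / map
# ---------------------------------------------------------------------------

def _csv_resource(path, selectors, **kw):
    kw.setdefault("extra", {"kb:header": ["true"]})
    return _resource(selectors, endpoint=path.absolute().as_uri(), **kw)


def test_cache_creates_one_item_per_distinct_key(tmp_path, gene_csv):
    model = minimal_gene_model(gene_csv)
    kb = KnowledgeBase.for_model(model)
    frag = run_cache(model.resources["HGNC"], model, kb)
    n_rows = len(gene_csv.read_text().strip().splitlines()) - 1
    assert frag.records_seen == n_rows
    assert frag.items_created == n_rows


def test_cache_on_empty_source_is_clean(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("id,symbol\n")
    model = minimal_gene_model(path)
    kb = KnowledgeBase.for_model(model)
    frag = run_cache(model.resources["HGNC"], model, kb)
    assert frag.items_created == 0 and not frag.errors


def test_cache_merges_duplicate_identifiers(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text("id,symbol\nG1,BRCA2\nG1,ALT9\n")
    model = minimal_gene_model(path)
    kb = KnowledgeBase.for_model(model)
    frag = run_cache(model.resources["HGNC"], model, kb)
    assert frag.items_created == 1
    subject = URIRef(mint_item_uri("HGNC", "G1",
                                   model.config.base_namespace))
    symbols = {str(o) for o in kb.graph.objects(
        subject, URIRef(model.config.base_namespace + "symbol"))}
    assert symbols == {"BRCA2", "ALT9"}


def _built_gene_kb(gene_csv):
    model = minimal_gene_model(gene_csv)
    kb = KnowledgeBase.for_model(model)
    run_cache(model.resources["HGNC"], model, kb)
    return model, kb


def test_complete_per_item_appends_without_creating_items(tmp_path, gene_csv):
    model, kb = _built_gene_kb(gene_csv)
    docs = tmp_path / "docs"
    docs.mkdir()
    ids = ["HGNC:1101", "HGNC:11998", "HGNC:3430"]
    # files carry the raw identifier; the fetch URL percent-encodes it
    for gid in ids[:2]:  # only two items get documents
        (docs / f"{gid}.xml").write_text(
            f"<gene><approved>SYM-{gid[-4:]}</approved></gene>")
    res = _resource(
        [Selector(query="approved/text()", properties=["seed:approved"],
                  is_key=True)],
        key="names", kind="xml", method="complete", extends_key="HGNC",
        endpoint=docs.absolute().as_uri() + "/#replace#.xml")
    items_before = len(list(kb.graph.subjects(
        RDF.type, VOCAB.classes["Item"], unique=True)))
    frag = run_complete(res, model, kb)
    items_after = len(list(kb.graph.subjects(
        RDF.type, VOCAB.classes["Item"], unique=True)))
    assert items_after == items_before  # conservation
    assert frag.items_created == 0
    assert frag.statements_added == 2  # one appended statement per document
    assert frag.skips == 1 and len(frag.errors) == 1  # missing third doc


def test_complete_join_mode_matches_items_by_key_value(tmp_path, gene_csv):
    model, kb = _built_gene_kb(gene_csv)
    extra = tmp_path / "extra.csv"
    extra.write_text("id,name\nHGNC:1101,breast cancer 2\n"
                     "HGNC:9999,unknown gene\n")
    res = _csv_resource(
        extra,
        [Selector(query="0", properties=["dc:identifier"], is_key=True),
         Selector(query="1", properties=["seed:approvedName"])],
        key="names", method="complete", extends_key="HGNC")
    frag = run_complete(res, model, kb)
    assert frag.items_created == 0
    subject = URIRef(mint_item_uri("HGNC", "HGNC:1101",
                                   model.config.base_namespace))
    assert str(kb.graph.value(
        subject, URIRef(model.config.base_namespace + "approvedName"))) == \
        "breast cancer 2"
    # the unmatched row creates nothing
    stray = URIRef(mint_item_uri("HGNC", "HGNC:9999",
                                 model.config.base_namespace))
    assert (stray, None, None) not in kb.graph


def test_complete_with_no_existing_items_fetches_nothing(tmp_path):
    model = _gene_model()
    model.resources["R"] = res = _resource(
        [Selector(query="x/text()", properties=["seed:p"], is_key=True)],
        kind="xml", method="complete", extends_key="HGNC",
        endpoint="file:///nonexistent/#replace#.xml")
    kb = KnowledgeBase.for_model(model)
    frag = run_complete(res, model, kb)
    assert frag.records_seen == 0 and not frag.errors


def test_map_links_existing_items_and_skips_missing(tmp_path, gene_csv):
    model, kb = _built_gene_kb(gene_csv)
    model.concepts["UniProt"] = ConceptDef(key="UniProt", entity_key="Gene")
    for acc in ("P51587", "P04637"):
        triplify(ItemMap(acc, "UniProt"), model, kb)
    pairs = tmp_path / "pairs.csv"
    pairs.write_text("acc,gene\nP51587,HGNC:1101\nP04637,HGNC:11998\n"
                     "P99999,HGNC:1101\n")
    res = _csv_resource(
        pairs,
        [Selector(query="0", properties=["dc:identifier"], is_key=True),
         Selector(query="1", properties=["kb:isAssociatedTo"])],
        key="map", method="map", concept_key="UniProt", extends_key="HGNC")
    frag = run_map(res, model, kb)
    assert frag.links_created == 2
    assert frag.skips == 1  # P99999 item does not exist
    src = URIRef(mint_item_uri("UniProt", "P51587",
                               model.config.base_namespace))
    tgt = URIRef(mint_item_uri("HGNC", "HGNC:1101",
                               model.config.base_namespace))
    assoc = VOCAB.predicates["isAssociatedTo"]
    assert (src, assoc, tgt) in kb.graph
    assert (tgt, assoc, src) in kb.graph  # mirrored
    # map adds no literal properties
    assert frag.statements_added == 2 * frag.links_created


def test_map_with_empty_list_creates_no_links(tmp_path, gene_csv):
    model, kb = _built_gene_kb(gene_csv)
    pairs = tmp_path / "pairs.csv"
    pairs.write_text("acc,gene\n")
    res = _csv_resource(
        pairs,
        [Selector(query="0", properties=["dc:identifier"], is_key=True),
         Selector(query="1", properties=["kb:isAssociatedTo"])],
        key="map", method="map", concept_key="HGNC", extends_key="HGNC")
    assert run_map(res, model, kb).links_created == 0


# ---------------------------------------------------------------------------
# whole-seed builds
# ---------------------------------------------------------------------------

def test_zero_resource_build_writes_only_structure():
    model = _gene_model()
    kb = KnowledgeBase.for_model(model)
    report = build_seed(model, kb)
    assert report.total_items == 0
    assert report.structural_statements == len(kb)
    assert (URIRef(NS + "concept_HGNC"), RDF.type,
            VOCAB.classes["Concept"]) in kb.graph
    # seed includes the entity, and the inverse is materialised
    seed = URIRef(NS + "seed")
    entity = URIRef(NS + "entity_Gene")
    assert (seed, VOCAB.predicates["includes"], entity) in kb.graph
    assert (entity, VOCAB.predicates["isIncludedIn"], seed) in kb.graph


def test_report_totals_are_the_sum_of_fragments(built):
    kb, report = built
    assert report.total_statements == report.structural_statements + \
        sum(f.statements_added for f in report.fragments)
    assert report.total_statements == len(kb)


def test_build_is_idempotent(bundle):
    from kbseed import build_bundle
    kb1, _ = build_bundle(bundle, use_http=False)
    kb2, _ = build_bundle(bundle, use_http=False)
    from kbseed.engine import build_seed as _noop  # noqa: F401
    # build once more into the same store: nothing changes
    import copy
    from rdflib import Graph
    from kbseed.fixtures import AUX_ENDPOINT_TOKEN
    from kbseed.engine import BuildContext
    aux = Graph().parse(bundle.aux_graph_path, format="turtle")
    model = copy.deepcopy(bundle.model)
    build_seed(model, kb2, BuildContext(services={AUX_ENDPOINT_TOKEN: aux}))
    assert isomorphic(kb1.graph, kb2.graph)


def test_statement_count_law_against_brute_force(tmp_path):
    """Cache statements = sum over records of |values| x |properties| plus
    the structural constant per item, on a generated CSV <= 100 rows."""
    import csv as _csv
    import random
    rng = random.Random(7)
    rows = [[f"G{i}", f"SYM{i}", f"note {rng.randint(0, 9)}"]
            for i in range(97)]
    path = tmp_path / "law.csv"
    with path.open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["id", "symbol", "note"])
        writer.writerows(rows)
    model = minimal_gene_model(path)
    res = model.resources["HGNC"]
    res.selectors.append(Selector(query="2", properties=["seed:note",
                                                         "dc:description"]))
    kb = KnowledgeBase.for_model(model)
    frag = run_cache(res, model, kb)

    # brute-force counter, straight from the source rows
    expected_pairs = 0
    for row in rows:
        expected_pairs += 1 * 2   # column 0 -> dc:identifier, dc:source
        expected_pairs += 1 * 1   # column 1 -> seed:symbol
        expected_pairs += 1 * 2   # column 2 -> seed:note, dc:description
    expected = expected_pairs + STRUCTURAL_TRIPLES_PER_ITEM * len(rows)
    assert frag.statements_added == expected
    assert frag.items_created == len(rows)


def test_every_item_has_exactly_one_concept_after_build(built_kb):
    assert audit_concept_membership(built_kb) == []


def test_failed_resource_does_not_abort_the_build(gene_csv):
    model = minimal_gene_model(gene_csv)
    model.concepts["Broken"] = ConceptDef(key="Broken", entity_key="Gene")
    model.entities["Gene"].concept_keys.append("Broken")
    model.resources["Broken"] = _resource(
        [Selector(query="0", properties=["dc:identifier"], is_key=True)],
        key="Broken", concept_key="Broken",
        endpoint="file:///does/not/exist.csv")
    kb = KnowledgeBase.for_model(model)
    report = build_seed(model, kb)
    assert not report.ok
    by_key = {f.resource: f for f in report.fragments}
    assert by_key["Broken"].failed
    assert by_key["HGNC"].items_created == 3
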