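"""Deterministic offline fixtures emulating public biomedical sources.

Everything here is synthetic: identifiers mimic the *shapes* of real ones
(6-digit disease numbers, ``HGNC:<n>`` gene ids, ``[OPQ][0-9A-Z]{5}``
protein accessions, 4-character structure ids, ...) so that URI
sanitization and cross-linking paths are exercised, but no real content is
mirrored.  The same spec and random seed always produce byte-identical
files, so every other module can be tested without network access.

The flagship generator, :func:`generate_fixture_seed`, writes a complete
seed bundle — properties file, setup graph, CSV/XML/SQLite/SPARQL sources
and a manifest predicting record, item and link counts — wired as a
rare-disease integration chain across eleven concepts
(disease → gene → protein → structure/domain/pharmacogenomics → literature)
using all four connector kinds and all three integration methods.
"""

from __future__ import annotations

import copy
import json
import random
import sqlite3
import string
import urllib.parse
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS

from .engine import BuildContext, BuildReport, KnowledgeBase, build_seed
from .errors import ValidationError
from .model import (
    BridgeDef,
    ConceptDef,
    EntityDef,
    ResourceDef,
    SeedConfig,
    SeedModel,
    Selector,
)
from .server import SeedServer
from .setup_io import serialize_model

DEFAULT_CONCEPTS = (
    "OMIM", "Orphanet", "HGNC", "Entrez", "UniProt",
    "PDB", "PROSITE", "InterPro", "PharmGKB", "PubMed", "MeSH",
)

_ENTITY_OF = {
    "OMIM": "Disease", "Orphanet": "Disease", "MeSH": "Disease",
    "HGNC": "Gene", "Entrez": "Gene",
    "UniProt": "Protein", "PDB": "Protein", "PROSITE": "Protein",
    "InterPro": "Protein", "PharmGKB": "Protein",
    "PubMed": "Literature",
}

AUX_ENDPOINT_TOKEN = "#endpoint:aux#"
_AUX_NS = "http://example.org/xmap#"


@dataclass
class FixtureSpec:
    """Study conditions for fixture generation.

    Defaults are sized for a desk-scale integration chain: a handful of
    diseases, one-to-three genes each, one or two proteins per gene and a
    few cross-references per protein — enough to populate every concept and
    exercise every join, while building in well under a second.
    """

    random_seed: int = 42
    n_diseases: int = 4
    genes_per_disease: tuple[int, int] = (1, 3)
    proteins_per_gene: tuple[int, int] = (1, 2)
    xrefs_per_protein: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"PDB": (1, 3), "PROSITE": (1, 2),
                                 "InterPro": (1, 2), "PharmGKB": (1, 1),
                                 "MeSH": (1, 2)})
    concept_list: tuple[str, ...] = DEFAULT_CONCEPTS
    output_dir: str | Path = "fixture-seed"

    def __post_init__(self) -> None:
        if self.n_diseases < 0:
            raise ValidationError("n_diseases must be >= 0")
        for lo, hi in (self.genes_per_disease, self.proteins_per_gene,
                       *self.xrefs_per_protein.values()):
            if lo < 0 or hi < lo:
                raise ValidationError("count ranges must satisfy 0 <= lo <= hi")


class _IdFactory:
    """Unique, deterministically random identifiers in realistic shapes."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self._seen: set[str] = set()

    def _unique(self, make) -> str:
        while True:
            candidate = make()
            if candidate not in self._seen:
                self._seen.add(candidate)
                return candidate

    def omim(self):
        return self._unique(lambda: str(self.rng.randint(100000, 619999)))

    def orphanet(self):
        return self._unique(lambda: f"ORPHA:{self.rng.randint(10, 99999)}")

    def hgnc(self):
        return self._unique(lambda: f"HGNC:{self.rng.randint(1, 49999)}")

    def symbol(self):
        return self._unique(lambda: "".join(
            self.rng.choices(string.ascii_uppercase, k=self.rng.randint(3, 5)))
            + str(self.rng.randint(1, 9)))

    def uniprot(self):
        return self._unique(lambda: self.rng.choice("OPQ") + "".join(
            self.rng.choices(string.digits + string.ascii_uppercase, k=5)))

    def pdb(self):
        return self._unique(lambda: self.rng.choice(string.digits[1:]) + "".join(
            self.rng.choices(string.ascii_uppercase + string.digits, k=3)))

    def prosite(self):
        return self._unique(lambda: f"PS{self.rng.randint(0, 99999):05d}")

    def interpro(self):
        return self._unique(lambda: f"IPR{self.rng.randint(0, 999999):06d}")

    def pharmgkb(self):
        return self._unique(lambda: f"PA{self.rng.randint(100, 99999)}")

    def mesh(self):
        return self._unique(lambda: f"D{self.rng.randint(0, 999999):06d}")

    def entrez(self):
        return self._unique(lambda: str(self.rng.randint(1, 199999)))

    def pubmed(self):
        return self._unique(lambda: str(self.rng.randint(1000000, 39999999)))


_WORDS = ("hereditary", "familial", "congenital", "juvenile", "autosomal",
          "recessive", "dominant", "syndromic", "progressive", "atypical")
_NOUNS = ("dystrophy", "ataxia", "neuropathy", "myopathy", "dysplasia",
          "anemia", "deafness", "cardiomyopathy", "ichthyosis", "porphyria")


@dataclass
class _World:
    """The ground-truth relational structure behind every generated file."""

    diseases: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    proteins: list[dict] = field(default_factory=list)


def _generate_world(spec: FixtureSpec) -> _World:
    rng = random.Random(spec.random_seed)
    ids = _IdFactory(rng)
    world = _World()
    for _ in range(spec.n_diseases):
        disease = {
            "omim": ids.omim(),
            "orpha": ids.orphanet(),
            "name": f"{rng.choice(_WORDS)} {rng.choice(_NOUNS)}",
            "genes": [],
        }
        for _ in range(rng.randint(*spec.genes_per_disease)):
            gene = {
                "hgnc": ids.hgnc(),
                "symbol": ids.symbol(),
                "entrez": ids.entrez(),
                "pubmeds": [ids.pubmed() for _ in range(rng.randint(1, 2))],
                "proteins": [],
            }
            for _ in range(rng.randint(*spec.proteins_per_gene)):
                protein = {"acc": ids.uniprot(),
                           "name": f"{gene['symbol']} protein",
                           "gene": gene["hgnc"],
                           "xrefs": {}}
                for target, (lo, hi) in sorted(spec.xrefs_per_protein.items()):
                    maker = getattr(ids, target.lower())
                    protein["xrefs"][target] = [
                        maker() for _ in range(rng.randint(lo, hi))]
                gene["proteins"].append(protein)
                world.proteins.append(protein)
            disease["genes"].append(gene)
            world.genes.append(gene)
        world.diseases.append(disease)
    return world


def _write_csv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    import csv as _csv
    with path.open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def generate_hgnc_csv(spec: FixtureSpec) -> tuple[Path, dict]:
    """Write a gene-list CSV (column 0 = gene identifier, column 1 =
    approved symbol) plus a manifest of row and distinct-id counts."""
    world = _generate_world(spec)
    out = Path(spec.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [[g["hgnc"], g["symbol"]] for g in world.genes]
    path = out / "hgnc.csv"
    _write_csv(path, ["hgnc_id", "approved_symbol"], rows)
    manifest = {"rows": len(rows),
                "distinct_ids": len({r[0] for r in rows})}
    (out / "hgnc.manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return path, manifest


def _protein_entry_xml(protein: dict) -> str:
    xrefs = "".join(
        f'    <dbReference type="{target}" id="{xid}"/>\n'
        for target, xids in sorted(protein["xrefs"].items()) for xid in xids)
    return (f'  <entry>\n'
            f'    <accession>{protein["acc"]}</accession>\n'
            f'    <name>{protein["name"]}</name>\n'
            f'    <gene>{protein["gene"]}</gene>\n'
            f'{xrefs}  </entry>\n')


def generate_protein_xml(spec: FixtureSpec) -> tuple[dict[str, Path], dict]:
    """Write one XML document per gene, each with one ``entry`` node per
    protein carrying accession, name and cross-reference elements."""
    world = _generate_world(spec)
    out = Path(spec.output_dir) / "proteins"
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest: dict[str, dict] = {}
    for gene in world.genes:
        doc = '<?xml version="1.0" encoding="UTF-8"?>\n<uniprot>\n'
        doc += "".join(_protein_entry_xml(p) for p in gene["proteins"])
        doc += "</uniprot>\n"
        safe = urllib.parse.quote(gene["hgnc"], safe="")
        path = out / f"{safe}.xml"
        path.write_text(doc)
        paths[gene["hgnc"]] = path
        manifest[gene["hgnc"]] = {
            "entries": len(gene["proteins"]),
            "xrefs": sum(len(x) for p in gene["proteins"]
                         for x in p["xrefs"].values()),
        }
    return paths, manifest


def minimal_gene_model(csv_path: str | Path,
                       namespace: str = "http://example.org/genes/"
                       ) -> SeedModel:
    """The smallest useful configuration: one Gene entity, one HGNC
    concept, one cache CSV resource with two selectors — column 0 feeds
    ``dc:source`` and ``dc:identifier`` (the key), column 1 the symbol."""
    config = SeedConfig(name="gene-seed", base_namespace=namespace)
    model = SeedModel(config=config)
    model.entities["Gene"] = EntityDef(key="Gene", label="Gene",
                                       concept_keys=["HGNC"])
    model.concepts["HGNC"] = ConceptDef(key="HGNC", entity_key="Gene",
                                        label="HGNC", resource_refs=["HGNC"])
    model.resources["HGNC"] = ResourceDef(
        key="HGNC", kind="csv", concept_key="HGNC",
        endpoint=Path(csv_path).absolute().as_uri(), connector_hint="kb:CSV",
        extra={"kb:header": ["true"]},
        selectors=[
            Selector(query="0", properties=["dc:identifier", "dc:source"],
                     is_key=True, key="csv_HGNC_id"),
            Selector(query="1", properties=["seed:symbol"],
                     key="csv_HGNC_symbol"),
        ])
    return model


@dataclass
class FixtureBundle:
    """A generated, buildable seed: configuration, sources and manifest."""

    spec: FixtureSpec
    root: Path
    config: SeedConfig
    model: SeedModel
    manifest: dict
    aux_graph_path: Path


def _sel(query: str, properties: list[str], is_key: bool = False,
         key: str = "") -> Selector:
    return Selector(query=query, properties=properties, is_key=is_key, key=key)


def generate_fixture_seed(spec: FixtureSpec) -> FixtureBundle:
    """Generate the full multi-concept bundle (see module docstring).

    The returned model chains cache, complete and map resources over CSV,
    XML, SQL and SPARQL sources; the manifest predicts per-resource record
    counts, per-concept item counts and per-map link counts by closed-form
    bookkeeping over the generated world.
    """
    required = {"OMIM", "HGNC", "UniProt"}
    if not required <= set(spec.concept_list):
        raise ValidationError(
            f"concept_list must include at least {sorted(required)}")
    world = _generate_world(spec)
    root = Path(spec.output_dir)
    src = root / "sources"
    (src / "uniprot").mkdir(parents=True, exist_ok=True)
    (src / "pubmed").mkdir(parents=True, exist_ok=True)

    config = SeedConfig(
        name="rare-disease-seed",
        version="1.0",
        description="synthetic rare-disease integration chain",
        environment="test",
        base_namespace="http://example.org/rds/",
        prefixes={},
    )
    (root / "config.json").write_text(json.dumps({
        "name": config.name, "version": config.version,
        "description": config.description, "environment": config.environment,
        "namespace": config.base_namespace, "prefixes": config.prefixes,
        "ontologies": [],
    }, indent=2, sort_keys=True))

    # ---- source files -------------------------------------------------
    morbid_rows = [[d["omim"], d["name"], g["hgnc"], g["symbol"]]
                   for d in world.diseases for g in d["genes"]]
    _write_csv(src / "morbidmap.csv",
               ["omim_id", "disease_name", "hgnc_id", "gene_symbol"],
               morbid_rows)
    _write_csv(src / "genes.csv", ["hgnc_id", "symbol"],
               [[g["hgnc"], g["symbol"]] for g in world.genes])
    _write_csv(src / "gene_names.csv", ["hgnc_id", "approved_name"],
               [[g["hgnc"], f"{g['symbol']} protein-coding gene"]
                for g in world.genes])
    _write_csv(src / "orphanet.csv", ["orpha_id", "label", "omim_id"],
               [[d["orpha"], d["name"], d["omim"]] for d in world.diseases])
    mesh_ids = [x for p in world.proteins for x in p["xrefs"].get("MeSH", [])]
    _write_csv(src / "mesh.csv", ["mesh_id", "term"],
               [[m, f"term {m}"] for m in mesh_ids])
    _write_csv(src / "protein_mesh.csv", ["accession", "mesh_id"],
               [[p["acc"], m] for p in world.proteins
                for m in p["xrefs"].get("MeSH", [])])

    db_path = src / "proteins.db"
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    con.execute("CREATE TABLE proteins "
                "(accession TEXT, name TEXT, hgnc TEXT)")
    con.executemany("INSERT INTO proteins VALUES (?,?,?)",
                    [(p["acc"], p["name"], p["gene"]) for p in world.proteins])
    con.commit()
    con.close()

    doc = '<?xml version="1.0" encoding="UTF-8"?>\n<uniprot>\n'
    doc += "".join(_protein_entry_xml(p) for p in world.proteins)
    doc += "</uniprot>\n"
    (src / "proteins.xml").write_text(doc)

    for p in world.proteins:
        (src / "uniprot" / f"{p['acc']}.xml").write_text(
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<entry>\n  <accession>{p["acc"]}</accession>\n'
            f'  <fullName>{p["name"]} full</fullName>\n</entry>\n')
    pubmed_ids = [pm for g in world.genes for pm in g["pubmeds"]]
    for g in world.genes:
        for pm in g["pubmeds"]:
            (src / "pubmed" / f"{pm}.xml").write_text(
                '<?xml version="1.0" encoding="UTF-8"?>\n'
                f'<article>\n  <title>Findings on {g["symbol"]} '
                f'({pm})</title>\n</article>\n')

    aux = Graph()
    AUX = Namespace(_AUX_NS)
    aux.bind("ex", AUX)
    for i, g in enumerate(world.genes):
        node = URIRef(f"urn:genemap:{i}")
        aux.add((node, RDF.type, AUX.GeneMap))
        aux.add((node, AUX.entrez, Literal(g["entrez"])))
        aux.add((node, AUX.hgnc, Literal(g["hgnc"])))
        for j, pm in enumerate(g["pubmeds"]):
            pnode = URIRef(f"urn:pubmap:{i}:{j}")
            aux.add((pnode, RDF.type, AUX.PubMap))
            aux.add((pnode, AUX.entrez, Literal(g["entrez"])))
            aux.add((pnode, AUX.pubmed, Literal(pm)))
    aux_path = src / "entrez.ttl"
    aux_path.write_text(aux.serialize(format="turtle"))

    # ---- model --------------------------------------------------------
    model = SeedModel(config=config)
    entities = ("Disease", "Gene", "Protein", "Literature")
    for ent in entities:
        model.entities[ent] = EntityDef(key=ent, label=ent)
    for concept in spec.concept_list:
        entity = _ENTITY_OF.get(concept, "Disease")
        model.concepts[concept] = ConceptDef(
            key=concept, entity_key=entity, label=concept)
        model.entities[entity].concept_keys.append(concept)
    for ent in model.entities.values():
        ent.concept_keys.sort()

    def furi(p: Path) -> str:
        return p.absolute().as_uri()

    aux_prefix = f"PREFIX ex: <{_AUX_NS}>\n"

    def add(res: ResourceDef) -> None:
        model.resources[res.key] = res
        model.concepts[res.concept_key].resource_refs.append(res.key)

    add(ResourceDef(
        key="OMIM", kind="csv", concept_key="OMIM", order=10,
        endpoint=furi(src / "morbidmap.csv"), connector_hint="kb:CSV",
        extra={"kb:header": ["true"]},
        selectors=[_sel("0", ["dc:identifier"], is_key=True),
                   _sel("1", ["rdfs:label"])]))
    add(ResourceDef(
        key="HGNC", kind="csv", concept_key="HGNC", order=20,
        endpoint=furi(src / "genes.csv"), connector_hint="kb:CSV",
        extra={"kb:header": ["true"]},
        selectors=[_sel("0", ["dc:identifier", "dc:source"], is_key=True),
                   _sel("1", ["seed:symbol"])]))
    add(ResourceDef(
        key="HGNC_names", kind="csv", concept_key="HGNC", order=25,
        method="complete", extends_key="HGNC",
        endpoint=furi(src / "gene_names.csv"),
        extra={"kb:header": ["true"]},
        selectors=[_sel("0", ["dc:identifier"], is_key=True),
                   _sel("1", ["seed:approvedName"])]))
    add(ResourceDef(
        key="OMIM_genes", kind="csv", concept_key="OMIM", order=30,
        method="map", extends_key="HGNC",
        endpoint=furi(src / "morbidmap.csv"),
        extra={"kb:header": ["true"]},
        selectors=[_sel("0", ["dc:identifier"], is_key=True),
                   _sel("2", ["kb:isAssociatedTo"])]))
    if "Orphanet" in spec.concept_list:
        add(ResourceDef(
            key="Orphanet", kind="csv", concept_key="Orphanet", order=15,
            endpoint=furi(src / "orphanet.csv"),
            extra={"kb:header": ["true"]},
            selectors=[_sel("0", ["dc:identifier"], is_key=True),
                       _sel("1", ["rdfs:label"])]))
        add(ResourceDef(
            key="Orphanet_OMIM", kind="csv", concept_key="Orphanet",
            order=35, method="map", extends_key="OMIM",
            endpoint=furi(src / "orphanet.csv"),
            extra={"kb:header": ["true"]},
            selectors=[_sel("0", ["dc:identifier"], is_key=True),
                       _sel("2", ["kb:isAssociatedTo"])]))
    add(ResourceDef(
        key="UniProt", kind="sql", concept_key="UniProt", order=40,
        endpoint=f"sqlite://{db_path.absolute()}", connector_hint="kb:SQL",
        query_text="SELECT accession, name, hgnc FROM proteins "
                   "ORDER BY accession",
        selectors=[_sel("accession", ["dc:identifier"], is_key=True),
                   _sel("name", ["seed:proteinName"])]))
    add(ResourceDef(
        key="UniProt_HGNC", kind="sql", concept_key="UniProt", order=45,
        method="map", extends_key="HGNC",
        endpoint=f"sqlite://{db_path.absolute()}",
        query_text="SELECT accession, hgnc FROM proteins ORDER BY accession",
        selectors=[_sel("accession", ["dc:identifier"], is_key=True),
                   _sel("hgnc", ["kb:isAssociatedTo"])]))
    add(ResourceDef(
        key="UniProt_details", kind="xml", concept_key="UniProt", order=50,
        method="complete", extends_key="UniProt",
        endpoint=furi(src / "uniprot") + "/#replace#.xml",
        selectors=[_sel("accession/text()", ["dc:identifier"], is_key=True),
                   _sel("fullName/text()", ["seed:fullName"])]))
    for xref_concept in ("PDB", "PROSITE", "InterPro", "PharmGKB"):
        if xref_concept not in spec.concept_list:
            continue
        add(ResourceDef(
            key=xref_concept, kind="xml", concept_key=xref_concept,
            order=60, endpoint=furi(src / "proteins.xml"),
            connector_hint="kb:XML",
            extra={"kb:recordPath":
                   [f"//dbReference[@type='{xref_concept}']"]},
            selectors=[_sel("@id", ["dc:identifier"], is_key=True)]))
    if "Entrez" in spec.concept_list:
        add(ResourceDef(
            key="Entrez", kind="sparql", concept_key="Entrez", order=70,
            endpoint=AUX_ENDPOINT_TOKEN, connector_hint="kb:SPARQL",
            query_text=aux_prefix + "SELECT ?entrez WHERE { ?m a ex:GeneMap ;"
                                    " ex:entrez ?entrez } ORDER BY ?entrez",
            selectors=[_sel("entrez", ["dc:identifier"], is_key=True)]))
        add(ResourceDef(
            key="Entrez_HGNC", kind="sparql", concept_key="Entrez", order=75,
            method="map", extends_key="HGNC", endpoint=AUX_ENDPOINT_TOKEN,
            query_text=aux_prefix + "SELECT ?entrez ?hgnc WHERE { ?m a "
                                    "ex:GeneMap ; ex:entrez ?entrez ; "
                                    "ex:hgnc ?hgnc } ORDER BY ?entrez",
            selectors=[_sel("entrez", ["dc:identifier"], is_key=True),
                       _sel("hgnc", ["kb:isAssociatedTo"])]))
    if "PubMed" in spec.concept_list:
        add(ResourceDef(
            key="PubMed", kind="sparql", concept_key="PubMed", order=80,
            endpoint=AUX_ENDPOINT_TOKEN,
            query_text=aux_prefix + "SELECT ?pmid WHERE { ?m a ex:PubMap ; "
                                    "ex:pubmed ?pmid } ORDER BY ?pmid",
            selectors=[_sel("pmid", ["dc:identifier"], is_key=True)]))
        add(ResourceDef(
            key="PubMed_details", kind="xml", concept_key="PubMed", order=85,
            method="complete", extends_key="PubMed",
            endpoint=furi(src / "pubmed") + "/#replace#.xml",
            selectors=[_sel("title/text()", ["dc:title"], is_key=True)]))
    if "MeSH" in spec.concept_list:
        add(ResourceDef(
            key="MeSH", kind="csv", concept_key="MeSH", order=90,
            endpoint=furi(src / "mesh.csv"), extra={"kb:header": ["true"]},
            selectors=[_sel("0", ["dc:identifier"], is_key=True),
                       _sel("1", ["rdfs:label"])]))
        add(ResourceDef(
            key="UniProt_MeSH", kind="csv", concept_key="UniProt", order=95,
            method="map", extends_key="MeSH",
            endpoint=furi(src / "protein_mesh.csv"),
            extra={"kb:header": ["true"]},
            selectors=[_sel("0", ["dc:identifier"], is_key=True),
                       _sel("1", ["kb:isAssociatedTo"])]))

    model.bridges["UniProt"] = BridgeDef(
        key="UniProt", concept_key="UniProt",
        pattern="https://www.uniprot.org/uniprot/#replace#")
    model.concepts["UniProt"].bridge_refs.append("UniProt")
    for con_def in model.concepts.values():
        con_def.resource_refs.sort()

    # ---- manifest (closed-form counts from the world) ------------------
    n_pairs = len(morbid_rows)
    items = {
        "OMIM": len(world.diseases),
        "HGNC": len(world.genes),
        "UniProt": len(world.proteins),
    }
    if "Orphanet" in spec.concept_list:
        items["Orphanet"] = len(world.diseases)
    if "Entrez" in spec.concept_list:
        items["Entrez"] = len(world.genes)
    if "PubMed" in spec.concept_list:
        items["PubMed"] = len(pubmed_ids)
    if "MeSH" in spec.concept_list:
        items["MeSH"] = len(mesh_ids)
    for xref_concept in ("PDB", "PROSITE", "InterPro", "PharmGKB"):
        if xref_concept in spec.concept_list:
            items[xref_concept] = sum(
                len(p["xrefs"].get(xref_concept, [])) for p in world.proteins)
    records = {
        "OMIM": n_pairs, "HGNC": len(world.genes),
        "HGNC_names": len(world.genes), "OMIM_genes": n_pairs,
        "UniProt": len(world.proteins), "UniProt_HGNC": len(world.proteins),
        "UniProt_details": len(world.proteins),
    }
    links = {"OMIM_genes": n_pairs, "UniProt_HGNC": len(world.proteins)}
    if "Orphanet" in spec.concept_list:
        records["Orphanet"] = len(world.diseases)
        records["Orphanet_OMIM"] = len(world.diseases)
        links["Orphanet_OMIM"] = len(world.diseases)
    if "Entrez" in spec.concept_list:
        records["Entrez"] = len(world.genes)
        records["Entrez_HGNC"] = len(world.genes)
        links["Entrez_HGNC"] = len(world.genes)
    if "PubMed" in spec.concept_list:
        records["PubMed"] = len(pubmed_ids)
        records["PubMed_details"] = len(pubmed_ids)
    if "MeSH" in spec.concept_list:
        records["MeSH"] = len(mesh_ids)
        records["UniProt_MeSH"] = len(mesh_ids)
        links["UniProt_MeSH"] = len(mesh_ids)
    for xref_concept in ("PDB", "PROSITE", "InterPro", "PharmGKB"):
        if xref_concept in spec.concept_list:
            records[xref_concept] = items[xref_concept]

    manifest = {"items": items, "records": records, "links": links,
                "concepts": len(spec.concept_list)}
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    (root / "setup.ttl").write_text(serialize_model(model, "turtle"))

    return FixtureBundle(spec=spec, root=root, config=config, model=model,
                         manifest=manifest, aux_graph_path=aux_path)


def build_bundle(bundle: FixtureBundle, use_http: bool = True
                 ) -> tuple[KnowledgeBase, BuildReport]:
    """Build a generated bundle into a fresh knowledge base.

    SPARQL resources point at the bundle's auxiliary graph; with
    ``use_http`` (default) an in-process loopback endpoint is spawned so
    the genuine HTTP SPARQL connector path is exercised, otherwise the
    graph is queried directly in process.
    """
    aux = Graph()
    aux.parse(bundle.aux_graph_path, format="turtle")
    model = copy.deepcopy(bundle.model)
    kb = KnowledgeBase.for_model(model)
    if use_http and any(r.endpoint == AUX_ENDPOINT_TOKEN
                        for r in model.resources.values()):
        with SeedServer(KnowledgeBase.wrap(aux)) as server:
            for res in model.resources.values():
                if res.endpoint == AUX_ENDPOINT_TOKEN:
                    res.endpoint = server.sparql_url
            report = build_seed(model, kb)
    else:
        ctx = BuildContext(services={AUX_ENDPOINT_TOKEN: aux})
        report = build_seed(model, kb, ctx)
    return kb, report


def populated_concepts(kb: KnowledgeBase, model: SeedModel) -> list[str]:
    """Concept keys having at least one item in the store."""
    has_concept = kb.vocab.predicates["hasConcept"]
    out = []
    for key in model.concepts:
        concept_uri = URIRef(model.config.base_namespace + "concept_" + key)
        if next(kb.graph.subjects(has_concept, concept_uri), None) is not None:
            out.append(key)
    return out


# ---------------------------------------------------------------------------
# federation fixtures: three endpoints answering one question together
# ---------------------------------------------------------------------------

_FED1 = Namespace("http://example.org/fed1#")
_FED3 = Namespace("http://example.org/fed3#")
_FEDP = "http://example.org/fedprotein/"


@dataclass
class FederationFixture:
    """Three graphs (gene labels / gene→protein links / protein→structure
    and descriptor links) plus the SERVICE query that spans them."""

    graphs: list[Graph]
    query_template: str
    target_symbol: str
    expected_pairs: set[tuple[str, str]]

    def query(self, ep1: str, ep2: str, ep3: str) -> str:
        return (self.query_template
                .replace("{ep1}", ep1).replace("{ep2}", ep2)
                .replace("{ep3}", ep3))


def generate_federation_bundles(spec: FixtureSpec,
                                vocab=None) -> FederationFixture:
    """Replicate the three-endpoint topology: endpoint 1 resolves a gene
    symbol to its label, endpoint 2 maps the label to protein identifiers,
    endpoint 3 maps proteins to structure (PDB-style) and descriptor
    (MeSH-style) identifiers."""
    from .vocab import VOCAB
    vocab = vocab or VOCAB
    world = _generate_world(spec)
    if not world.genes:
        raise ValidationError("federation fixture needs at least one gene")
    g1, g2, g3 = Graph(), Graph(), Graph()
    g1.bind("ex1", _FED1)
    g3.bind("ex3", _FED3)
    assoc = vocab.predicates["isAssociatedTo"]
    for i, gene in enumerate(world.genes):
        label = f"{gene['symbol']} gene"
        node = URIRef(f"http://example.org/fed1/gene/{i}")
        g1.add((node, _FED1.symbol, Literal(gene["symbol"])))
        g1.add((node, RDFS.label, Literal(label)))
        gnode = URIRef(f"http://example.org/fed2/gene/{i}")
        g2.add((gnode, RDFS.label, Literal(label)))
        for protein in gene["proteins"]:
            pnode = URIRef(_FEDP + protein["acc"])
            g2.add((gnode, assoc, pnode))
            for pdb in protein["xrefs"].get("PDB", []):
                g3.add((pnode, _FED3.pdb, Literal(pdb)))
            for mesh in protein["xrefs"].get("MeSH", []):
                g3.add((pnode, _FED3.mesh, Literal(mesh)))

    target = world.genes[0]
    expected = {(pdb, mesh)
                for p in target["proteins"]
                for pdb in p["xrefs"].get("PDB", [])
                for mesh in p["xrefs"].get("MeSH", [])}
    query = f"""PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX ex1: <{_FED1}>
PREFIX ex3: <{_FED3}>
PREFIX kb: <{vocab.namespace}>
SELECT ?pdb ?mesh WHERE {{
  SERVICE <{{ep1}}> {{ ?g ex1:symbol "{target['symbol']}" . ?g rdfs:label ?label . }}
  SERVICE <{{ep2}}> {{ ?gene rdfs:label ?label . ?gene kb:isAssociatedTo ?protein . }}
  SERVICE <{{ep3}}> {{ ?protein ex3:pdb ?pdb . ?protein ex3:mesh ?mesh . }}
}}"""
    return FederationFixture(graphs=[g1, g2, g3], query_template=query,
                             target_symbol=target["symbol"],
                             expected_pairs=expected)


def spawn_test_endpoints(bundles: list) -> list[SeedServer]:
    """Start one in-process SPARQL endpoint per bundle (a Graph,
    KnowledgeBase or built FixtureBundle); caller stops the returned
    servers (or use :func:`live_endpoints`)."""
    servers = []
    for bundle in bundles:
        if isinstance(bundle, KnowledgeBase):
            kb = bundle
        elif isinstance(bundle, Graph):
            kb = KnowledgeBase.wrap(bundle)
        elif isinstance(bundle, FixtureBundle):
            kb, _ = build_bundle(bundle)
        else:
            raise TypeError(f"cannot serve {type(bundle).__name__}")
        servers.append(SeedServer(kb).start())
    return servers


@contextmanager
def live_endpoints(bundles: list):
    """Context manager over :func:`spawn_test_endpoints` yielding the list
    of running servers and guaranteeing teardown."""
    servers = spawn_test_endpoints(bundles)
    try:
        yield servers
    finally:
        for server in servers:
            server.stop()
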