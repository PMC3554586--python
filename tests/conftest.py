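"""Shared fixtures: every data file is generated at test time."""

from __future__ import annotations

import pytest

from kbseed import (
    FixtureSpec,
    KnowledgeBase,
    build_bundle,
    generate_fixture_seed,
    minimal_gene_model,
)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The full multi-concept fixture bundle (generated once)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_fixture_seed(FixtureSpec(output_dir=out))


@pytest.fixture(scope="session")
def built(bundle):
    """The bundle built into a knowledge base (with its report)."""
    return build_bundle(bundle)


@pytest.fixture(scope="session")
def built_kb(built) -> KnowledgeBase:
    return built[0]


@pytest.fixture()
def gene_csv(tmp_path):
    """A three-gene CSV with header, plus the matching minimal model."""
    path = tmp_path / "genes.csv"
    path.write_text(
        "hgnc_id,approved_symbol\n"
        "HGNC:1101,BRCA2\n"
        "HGNC:11998,TP53\n"
        "HGNC:3430,CDH1\n")
    return path


@pytest.fixture()
def gene_model(gene_csv):
    return minimal_gene_model(gene_csv)
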