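from __future__ import annotations

from pathlib import Path

import pytest

from diseasome import (
    FixtureConfig,
    generate_fixture,
    ingest,
    integrate,
)


def bundle_to_table(bundle) -> integrate.AssociationTable:
    """Run ingest + normalize + merge + label on an emitted bundle."""
    aliases = ingest.load_alias_table(bundle.aliases)
    umap = ingest.load_umls_map(bundle.umls_map)
    orpha = ingest.read_orphanet_xml(bundle.orphanet)
    omim = ingest.read_omim_genemap(bundle.omim)
    disgenet = ingest.read_disgenet_tsv(bundle.disgenet, umap)
    table = integrate.merge_sources(
        ingest.normalize_symbols(orpha.associations, aliases),
        ingest.normalize_symbols(omim.associations, aliases),
        ingest.normalize_symbols(disgenet.associations, aliases),
        orphanet_xref=orpha.omim_xref,
    )
    return integrate.label_categories(table)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory) -> tuple:
    """One default-scale bundle shared by read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_fixture(FixtureConfig(seed=11), out)


@pytest.fixture(scope="session")
def default_table(default_bundle):
    bundle, _ = default_bundle
    return bundle_to_table(bundle)
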