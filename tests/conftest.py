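import warnings

import pytest

from orthomap.expression_harmonization import (
    apply_qc,
    harmonize_genes,
    lognormalize,
    merge_species,
)
from orthomap.synthetic_fixtures import (
    FixtureConfig,
    build_bundle_table,
    simulate_fixture,
)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default two-species world: 200 genes, 3 cell types, 600 cells."""
    out = tmp_path_factory.mktemp("default_world")
    return simulate_fixture(FixtureConfig(seed=11), out)


@pytest.fixture(scope="session")
def default_table(default_bundle):
    return build_bundle_table(default_bundle)


@pytest.fixture(scope="session")
def quota_bundle(tmp_path_factory):
    """World whose intended tier counts are fixed quotas."""
    out = tmp_path_factory.mktemp("quota_world")
    cfg = FixtureConfig.from_tier_quotas(
        unique_db=20,
        protein_align=10,
        nucleotide_align=5,
        levenshtein=5,
        lowercase=5,
        seed=23,
    )
    return simulate_fixture(cfg, out)


@pytest.fixture(scope="session")
def merged_matrix(default_bundle, default_table):
    """QC'd, log-normalised, harmonised and merged joint matrix."""
    b = default_bundle
    fa = apply_qc(b.matrix_a, b.qc_thresholds)
    fb = apply_qc(b.matrix_b, b.qc_thresholds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ha = harmonize_genes(lognormalize(fa), default_table, side="source")
        hb = harmonize_genes(lognormalize(fb), default_table, side="target")
    return merge_species(ha, hb)
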