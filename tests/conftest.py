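"""Shared fixtures.

The full-pipeline runs (strong-signal, null and the repeat used for the
determinism check) are session-scoped: several tests inspect the same
fitted results rather than re-running the multi-minute CV pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from miralink.model import AssociationModel, PipelineConfig
from miralink.simulate import FixtureSpec, generate_tables, holdout_recovery_check

STRONG_SPEC = FixtureSpec(seed=1)  # 30 x 50, 3 blocks, within 0.5 / cross 0.02
NULL_SPEC = FixtureSpec(
    within_block_edge_prob=0.2, cross_block_edge_prob=0.2, seed=1
)
FIT_SEED = 1


@pytest.fixture(scope="session")
def strong_bundle():
    return generate_tables(STRONG_SPEC)


@pytest.fixture(scope="session")
def null_bundle():
    return generate_tables(NULL_SPEC)


@pytest.fixture(scope="session")
def strong_report(strong_bundle):
    """Full 5-fold CV pipeline on the planted-signal fixture."""
    return holdout_recovery_check(strong_bundle, seed=FIT_SEED)


@pytest.fixture(scope="session")
def null_report(null_bundle):
    """Full 5-fold CV pipeline on the signal-free fixture."""
    return holdout_recovery_check(null_bundle, seed=FIT_SEED)


@pytest.fixture(scope="session")
def strong_rerun(strong_bundle):
    """Independent second run with the same seed, for determinism checks."""
    model = AssociationModel.from_tables(
        strong_bundle.network,
        strong_bundle.gene_network,
        strong_bundle.disease_genes,
        strong_bundle.mirna_targets,
        strong_bundle.mirna_families,
        strong_bundle.mirna_clusters,
        strong_bundle.rsd,
        config=PipelineConfig.compact(),
    )
    return model.fit(seed=FIT_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
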