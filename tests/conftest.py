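"""Shared fixtures: a small synthetic cohort exercised by most test modules."""

import numpy as np
import pytest

from regdriver.pipeline import run_pipeline
from regdriver.synthetic import SyntheticConfig, generate_cohort

#: Scaled-down study conditions for unit tests (fast to generate and analyse).
SMALL_KW = dict(
    n_chromosomes=4,
    chrom_length=600_000,
    n_genes=80,
    n_samples=100,
    max_enhancer_distance=60_000,
    n_spiked_drivers=6,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SyntheticConfig(seed=42, **SMALL_KW))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return run_pipeline(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
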