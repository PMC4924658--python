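import numpy as np
import pytest

from sigdriver import (SimulationConfig, merge_on_shared_genes,
                       simulate_multistudy_expression)


@pytest.fixture(scope="session")
def small_scenario():
    """A 300-gene three-study cohort with planted DE, plus its truth."""
    cfg = SimulationConfig(n_genes=300, seed=5)
    return simulate_multistudy_expression(cfg)


@pytest.fixture(scope="session")
def merged_cohort(small_scenario):
    cohort, _ = small_scenario
    return merge_on_shared_genes(cohort.split_by_study())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
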