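import numpy as np
import pytest

from pollentx.simulate import (
    SimulationConfig,
    gen_annotation,
    gen_counts,
    expression_from_counts,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=200, n_tes=160)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return gen_annotation(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_annotation):
    gene_counts, te_counts, truth = gen_counts(small_config, small_annotation)
    return gene_counts, te_counts, truth


@pytest.fixture(scope="session")
def small_expression(small_counts, small_annotation):
    gene_counts, _, _ = small_counts
    return expression_from_counts(gene_counts, small_annotation)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
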