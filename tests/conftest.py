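import numpy as np
import pytest

from crossgex import (
    GeneSet,
    HUMAN_IN_VITRO,
    RAT_IN_VITRO,
    SimulationConfig,
    build_examples,
    fit_scaling,
    generate_cohort,
)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        n_compounds=3,
        n_genes=8,
        frac_constant_genes=0.25,
        replicate_noise_sd=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config, RAT_IN_VITRO, HUMAN_IN_VITRO)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        n_compounds=3,
        n_genes=8,
        frac_constant_genes=0.25,
        replicate_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return generate_cohort(noiseless_config, RAT_IN_VITRO, HUMAN_IN_VITRO)


@pytest.fixture(scope="session")
def tiny_examples(tiny_cohort):
    source, target = tiny_cohort
    genes = GeneSet("all", source.gene_ids)
    scalings = (fit_scaling(source, genes), fit_scaling(target, genes))
    return build_examples(source, target, genes, scalings)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
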