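import numpy as np
import pytest

from exocnv.simulate import SimulationConfig, simulate_cohort, write_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small end-to-end cohort: 40 regions, 20 samples, one causal deletion."""
    config = SimulationConfig(
        n_case=10, n_control=10, n_regions=40, region_length=200,
        causal_region_ids=["region_00020"], deletion_allele_freq=0.6,
        odds_ratio=1.5, batch_phenotype_confounding=0.3, seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def tiny_fixture_dir(tiny_cohort, tmp_path_factory):
    directory = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(tiny_cohort, directory)
    return directory, paths
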