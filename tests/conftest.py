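import logging

import pytest

from transomics.simulate import SimulationConfig, simulate_cohort

logging.getLogger("transomics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A small null cohort shared across association/pipeline tests."""
    cfg = SimulationConfig(
        n_samples=400,
        n_genes=60,
        features_per_gene_by_omics={"genotype": 2, "methylation": 2, "expression": 2},
        seed=11,
    )
    omics, covariates, feature_map, outcomes = simulate_cohort(cfg)
    return {
        "config": cfg,
        "omics": omics,
        "covariates": covariates,
        "feature_map": feature_map,
        "outcomes": outcomes,
    }
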