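import numpy as np
import pytest

from connfit import (
    RunConfig,
    SyntheticConfig,
    generate_dataset,
    make_parcellation,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale design: 8 modeled regions + 2 extra targets, 4 domains."""
    return SyntheticConfig(
        n_vertices=360,
        n_regions_per_hemisphere=4,
        n_extra_targets=2,
        n_subjects=2,
        n_runs=2,
        n_timepoints=80,
        n_domains=4,
        n_categories=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_parcellation(small_config):
    return make_parcellation(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_run_bundle(small_config):
    from connfit import run_pipeline

    cfg = RunConfig(synthetic=small_config, n_permutations=60, master_seed=7)
    with pytest.warns(RuntimeWarning):
        return run_pipeline(cfg)
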