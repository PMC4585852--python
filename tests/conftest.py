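import warnings

import pytest

from riborestore.config import RunConfig
from riborestore.simulate import SimulationConfig, simulate_all


def small_sim_config(**overrides) -> SimulationConfig:
    """A scaled-down study used by unit tests (fast; same structure)."""
    kwargs = dict(
        seed=11, n_genes=300, n_chrom=3, recurrent_region_count=6,
        region_width_genes=12, n_restore_up=12, n_restore_down=12,
        n_enhance_up=8, n_enhance_down=8, cohort_size=60, n_complexes=15,
        min_lines_per_region=8,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def fast_run_config() -> RunConfig:
    cfg = RunConfig()
    cfg.diffrep.rp_n_perm = 200
    cfg.diffrep.sam_n_perm = 30
    cfg.restore.n_boot = 100
    cfg.stoichiometry.n_boot = 100
    cfg.cna.n_perm_recurrence = 50
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_all(small_sim_config())


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study (the conditions the pipeline is specified
    to recover); shared by the acceptance tests."""
    return simulate_all(SimulationConfig())


@pytest.fixture(scope="session")
def default_summary(default_dataset):
    from riborestore.pipeline import run_pipeline
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(default_dataset, RunConfig())
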