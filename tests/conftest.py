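import numpy as np
import pytest

from dcmpeb.synthetic_cohort import (CohortSpec, ParadigmSpec,
                                     default_truth_template,
                                     generate_cohort, generate_paradigm)


@pytest.fixture(scope="session")
def paradigm():
    """Full-scale task: 2 runs x 12 blocks, 18 trials per block."""
    return ParadigmSpec()


@pytest.fixture(scope="session")
def design_events(paradigm):
    return generate_paradigm(paradigm)


@pytest.fixture(scope="session")
def design(design_events):
    return design_events[0]


@pytest.fixture(scope="session")
def short_paradigm():
    """Down-scaled task (1 run x 4 blocks) for fast inversion tests."""
    return ParadigmSpec(n_runs=1, blocks_per_run=4, go_blocks_per_run=2,
                        nogo_blocks_per_run=2, trials_per_go_block=9,
                        go_trials_per_nogo_block=6,
                        nogo_trials_per_nogo_block=3)


@pytest.fixture(scope="session")
def short_design(short_paradigm):
    return generate_paradigm(short_paradigm)[0]


@pytest.fixture(scope="session")
def template():
    return default_truth_template()


@pytest.fixture(scope="session")
def small_cohort(short_paradigm):
    spec = CohortSpec(n_subjects=6, n_female=3, master_seed=123)
    return generate_cohort(spec, short_paradigm)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
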