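import numpy as np
import pytest

from motionddm.hierarchy import filter_trials
from motionddm.synth import GeneratorConfig, StudyDesign, generate_behaviour


@pytest.fixture(scope="session")
def small_study():
    """2x4 participants, one task, default generator truth."""
    design = StudyDesign(n_per_group=4, tasks=("motion_coherence",))
    config = GeneratorConfig(seed=123)
    trials, truth = generate_behaviour(design, config)
    return design, config, trials, truth


@pytest.fixture(scope="session")
def filtered_small(small_study):
    _, _, trials, _ = small_study
    kept, report = filter_trials(trials)
    return kept, report


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
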