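import numpy as np
import pytest

from cnatai import PipelineConfig, SimulationParams
from cnatai.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared synthetic cohort: 20 samples, 2,000 probes, fixed seed."""
    params = SimulationParams(n_samples=20, n_probes=2000, seed=7)
    probe_map, profiles, clinical, truth = simulate_cohort(params)
    return params, probe_map, profiles, clinical, truth


@pytest.fixture(scope="session")
def segmented_small_cohort(small_cohort):
    from cnatai.segmentation import segment_cohort

    _, probe_map, profiles, _, _ = small_cohort
    return segment_cohort(profiles, probe_map, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
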