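"""Shared fixtures for the test suite."""

import numpy as np
import pytest
from hypothesis import settings

from isoribo import simulate as sim

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulated annotation with ground truth."""
    cfg = sim.SimulationConfig(seed=11, n_genes=12, mean_reads_per_orf=300)
    annotation, truth = sim.simulate_annotation(cfg)
    return cfg, annotation, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
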