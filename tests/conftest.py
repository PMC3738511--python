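import numpy as np
import pandas as pd
import pytest

from loopmix import EffectSpec, generate, make_loop_design


@pytest.fixture(scope="session")
def exp1_design():
    """Three groups of eight queens on twelve two-channel arrays."""
    return make_loop_design([("haplo", 8), ("win", 8), ("los", 8)], plex=12)


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment shared across read-only tests."""
    spec = EffectSpec(n_transcripts=60, fraction_de=0.2, seed=11,
                      baseline_mean=12.0)
    raw, design, truth = generate(spec)
    return raw, design, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
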