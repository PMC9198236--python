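import numpy as np
import pytest
from hypothesis import settings

import tplsim as t

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def stair_cfg():
    """Default 60-trial staircase at the 200 ms standard."""
    return t.StaircaseConfig(standard_T=200)


def flat_observer(wf: float, lapse: float = 0.0, condition=("empty", 200)):
    """Stationary observer: one condition, no learning."""
    return t.ObserverParams(
        participant="obs",
        group="EI",
        learning={condition: t.LearningParams.flat(wf)},
        lapse_rate=lapse,
    )


@pytest.fixture
def tiny_config():
    """One observer per group: fast end-to-end runs."""
    return t.ExperimentConfig(n_ei=1, n_fi=1)
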