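import numpy as np
import pytest

from ringfrap import SimulationConfig, correct_and_normalize, simulate_condition


@pytest.fixture
def noiseless_config():
    """Distortion-free acquisition: every downstream value is analytic."""
    return SimulationConfig(
        noise_sd=0.0,
        cell_cv=0.0,
        acq_bleach_per_frame=0.0,
        background_level=0.0,
        seed=11,
    )


@pytest.fixture
def sum_lt_one_params():
    """Kinetics with c_eq1 + c_eq2 < 1 (a fast-refilling unbound pool)."""
    return dict(c_eq1=0.6, c_eq2=0.35, koff1=0.05, koff2=0.004, r=0.2)


def normalized_traces(config: SimulationConfig):
    exps, truth = simulate_condition(config)
    return [correct_and_normalize(e) for e in exps], truth
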