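import dataclasses

import numpy as np
import pytest

from fearbold import CompetitionParams, ModelParams


@pytest.fixture
def neutral_params():
    """Exchangeable phenotypes: no energy cost, equal selection and capture."""
    return ModelParams(
        n_total=10,
        max_age=1,
        n_attacks=2,
        beta=1.0,
        p_capture_f=0.3,
        p_capture_b=0.3,
        energy_gain=10.0,
        energy_cost_escape=0.0,
        base_seed=42,
    )


@pytest.fixture
def asym_params():
    """Small asymmetric scenario used across predation/reproduction tests."""
    return ModelParams(
        n_total=10,
        max_age=3,
        n_attacks=2,
        n_disturbances=2,
        beta=0.5,
        p_capture_f=0.2,
        p_capture_b=0.6,
        energy_gain=10.0,
        energy_cost_escape=0.5,
        base_seed=7,
    )


@pytest.fixture
def competition_params():
    return CompetitionParams(
        r_f=2.4, r_b=1.8, a_ff=0.008, a_fb=0.010, a_bf=0.002, a_bb=0.012
    )


def make_params(**overrides) -> ModelParams:
    defaults = dict(
        n_total=10,
        max_age=2,
        n_attacks=2,
        beta=0.5,
        p_capture_f=0.2,
        p_capture_b=0.4,
        energy_gain=10.0,
        energy_cost_escape=0.2,
        base_seed=1,
    )
    defaults.update(overrides)
    return ModelParams(**defaults)


def rng(seed=0):
    return np.random.default_rng(seed)
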