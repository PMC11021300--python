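import numpy as np
import pytest

from extrot.cohort import (ChoicePolicy, CohortConfig, Distribution,
                           ParticipantProfile)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(**overrides) -> ParticipantProfile:
    base = dict(a_int=1000.0, b_int=2.0, sigma_rt=0.0, eps0_int=0.0,
                eps1_int=0.0, a_man=400.0, eps_man=0.0, rt_bias=0.0,
                policy=ChoicePolicy())
    base.update(overrides)
    return ParticipantProfile(**base)


def point_config(n=3, seed=0, **values) -> CohortConfig:
    defaults = dict(a_int=1000.0, b_int=2.0, sigma_rt=0.0, eps0_int=0.0,
                    eps1_int=0.0, a_man=400.0, eps_man=0.0, rt_bias=0.0,
                    beta0=0.0, beta_rt=0.0, beta_acc=0.0, beta_angle=0.0,
                    beta_stick=0.0)
    defaults.update(values)
    dists = {k: Distribution("point", v) for k, v in defaults.items()}
    return CohortConfig(n_participants=n, distributions=dists, seed=seed)
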