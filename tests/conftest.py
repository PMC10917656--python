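import numpy as np
import pytest

import distrl


@pytest.fixture(scope="session")
def static_trials():
    """One medium static session at ceiling accuracy (levels 1-4 chosen)."""
    return distrl.generate_static_task(600, accuracy=1.0, seed=101)


@pytest.fixture(scope="session")
def static_trials_98():
    return distrl.generate_static_task(600, accuracy=0.98, seed=102)


@pytest.fixture(scope="session")
def dynamic_trials():
    return distrl.generate_dynamic_task(600, seed=103)


@pytest.fixture(scope="session")
def coupled_dynamic_population(dynamic_trials):
    """Coupled population, moderate noise, all positive coding (for model fits)."""
    return distrl.make_population(
        dynamic_trials, 20, seed=104, noise_sd=1.25, negative_fraction=0.0
    )


def single_cue_trials(rewards):
    """Minimal dynamic-dialect table with one cue and a given reward stream."""
    import pandas as pd

    r = np.asarray(rewards, dtype=float)
    return pd.DataFrame(
        {
            "trial_index": np.arange(r.size),
            "cue_id": np.ones(r.size, dtype=int),
            "reward_level": r,
            "block_id": np.zeros(r.size, dtype=int),
            "delivered_reward": r,
        }
    )
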