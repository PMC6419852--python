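import numpy as np
import pytest

import invarmir as iv


@pytest.fixture(scope="session")
def tiny_study():
    """Small but informative study: 5 regulators, 8 targets, 3 environments,
    all regulators intervened so every parent is identifiable."""
    return iv.simulate_sem(
        p=5, t=8, parents_per_target=2, env_sizes=(60, 60, 60),
        gamma_scale=1.0, gamma_jitter=0.0, intervention_scale=2.0,
        intervened_regulators="all", seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
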