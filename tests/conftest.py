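import warnings

import numpy as np
import pytest

from paitraj.simulate import CohortConfig, generate_cohort

# statsmodels emits convergence chatter on tiny fits; keep test output readable
warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")


def zero_effects(k: int = 4) -> dict:
    """PAI effects switched off for both sexes (class mix equals the configured pi)."""
    return {s: {"active": (0.0,) * k, "spectator": (0.0,) * k} for s in ("male", "female")}


@pytest.fixture(scope="session")
def clean_cohort():
    """n=500 cohort, no spelling corruption: gold labels equal lexicon presence."""
    cfg = CohortConfig(n_persons=500, seed=5, corruption_rate=0.0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """n=2000 cohort under the default study conditions."""
    return generate_cohort(CohortConfig(n_persons=2000, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
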