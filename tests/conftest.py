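import numpy as np
import pytest

from movebias.estimators import StepSeries
from movebias.simulate import SimScenario, run_two_animal_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def consensus_replicate():
    """One standard two-animal replicate of the consensus model (2, 0.5)."""
    scenario = SimScenario(model="consensus", kappa1=2.0, kappa2=0.5)
    return run_two_animal_replicate(scenario, rng=np.random.default_rng(42))


@pytest.fixture
def random_series(rng):
    """Small random two-animal StepSeries with one target bearing."""
    n = 30
    return StepSeries(
        animal=np.repeat(["a", "b"], n // 2),
        t=np.tile(np.arange(n // 2), 2),
        y=rng.uniform(-np.pi, np.pi, n),
        psi1=rng.uniform(-np.pi, np.pi, n),
    )
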