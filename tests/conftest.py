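import numpy as np
import pandas as pd
import pytest

from coxval.model_spec import SurvivalSample
from coxval.synthetic_data import SimulationScenario, apparent_scenario, generate


@pytest.fixture
def toy_sample():
    """Six subjects, one covariate, mixed censoring, no ties."""
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 0, 1, 1, 0, 1],
            "x": [1.2, -0.4, 0.8, -1.1, 0.3, -0.6],
        }
    )
    return SurvivalSample(df, "time", "event")


@pytest.fixture(scope="session")
def sim_pair():
    """Self-consistent derivation/validation pair, n = 800 each."""
    scn = SimulationScenario(n_subjects=800, seed=20260918)
    return generate(scn)


@pytest.fixture(scope="session")
def bundle(sim_pair):
    """What the derivation arm would publish (L1 + L2 + L3)."""
    derivation, _ = sim_pair
    return apparent_scenario(derivation)


def make_censored_dataset(rng, n):
    """Random censored survival data with a weakly prognostic score."""
    pi = rng.normal(0, 1, n)
    t = rng.exponential(1.0 / np.exp(0.8 * pi))
    c = rng.exponential(1.5, n)
    return SurvivalSample(
        pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int), "_pi": pi}
        ),
        "time",
        "event",
    )
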