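import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pupmonitor import condition as cond
from pupmonitor import synthetic_data as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_config(seed: int = 11) -> sd.SimulationConfig:
    """Reduced 3-colony world (20 years, 40 pups measured per colony-year)
    used where the full 35-year default would only add runtime."""
    colonies = tuple(
        sd.ColonyConfig(
            name=c.name,
            baseline=c.baseline,
            decline_rate=c.decline_rate,
            sin_amplitude=c.sin_amplitude,
            sin_period=c.sin_period,
            episodic_drops={2000: 0.6},
            marking_fraction=c.marking_fraction,
            q_replicates=c.q_replicates,
            coverage=c.coverage,
            mortality_rate=c.mortality_rate,
            n_pups_measured=40,
            effects=c.effects,
        )
        for c in sd.default_config().colonies
    )
    return sd.SimulationConfig(seed=seed, start_year=1991, n_years=20, colonies=colonies)


@pytest.fixture(scope="session")
def small_dataset() -> sd.SyntheticDataset:
    return sd.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def scored_condition(small_dataset) -> tuple[pd.DataFrame, cond.AllometryFit]:
    return cond.add_condition_indices(small_dataset.biometrics)
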