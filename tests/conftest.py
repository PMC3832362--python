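import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def timelines(times, duration_min=30.0, interval_s=64.0):
    """Build a timelines table from event times (np.inf = censored)."""
    times = np.asarray(times, dtype=np.float64)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(times))],
            "time_min": np.where(np.isfinite(times), times, np.nan),
            "censored": ~np.isfinite(times),
        }
    )
    df.attrs["duration_min"] = duration_min
    df.attrs["interval_s"] = interval_s
    return df


@pytest.fixture(scope="session")
def induced_population():
    """A featurized induced SS-like population with ground truth (n=2500)."""
    from sicklekit.morphometry import featurize_events
    from sicklekit.simulate.population import PopulationConfig, sample_population

    events, truth = sample_population(PopulationConfig(n_events=2500, seed=101))
    feats = featurize_events(events)
    return feats, truth.reset_index(drop=True)


@pytest.fixture(scope="session")
def training_sets():
    from sicklekit.training import make_training_sets

    return make_training_sets(seed=7, n_per_set=120)
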