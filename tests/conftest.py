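import numpy as np
import pandas as pd
import pytest

from cmimpute import SimulationScenario, TrialDataset, simulate_trial


def make_long_df(outcomes, arms, baselines=None, ice_visits=None, strategies=None,
                 subject_ids=None, **extra):
    """Long-format frame from a per-subject outcome matrix (NaN = missing)."""
    Y = np.asarray(outcomes, dtype=float)
    n, J = Y.shape
    arms = list(arms)
    baselines = [0.0] * n if baselines is None else list(baselines)
    ice_visits = [np.nan] * n if ice_visits is None else list(ice_visits)
    strategies = ["MAR"] * n if strategies is None else list(strategies)
    subject_ids = [f"S{i+1}" for i in range(n)] if subject_ids is None else list(subject_ids)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, J),
            "arm": np.repeat(arms, J),
            "visit": np.tile(np.arange(1, J + 1), n),
            "outcome": Y.ravel(),
            "baseline": np.repeat(baselines, J),
            "ice_visit": np.repeat(ice_visits, J),
            "ice_strategy": np.repeat(strategies, J),
        }
    )
    for k, v in extra.items():
        df[k] = np.repeat(list(v), J)
    return df


@pytest.fixture
def make_dataset():
    def _make(*args, **kwargs):
        return TrialDataset(make_long_df(*args, **kwargs))
    return _make


@pytest.fixture(scope="session")
def small_trial():
    """One simulated trial (30/arm, alternative) with J2R-flagged ICEs."""
    sc = SimulationScenario(n_per_arm=30, hypothesis="alternative")
    return simulate_trial(sc, seed=42, ice_strategy="J2R")


@pytest.fixture(scope="session")
def medium_trial():
    """One simulated trial at the headline size (100/arm, null)."""
    sc = SimulationScenario(hypothesis="null")
    return simulate_trial(sc, seed=7, ice_strategy="J2R")
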