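import numpy as np
import pandas as pd
import pytest

from fairsent.synthetic_experiment import SimConfig, TrueParams, simulate_trials


@pytest.fixture
def tiny_trials() -> pd.DataFrame:
    """Hand-written six-trial table covering responses, fillers, and a
    non-response."""
    df = pd.DataFrame(
        {
            "participant_id": ["P1", "P1", "P2", "P2", "P1", "P2"],
            "item_id": ["W1", "W2", "W1", "W2", "F1", "F2"],
            "experiment": [1, 1, 1, 1, 1, 1],
            "condition": ["unmarked"] * 6,
            "pronoun_gender": ["feminine", "masculine"] * 3,
            "list_id": ["A", "A", "B", "B", "A", "B"],
            "trial_role": ["experimental"] * 4 + ["filler_good", "filler_bad"],
            "response": ["yes", "no", "yes", "none", "yes", "no"],
            "correct": pd.array([True, False, True, pd.NA, True, True], dtype="boolean"),
            "rt_ms": [1000.0, 1500.0, 2000.0, np.nan, 900.0, 1100.0],
        }
    )
    return df


@pytest.fixture(scope="session")
def uncorrelated_params() -> TrueParams:
    return TrueParams(intercept_correlation=0.0)


@pytest.fixture(scope="session")
def exp1_small(uncorrelated_params) -> pd.DataFrame:
    """One simulated experiment-1 dataset at a small crossed design."""
    cfg = SimConfig(
        experiment=1, n_participants=12, n_items=8, seed=314, true_params=uncorrelated_params
    )
    return simulate_trials(cfg)
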