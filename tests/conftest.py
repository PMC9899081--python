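import numpy as np
import pandas as pd
import pytest

from acx import synthetic as syn


@pytest.fixture(scope="session")
def vowel_trials():
    """Moderate-size vowel-task dataset shared across behavioral tests."""
    cfg = syn.BehaviorGenConfig(n_sessions=12, trials_per_session=150, seed=101)
    trials, truth = syn.gen_vowel_behavior(cfg)
    return trials, truth, cfg


@pytest.fixture(scope="session")
def small_ephys():
    """Small spiking dataset (fast); class balance as in the full generator."""
    cfg = syn.EphysGenConfig(n_units=40, seed=202)
    units, trial_table, truth = syn.gen_ephys_dataset(cfg)
    return units, trial_table, truth, cfg


def make_toy_trials(rows):
    """Build a minimal trial table from (treatment, temp, snr, correct) rows."""
    recs = []
    for i, (arm, temp, snr, correct) in enumerate(rows):
        recs.append(
            {
                "ferret": "F00",
                "session_id": f"s{i % 4}",
                "trial_index": i,
                "treatment": arm,
                "loop_temp_left_c": temp,
                "loop_temp_right_c": temp,
                "snr_db": snr,
                "level_db": 60.0,
                "is_correction": False,
                "responded": True,
                "correct": correct,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
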