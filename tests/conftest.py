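import numpy as np
import pandas as pd
import pytest

from stopplv import EpochSet, NeuralConfig, balanced_stop_trials, synthesize_epochs


@pytest.fixture(scope="session")
def gap_epochs():
    """120 successful-stop trials (60/hand) with a PLV hand contrast at T8-O2."""
    neural = NeuralConfig(pair_plv_targets={"T8-O2": {"RHR-SS": 0.90, "LHR-SS": 0.75}})
    trials = [t for t in balanced_stop_trials(60) if t.outcome == "SS"]
    return synthesize_epochs(trials, neural, seed=2024)


@pytest.fixture(scope="session")
def small_epochs():
    """40 stop trials (10 per hand x outcome) with the default coupling layout."""
    return synthesize_epochs(balanced_stop_trials(10), NeuralConfig(), seed=7)


@pytest.fixture()
def noise_epochs():
    """Pure-noise epochs: 12 trials, 4 channels, 750 samples at 500 Hz."""
    rng = np.random.default_rng(5)
    data = rng.normal(0, 2.0, (12, 4, 750))
    trials = pd.DataFrame(
        {
            "subject": ["S00"] * 6 + ["S01"] * 6,
            "hand": ["LHR", "RHR"] * 6,
            "outcome": ["SS", "SS", "FS", "FS"] * 3,
        }
    )
    return EpochSet(data, ["F3", "F4", "FZ", "CZ"], 500.0, -200.0, trials)
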