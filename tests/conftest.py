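import warnings

import pandas as pd
import pytest

from xtalk.simulate import simulate_study

SMALL_SIM = dict(
    n_source=12, n_target=8, n_background=30, edges_per_target=3, seed=11
)


@pytest.fixture(scope="session")
def small_study():
    """A small planted study shared by read-only tests."""
    return simulate_study(**SMALL_SIM)


@pytest.fixture()
def toy_counts():
    """3 genes x 4 samples, two diets at two timepoints (n=2 per cell)."""
    frame = pd.DataFrame(
        {
            "s1": [10, 100, 5],
            "s2": [12, 90, 6],
            "s3": [40, 110, 5],
            "s4": [38, 95, 7],
        },
        index=["g1", "g2", "g3"],
    )
    sheet = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "animal_id": ["a1", "a2", "a3", "a4"],
            "tissue": ["liver"] * 4,
            "diet": ["chow", "chow", "HFD", "HFD"],
            "time_weeks": [6, 6, 6, 6],
        }
    )
    return frame, sheet


@pytest.fixture(autouse=True)
def _quiet_balance_warning():
    """Silence the intentional source/target balance warning in tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="unbalanced analysis")
        yield
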