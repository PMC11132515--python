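import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_events(rows):
    """Build a validated-shape event table from (id, behavior, on, off) rows."""
    df = pd.DataFrame(rows, columns=["individual_id", "behavior", "onset_s",
                                     "offset_s"])
    df["session_id"] = "s1"
    df["location"] = "inside"
    df["bowls"] = 1
    df["condition"] = "together"
    return df


@pytest.fixture
def simple_events():
    return make_events([
        ("a", "feeding", 0.0, 1.0),
        ("a", "vigilance", 1.2, 2.0),
        ("b", "vigilance", 0.0, 2.0),
    ])
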