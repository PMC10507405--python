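import numpy as np
import pytest

from padeeg import default_emotion_table, load_reference_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """Bundled 42-visitor reference cohort (PAD scores + printed labels)."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def emotion_table():
    return default_emotion_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
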