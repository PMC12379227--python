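import numpy as np
import pytest

from sleepomics import Hypnogram, HypnogramSpec, gen_hypnogram


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def mixed_hypnogram():
    """Markov hypnogram with all three states present (2000 epochs, 5 s)."""
    return gen_hypnogram(
        HypnogramSpec(epoch_length_s=5.0, total_duration_s=10000.0, seed=11)
    )


def make_hypnogram(labels, epoch_length_s=5.0):
    return Hypnogram(labels=np.asarray(labels, dtype=object),
                     epoch_length_s=epoch_length_s)


@pytest.fixture
def nrem_session_hypnogram():
    """WAKE flanks around one long NREM bout (3000 s NREM)."""
    return make_hypnogram(["WAKE"] * 12 + ["NREM"] * 600 + ["WAKE"] * 12)
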