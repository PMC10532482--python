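import numpy as np
import pytest

from its2delimit.synthetic import default_tulasnella_like, generate_family


@pytest.fixture(scope="session")
def small_family():
    """Three species of six sequences, two planted CBCs per species."""
    return generate_family(n_species=3, seqs_per_species=6, seed=11)


@pytest.fixture(scope="session")
def study_family():
    """The built-in 143-sequence two-clade study family."""
    return default_tulasnella_like()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
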