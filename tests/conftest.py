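import numpy as np
import pytest

from wrkyfam import io, synthetic


@pytest.fixture(scope="session")
def table1():
    """The packaged 79-gene roster."""
    return io.load_packaged_table1()


@pytest.fixture(scope="session")
def references():
    """Deterministic synthetic labelled reference domains."""
    return synthetic.make_reference_set(np.random.default_rng(20170720))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
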