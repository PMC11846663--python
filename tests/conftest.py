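import numpy as np
import pytest

from guideset.scoring import load_default_table


@pytest.fixture(scope="session")
def cfd_table():
    table = load_default_table()
    assert table is not None, "bundled penalty table missing"
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_601)


def random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
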