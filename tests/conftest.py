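import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kmertune.readset_io import Read, ReadSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_readset(sequences, prefix="r"):
    return ReadSet([Read(f"{prefix}{i}", s) for i, s in enumerate(sequences)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_readset(rng):
    """120 uniform-random 60 bp reads."""
    bases = np.array(list("ACGT"))
    return make_readset("".join(row) for row in bases[rng.integers(0, 4, (120, 60))])
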