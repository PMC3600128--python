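import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sib_pair_pedigree():
    """500 two-child families."""
    from stoprace.quantgen import Pedigree

    fams = tuple((f"F{i}", (f"F{i}_0", f"F{i}_1")) for i in range(500))
    return Pedigree(families=fams)
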