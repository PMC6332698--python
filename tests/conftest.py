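import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prionscore.scales import load_amyloid_matrix, load_hydropathy, load_prion_propensity
from prionscore.seqio import STANDARD_AA, ProteinRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scale():
    return load_prion_propensity()


@pytest.fixture(scope="session")
def kd_scale():
    return load_hydropathy()


@pytest.fixture(scope="session")
def matrix():
    return load_amyloid_matrix()


@pytest.fixture
def random_record():
    """Factory: uniformly random standard-alphabet record of given length."""

    def make(length=120, seed=0, id_="rand"):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(STANDARD_AA), size=length))
        return ProteinRecord(id=f"{id_}_{length}_{seed}", sequence=seq)

    return make
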