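import numpy as np
import pytest

from prioncons.seqio import ProteinRecord
from prioncons.synthetic_data import SimConfig, simulate_family

AA20 = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_protein(rng):
    def make(length, species="spX", pid="p", comp=None):
        seq = "".join(rng.choice(list(AA20), size=length, p=comp))
        return ProteinRecord(id=pid, species=species, seq=seq)

    return make


@pytest.fixture
def small_family(rng):
    """One simulated ortholog family at the default study conditions."""
    return simulate_family(SimConfig(seed=11), rng)


@pytest.fixture
def slow_domain_config():
    """Low-rate configuration: orthologs stay ≥ 80% identical."""
    return SimConfig(flank_sub_rate=0.03, indel_rate=0.002, seed=5)
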