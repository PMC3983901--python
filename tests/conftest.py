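import numpy as np
import pytest

from pbnctrl.markov_engine import (
    CostSpec,
    build_tpm,
    controlled_tpm,
    default_partition,
)
from pbnctrl.pbn_model import cell_cycle_pbn, random_pbn


@pytest.fixture
def rng():
    return np.random.default_rng(20240403)


@pytest.fixture(scope="session")
def two_state():
    """1-gene identity network with p=0.1: P = [[.9,.1],[.1,.9]], U = {1}."""
    P = np.array([[0.9, 0.1], [0.1, 0.9]])
    Pa = controlled_tpm(P, 1)
    spec = CostSpec(np.array([True, False]), lam=0.2)
    return P, Pa, spec


@pytest.fixture(scope="session")
def cell_cycle():
    pbn = cell_cycle_pbn()
    P = build_tpm(pbn)
    Pa = controlled_tpm(P, 3)  # CycA is the control gene
    spec = CostSpec(default_partition(5, flavor="cycd-rb-down"), lam=0.2)
    return pbn, P, Pa, spec


@pytest.fixture
def three_gene(rng):
    """A random 3-gene PBN with its TPM and target-down cost structure."""
    pbn = random_pbn(3, rng=rng)
    P = build_tpm(pbn)
    spec = CostSpec(default_partition(3, target_gene=1), lam=0.2)
    return pbn, P, spec
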