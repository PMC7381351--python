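import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from baeocomp.simdata import SimConfig, simulate_strain_set


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated strain set shared across tests."""
    return simulate_strain_set(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast strain set with every corruption mechanism active."""
    cfg = SimConfig(n_families=24, codon_length=100, seed=7)
    return simulate_strain_set(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_coding_seq(rng, n_codons):
    """Random stop-free coding sequence for fixtures."""
    from baeocomp._codon import CODONS, IS_STOP

    ok = [c for i, c in enumerate(CODONS) if not IS_STOP[i]]
    return "".join(ok[i] for i in rng.integers(0, len(ok), size=n_codons))
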