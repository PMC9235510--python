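import numpy as np
import pytest

from molpotency.chem import parse_smiles
from molpotency.synthetic import SyntheticConfig, generate_molecules


@pytest.fixture(scope="session")
def ethanol():
    return parse_smiles("CCO", "ethanol")


@pytest.fixture(scope="session")
def benzene():
    return parse_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def random_molecules():
    """A pool of ~120 structurally varied valid molecules."""
    cfg = SyntheticConfig(n_molecules=120, seed=11)
    molecules, _ = generate_molecules(cfg)
    return molecules


@pytest.fixture(scope="session")
def random_fingerprints(random_molecules):
    from molpotency.chem import circular_fingerprint

    return np.stack([circular_fingerprint(m).bits for m in random_molecules])
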