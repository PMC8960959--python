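import numpy as np
import pytest

from extrapolab import molgen, responses
from extrapolab.descriptors import descriptor_matrix
from extrapolab.molgen import DegradationConfig


@pytest.fixture(scope="session")
def seed_mols():
    return dict(molgen.seed_library())


@pytest.fixture(scope="session")
def apix_small(seed_mols):
    """A quick 60-molecule apixaban degradation set for unit tests."""
    cfg = DegradationConfig(target_set_size=60, seed=123)
    return molgen.generate_set(seed_mols["apixaban"], cfg, "apixaban", 1)


@pytest.fixture(scope="session")
def apix_set_300(seed_mols):
    """One study-sized apixaban set."""
    cfg = DegradationConfig(target_set_size=300, seed=7)
    return molgen.generate_set(seed_mols["apixaban"], cfg, "apixaban", 1)


@pytest.fixture(scope="session")
def apix_300_skel_mw(apix_set_300):
    """(X, y): skeleton-spheres matrix and MW response for the 300-set."""
    X = descriptor_matrix(apix_set_300.molecules, "SkelSpheres")
    y = np.array([responses.mol_weight(m) for m in apix_set_300.molecules])
    return X, y


@pytest.fixture(scope="session")
def dict_corpus(seed_mols):
    """A 500-molecule corpus (apixaban + rosuvastatin products) for
    fragment-dictionary tests."""
    mols = []
    for name, seed in (("apixaban", 5), ("rosuvastatin", 6)):
        cfg = DegradationConfig(target_set_size=250, seed=seed)
        mols.extend(molgen.generate_set(seed_mols[name], cfg, name, 1).molecules)
    assert len(mols) == 500
    return mols
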