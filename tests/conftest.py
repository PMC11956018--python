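import numpy as np
import pytest

from hrsrdc import AlignmentTensor, generate_rdc_targets, helix_rdc_definitions, make_toy_helix


@pytest.fixture(scope="session")
def helix():
    return make_toy_helix(n_residues=7)


@pytest.fixture(scope="session")
def helix_rdcs(helix):
    return helix_rdc_definitions(helix)


@pytest.fixture(scope="session")
def demo_tensor():
    # weak anisotropy typical of partial alignment, all five components active
    return AlignmentTensor.from_components([2e-4, 1e-4, -5e-5, 3e-5, 8e-5])


@pytest.fixture(scope="session")
def targeted_rdcs(helix, demo_tensor):
    return generate_rdc_targets(helix, demo_tensor, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def helix_bond_vectors(helix, helix_rdcs):
    return np.array([helix.bond_vector(r.atoms) for r in helix_rdcs])
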