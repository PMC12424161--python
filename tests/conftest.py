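import numpy as np
import pytest

from pfaseval import build_correspondence, define_pocket, make_toy_complex


@pytest.fixture(scope="session")
def toy_native():
    return make_toy_complex(seed=1, n_residues=20, ligand_chain_length=8)


@pytest.fixture(scope="session")
def toy_pocket(toy_native):
    return define_pocket(toy_native)


@pytest.fixture(scope="session")
def identity_corr(toy_native):
    return build_correspondence(toy_native, toy_native)


def random_rigid(rng):
    """A random proper rotation (QR-based) and translation, for invariance tests."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=0.8, size=3)
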