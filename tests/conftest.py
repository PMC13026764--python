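import numpy as np
import pytest

from enscompare import ConformationEnsemble, resolve_selection
from enscompare.synthetic import HarmonicSpec, make_backbone, make_harmonic_ensemble


@pytest.fixture(scope="session")
def helix10():
    """10-residue ideal-helix reference (topology, coordinates)."""
    return make_backbone(10)


@pytest.fixture(scope="session")
def helix10_calpha(helix10):
    topo, _ = helix10
    return resolve_selection(topo, "calpha")


@pytest.fixture(scope="session")
def harmonic_small():
    """Small seeded harmonic ensemble for quick structural tests."""
    spec = HarmonicSpec(n_res=10, n_frames=200, sigma_profile=0.4, seed=7)
    return make_harmonic_ensemble(spec)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR decomposition."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture
def rng():
    return np.random.default_rng(42)
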