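import numpy as np
import pytest

from insulin_conformers.synth import build_class_toy, build_ideal_helix


@pytest.fixture(scope="session")
def class1_toy():
    return build_class_toy("CLASS1")


@pytest.fixture(scope="session")
def class2_toy():
    return build_class_toy("CLASS2")


@pytest.fixture(scope="session")
def alpha_helix12():
    return build_ideal_helix("alpha", 12)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
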