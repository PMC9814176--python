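import numpy as np
import pytest

from otsgp.markers import MarkerMatrix
from otsgp.synthdata import golden_fixture


@pytest.fixture(scope="session")
def toy6():
    return golden_fixture("toy6")


@pytest.fixture(scope="session")
def mini_hel():
    return golden_fixture("mini-hel")


@pytest.fixture(scope="session")
def mini_usp():
    return golden_fixture("mini-usp")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hybrid_panel(rng, n=8, m=20):
    """Small all-hybrid marker matrix with no missing data, all polymorphic."""
    while True:
        dosage = rng.integers(0, 3, size=(n, m)).astype(float)
        if (dosage.min(axis=0) < dosage.max(axis=0)).all():
            return MarkerMatrix(
                [f"H{i}" for i in range(n)], [f"M{j}" for j in range(m)],
                dosage, ["hybrid"] * n,
            )
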