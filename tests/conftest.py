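import numpy as np
import pytest

from afscreen.simulate import ClassModel, gen_rri


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_train():
    """Well-separated two-class training vectors (low- vs high-dispersion)."""
    noaf = gen_rri(ClassModel(label=-1, cv=0.03), 20, seed=100, id_prefix="tr-noaf")
    af = gen_rri(ClassModel(label=+1, cv=0.4), 20, seed=101, id_prefix="tr-af")
    return noaf + af


@pytest.fixture(scope="session")
def separable_test():
    noaf = gen_rri(ClassModel(label=-1, cv=0.03), 15, seed=200, id_prefix="te-noaf")
    af = gen_rri(ClassModel(label=+1, cv=0.4), 15, seed=201, id_prefix="te-af")
    return noaf + af


def random_vectors(seed, n, lengths=(1, 60)):
    """Unlabeled random positive sample vectors of varying length."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        d = int(rng.integers(lengths[0], lengths[1] + 1))
        out.append(rng.lognormal(mean=0.0, sigma=0.3, size=d))
    return out
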