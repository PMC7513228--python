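import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n, cond=10.0):
    """Random SPD matrix with eigenvalues in [1/cond, 1]."""
    Q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    w = rng.uniform(1.0 / cond, 1.0, size=n)
    return (Q * w) @ Q.T


def random_psd(rng, n, rank=None):
    """Random PSD matrix A^T A, optionally rank deficient."""
    r = rank or n
    A = rng.normal(size=(r, n))
    return A.T @ A
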