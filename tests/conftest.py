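import numpy as np
import pytest

from qolnet._kernels import warm_up


@pytest.fixture(scope="session", autouse=True)
def _compiled_kernels():
    """Pay the JIT compilation cost once per session."""
    warm_up()


@pytest.fixture
def random_correlation():
    """Factory for random well-conditioned correlation matrices."""

    def make(p: int, rng: np.random.Generator) -> np.ndarray:
        a = rng.normal(size=(p, p + 3))
        s = a @ a.T + 0.5 * p * np.eye(p)
        d = np.sqrt(np.diag(s))
        r = s / np.outer(d, d)
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        return r

    return make
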