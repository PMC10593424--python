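import numpy as np
import pytest


@pytest.fixture(scope="session", autouse=True)
def _compile_kernels():
    """Pay the JIT compilation cost once, before any timed work."""
    from gsam._fast import warm_up

    warm_up()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_prox_instance(rng, n_max=25, centered=True):
    """A random univariate subproblem on an untied uniform grid."""
    n = int(rng.integers(5, n_max + 1))
    x = np.sort(rng.uniform(-2.5, 2.5, n))
    r = rng.standard_normal(n) * 1.5
    if centered:
        r -= r.mean()
    lam1 = float(rng.uniform(0.01, 0.6))
    lam2 = float(rng.uniform(0.0, 0.4))
    return r, x, lam1, lam2
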