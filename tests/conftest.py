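import numpy as np
import pytest

from spotclone import CloneSet, Hyperparams


@pytest.fixture
def tiny_clones() -> CloneSet:
    """Two clones over two mutations: base clone and one mutated clone."""
    C = np.array([[0.0, 1.0], [0.0, 0.5]])
    F = np.array([0.4, 0.6])
    return CloneSet(C=C, F=F)


@pytest.fixture
def tiny_hyper() -> Hyperparams:
    return Hyperparams(zeta=2.0, r=0.09, p=1.0, Lambda=10.0)

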