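import numpy as np
import pytest

from covcomb import LabeledMatrix, PartialSample


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_spd(n, rng, scale=1.0):
    """A well-conditioned random SPD matrix (for use as a kernel/Sigma)."""
    A = rng.standard_normal((n, max(n + 2, 2 * n)))
    M = A @ A.T / A.shape[1]
    return scale * (M + 0.1 * np.eye(n))


def labeled_spd(labels, rng, scale=1.0, **kw):
    return LabeledMatrix(list(labels), random_spd(len(labels), rng, scale), **kw)


@pytest.fixture
def trio_pedigree_rows():
    return [("F1", "0", "0"), ("F2", "0", "0"), ("X", "F1", "F2")]


def partial(labels, values, weight=1.0, **kw):
    return PartialSample(LabeledMatrix(list(labels), values, **kw), weight=weight)
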