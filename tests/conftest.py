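import numpy as np
import pytest

from isresplus import BoundsBox, Cluster


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_box2():
    return BoundsBox(np.zeros(2), np.ones(2) * 10.0)


def make_cluster(center_x, objective, member_x, eta=None):
    """Assemble a Cluster directly from points and an objective callable."""
    center_x = np.asarray(center_x, dtype=float)
    member_x = np.asarray(member_x, dtype=float)
    n = center_x.size
    eta = np.ones(n) if eta is None else np.asarray(eta, dtype=float)
    return Cluster(
        center_x=center_x,
        center_f=float(objective(center_x)),
        center_eta=eta.copy(),
        member_x=member_x,
        member_f=np.array([objective(x) for x in member_x], dtype=float),
        member_eta=np.tile(eta, (member_x.shape[0], 1)),
    )
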