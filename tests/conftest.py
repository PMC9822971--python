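import numpy as np
import pytest

from rfdseg.decision_table import CandidateBreakpointSet, DecisionTable
from rfdseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def worked_example():
    """The 4-pixel two-class table whose rough-fuzzy quantities are known in
    closed form: brightness (10,10,20,20), labels (0,0,1,1), memberships
    A_1=(.9,.9,.2,.2), A_2=(.1,.1,.8,.8), candidates {10, 20}."""
    table = DecisionTable(
        brightness=np.array([10.0, 10.0, 20.0, 20.0]),
        labels=np.array([0, 0, 1, 1]),
        num_classes=2,
        value_range=(0.0, 255.0),
    )
    u = np.array([[0.9, 0.1], [0.9, 0.1], [0.2, 0.8], [0.2, 0.8]])
    candidates = CandidateBreakpointSet(np.array([10.0, 20.0]))
    return table, u, candidates


@pytest.fixture(scope="session")
def small_phantom():
    """A 16^3 noisy phantom with all four classes present."""
    return generate_phantom(PhantomSpec(shape=(16, 16, 16), seed=11))


def random_table(rng, n=100, m=3, n_values=12):
    """A random decision table over a limited brightness alphabet."""
    values = np.sort(rng.choice(np.arange(0, 256), size=n_values, replace=False))
    brightness = rng.choice(values, size=n).astype(np.float64)
    labels = rng.integers(0, m, size=n)
    return DecisionTable(
        brightness=brightness,
        labels=labels,
        num_classes=m,
        value_range=(0.0, 255.0),
    )


def random_membership(rng, brightness, m):
    """Row-stochastic memberships that depend only on brightness."""
    uniq, inverse = np.unique(brightness, return_inverse=True)
    rows = rng.random((len(uniq), m))
    rows /= rows.sum(axis=1, keepdims=True)
    return rows[inverse]
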