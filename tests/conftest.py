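import numpy as np
import pytest

from sgleeg import GroupStructure, Standardizer, indicator_from_labels
from sgleeg.synthetic import DesignSimSpec, gen_design


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_instance(seed, n=50, p_groups=4, d=3, M=2, magnitude=1.2,
                  active=(0, 1)):
    """Standardized random grouped logistic instance for solver tests."""
    X, y, beta_true, gi = gen_design(DesignSimSpec(
        n=n, p_groups=p_groups, d=d, M=M, active_groups=active,
        magnitude=magnitude, seed=seed))
    groups = GroupStructure(gi)
    Y, classes = indicator_from_labels(y)
    Z = Standardizer.fit(X).transform(X)
    return Z, Y, groups, classes


@pytest.fixture
def small_instance():
    return make_instance(seed=7)
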