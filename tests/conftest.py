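import numpy as np
import pytest

import calfort as cf


@pytest.fixture(scope="session")
def dri():
    return cf.DRITable.default()


@pytest.fixture(scope="session")
def npw_group(dri):
    """Nonpregnant women 19 <= age < 31 (EAR 800, UL 2500)."""
    return dri.lookup(25.0, "female")


def make_dist(values, weights=None, group=None):
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    return cf.UsualIntakeDistribution(
        group=group, values_mg=values, weights=np.asarray(weights, dtype=float)
    )


def expand_by_weights(values, weights):
    """Brute-force expansion of an integer-weighted sample."""
    out = []
    for v, w in zip(values, weights):
        out.extend([v] * int(w))
    return np.asarray(out, dtype=float)
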