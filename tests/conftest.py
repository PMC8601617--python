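import numpy as np
import pytest

import commcoal as cc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def env4():
    """Four-resource environment at the default supply and dilution."""
    return cc.Environment.table_defaults(4)


@pytest.fixture
def small_community(rng):
    """Random 3-species, 4-resource community with per-species metabolisms."""
    spec = cc.SamplingSpec(s=3, m=4, k_c=0.3, k_f=0.4, n_pref_mean=2.0,
                           leakage=0.4, shared_metabolism=False, seed=7)
    return cc.build_community(spec)


def single_consumer_community(leakage=0.0, cost=0.1, m=1):
    """One specialist on resource 1 of m; closed-form equilibrium exists."""
    prefs = np.zeros((1, m))
    prefs[0, 0] = 1.0
    return cc.Community(
        prefs=prefs,
        D=np.full((m, m), 1.0 / m),
        leakage=leakage,
        cost=cost,
        growth=1.0,
        eps=0.0,
        abundances=1.0,
    )
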