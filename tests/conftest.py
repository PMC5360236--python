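import numpy as np
import pytest

import equisim as eq


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params():
    """Cheap two-productivity parameter set for unit tests."""
    return eq.Params(n=10, L=20.0, beta=1.0, tau=0.01, generations=2, seed=3)


@pytest.fixture
def continuum_params():
    return eq.Params(mode="continuum", n=10, L=20.0, beta=1.0, tau=0.01,
                     generations=2, seed=3)


def fixture_pair(r_partner=0.0, mar_dm=0.0, prod=(1.0, 2.0),
                 params=None):
    """Two-individual fixture population: index 0 offers r, index 1 demands
    MAR (all four class entries set uniformly)."""
    params = params or eq.Params(n=2, L=20.0, beta=1.0, tau=0.01)
    spec = [
        {"productivity": prod[0], "rewards": r_partner, "mars": 0.0},
        {"productivity": prod[1], "rewards": 0.0, "mars": mar_dm},
    ]
    return eq.make_fixture_population(spec, params), params


@pytest.fixture
def monomorphic_half():
    """Four individuals, all traits 0.5: everyone accepts everyone."""
    params = eq.Params(n=4, L=50.0, beta=1.0, tau=0.05)
    spec = [{"productivity": p, "rewards": 0.5, "mars": 0.5}
            for p in (1.0, 1.0, 2.0, 2.0)]
    return eq.make_fixture_population(spec, params), params
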