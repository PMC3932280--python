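import numpy as np
import pytest

import predprey_rd as pp

# the "clean" worked parameter set: coexistence equilibrium at exactly (1, 1)
CLEAN = dict(eps=1.0, K=2.0, a=1.0, b=1.0, gamma=0.4, delta=0.6,
             D1=0.1, D2=0.1)


@pytest.fixture(scope="session")
def clean_params():
    return pp.ModelParams(**CLEAN)


@pytest.fixture(scope="session")
def h2():
    return pp.holling2(1.0)


@pytest.fixture(scope="session")
def clean_e3(clean_params, h2):
    eqs = pp.find_equilibria(clean_params, h2)
    return next(e for e in eqs if e.label == "E3")


@pytest.fixture(scope="session")
def clean_traj(clean_params, h2):
    """Clean-preset PDE run from a perturbed initial state, reused widely."""
    sc = pp.preset("clean_stable")
    return pp.simulate(sc.params, sc.response, sc.grid, sc.make_init(1),
                       sc.t_end)


@pytest.fixture(scope="session")
def extinct_traj():
    sc = pp.preset("extinction")
    return pp.simulate(sc.params, sc.response, sc.grid, sc.make_init(1),
                       sc.t_end)


def random_valid_params(rng, diffusion=False):
    """Draw a parameter set satisfying every sign constraint."""
    gamma = rng.uniform(0.05, 1.0)
    return pp.ModelParams(
        eps=rng.uniform(0.5, 2.0), K=rng.uniform(1.0, 5.0),
        a=rng.uniform(0.5, 2.0), b=rng.uniform(0.5, 2.0),
        gamma=gamma, delta=gamma * rng.uniform(1.2, 3.0),
        D1=rng.uniform(0.0, 10.0) if diffusion else 0.0,
        D2=rng.uniform(0.0, 10.0) if diffusion else 0.0)


def random_response(rng, params):
    """Holling II, or Holling IV with its increasing range beyond K."""
    if rng.random() < 0.5:
        return pp.holling2(rng.uniform(0.1, 10.0))
    l = params.K * rng.uniform(1.2, 3.0)
    return pp.holling4(l * l)
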