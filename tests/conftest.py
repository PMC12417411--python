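import dataclasses

import numpy as np
import pytest

import photoresp as pr
from photoresp.models import evaluate


@pytest.fixture(scope="session")
def ca_grid():
    """The default 12-level ambient CO2 sequence."""
    return np.array(pr.DEFAULT_CA_LEVELS)


@pytest.fixture(scope="session")
def noiseless_config():
    return dataclasses.replace(pr.default_config(seed=11), noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_curves(noiseless_config):
    return pr.simulate_dataset(noiseless_config)


def make_curve(params, ca, species="s", replicate=1, o2=0.21, par=2000.0,
               ci_ratio=0.75, noise=None, rng=None):
    """Curve whose P_n lies exactly on (or Gaussian-perturbed about) a model."""
    pn = np.asarray(evaluate(params, ca), dtype=float)
    if noise:
        pn = pn + (rng or np.random.default_rng(0)).normal(0.0, noise, ca.size)
    return pr.GasExchangeCurve(species=species, replicate=replicate,
                               o2_fraction=o2, par=par, ca=ca, pn=pn,
                               ci=ci_ratio * ca)
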