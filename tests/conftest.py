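import numpy as np
import pytest

import nanorelease as nr
from nanorelease.synthetic import EffectSpec, generate_dataset


@pytest.fixture(scope="session")
def design():
    return nr.load_doe_design()


@pytest.fixture(scope="session")
def default_dataset(design):
    """The study-scale synthetic dataset: 18 runs x 3 replicates, with curves."""
    return generate_dataset(design, seed=1)


@pytest.fixture(scope="session")
def dataset_nocurves(design):
    return generate_dataset(design, seed=1, with_curves=False)


@pytest.fixture(scope="session")
def noiseless_dataset(design):
    spec = EffectSpec(noise_sd={"br": 0.0, "trmax": 0.0, "rtrmax": 0.0, "le": 0.0})
    return generate_dataset(design, effects=spec, seed=1, with_curves=False)
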