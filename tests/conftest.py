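import warnings

import numpy as np
import pytest

from cgnma import fixtures as fx
from cgnma.enm import PotentialParams
from cgnma.model import ElasticNetworkModel


@pytest.fixture(scope="session")
def helix20():
    return fx.make_helix(20)


@pytest.fixture(scope="session")
def helix20_results(helix20):
    return ElasticNetworkModel(helix20).fit()


@pytest.fixture(scope="session")
def helix_small():
    return fx.make_helix(8)


@pytest.fixture(scope="session")
def dumbbell():
    return fx.make_dumbbell()


@pytest.fixture(scope="session")
def dumbbell_results(dumbbell):
    params = PotentialParams(anm_cutoff=fx.DUMBBELL_CUTOFF)
    return ElasticNetworkModel(dumbbell, params=params).fit()


@pytest.fixture(scope="session")
def dimer():
    return fx.make_dimer(8)


@pytest.fixture(scope="session")
def anm_params():
    return PotentialParams.anm()


@pytest.fixture()
def three_residue_pdb_text():
    return fx.make_pdb_text(fx.make_helix(3))


def fit_structure(structure, params=None, preprocessed=True):
    """Fit quietly; small toy geometries may warn about trivial-mode counts."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ElasticNetworkModel(structure, params=params,
                                   preprocessed=preprocessed).fit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
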