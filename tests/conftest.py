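import warnings

import numpy as np
import pytest

from ca1degen import synthetic as syn
from ca1degen.templates import load_template

# heavy shared fixtures are session-scoped: the synthetic ensembles drive
# several otherwise-independent checks


@pytest.fixture(scope="session")
def desk_template():
    return load_template("pyr_cAC_desk")


@pytest.fixture(scope="session")
def desk_mesh(desk_template):
    return desk_template.make_mesh()


@pytest.fixture(scope="session")
def pyr_ensemble():
    """Default-preset pyramidal cAC ensemble (12 cells, per-cell morphology)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return syn.make_ensemble("pyr_cAC_desk", n=12, seed=0)


@pytest.fixture(scope="session")
def interneuron_ensembles():
    """One small ensemble per interneuron e-type, shared morphology."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for et in ("int_cAC", "int_bAC", "int_cNAC"):
            out[et] = syn.make_ensemble(et, n=12, seed=0, morphology_variability=False)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
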