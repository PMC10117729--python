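import pytest

from feslogic import build_fes_model, wildtype_atlas

#: the unique fixpoint of the rules at Fe_ext=1, O2=1, derived by hand
#: evaluation of every node's rules (each node's target equals its value)
#: and confirmed by direct subspace scan.
MEDIUM_CONDITION_FIXPOINT = {
    "Fe_ext": 1,
    "O2": 1,
    "Fe_free": 1,
    "H2O2": 0,
    "OxyR": 0,
    "Hpx": 1,
    "Fur": 1,
    "RyhB": 1,
    "IscR-A": 1,
    "IscR-H": 0,
    "Isc": 0,
    "Suf": 1,
    "ErpA": 1,
    "NfuA": 1,
}


@pytest.fixture(scope="session")
def fes_model():
    return build_fes_model()


@pytest.fixture(scope="session")
def wt_atlas(fes_model):
    return wildtype_atlas(fes_model)
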