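import numpy as np
import pytest

from e2align.evomodel import make_params
from e2align.substitution import blosum62_model, two_letter_model

#: Demonstration AFR parameterization solved from the -11/-1 anchor.
AFR_DEMO = dict(lam=0.4296, muA=1.0023, r_M=0.75, r_X=0.6276)


@pytest.fixture(scope="session")
def b62():
    return blosum62_model()


@pytest.fixture(scope="session")
def toy2():
    return two_letter_model()


@pytest.fixture(scope="session")
def afr_params():
    return make_params("afr", **AFR_DEMO)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def model_default_params(model_id: str):
    """Representative valid parameters for every zoo model."""
    base = dict(lam=0.3, mu=0.6, muA_M=0.8, muA_D=1.0, muA_I=0.6, p=0.9)
    table = {
        "tkf91": dict(lam=0.3, mu=0.4),
        "tkf92": dict(lam=0.3, mu=0.4, r=0.5),
        "li": dict(lam=0.3, mu=0.6, muA=0.8, p=0.9),
        "lr": dict(lam=0.3, muA=0.9),
        "aali": base,
        "afg": {**base, "r_M": 0.4, "r_D": 0.3, "r_I": 0.5},
        "afr": dict(lam=0.3, muA=0.9, r_M=0.4, r_X=0.5),
        "aif": {**base, "r_I": 0.5},
        "aga": dict(lam=0.3, mu=0.6, muA_M=0.8, muA_D=1.0, muA_I=0.6,
                    sI=0.4, p=0.9),
    }
    return table[model_id]
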