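import copy

import numpy as np
import pytest

from asmcal.fixtures import FixtureSpec, make_dataset, make_sbr_context
from asmcal.model import GujerModel, load_model


@pytest.fixture(scope="session")
def model():
    """The packaged extended ASM3 model (compiled once per session)."""
    return load_model()


@pytest.fixture(scope="session")
def inert_model(model):
    """Variant with all rate constants effectively zero (transport-only).

    Used to isolate mixing/decant/washout mass balances from biology.
    """
    defn = copy.deepcopy(model.definition)
    rate_names = {"k_H", "k_STO", "mu_H", "mu_AOB", "mu_NOB", "b_H_O2",
                  "b_H_NOX", "b_AOB", "b_NOB", "b_STO_O2", "b_STO_NOX"}
    for p in defn["parameters"]:
        if p["name"] in rate_names:
            p["lower"] = 1e-12
            p["default"] = 1e-12
    return GujerModel(defn)


@pytest.fixture(scope="session")
def sbr_dataset():
    """Noise-free synthetic SBR dataset with planted truth parameters."""
    ds, truth = make_dataset(FixtureSpec(seed=1))
    return ds, truth


@pytest.fixture(scope="session")
def sbr_context(sbr_dataset, model):
    ds, _ = sbr_dataset
    return make_sbr_context(ds, model=model)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_params(model, rng, n=1):
    """Uniform draws from the parameter box."""
    u = rng.random((n, len(model.params)))
    draws = model.params.lower + u * (model.params.upper - model.params.lower)
    return draws[0] if n == 1 else draws


def random_state(model, rng, scale=50.0):
    return scale * rng.random(len(model.components))
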