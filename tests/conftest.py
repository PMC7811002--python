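import numpy as np
import pytest

from qeqpot.descriptors import AcsfParams, default_acsf_params
from qeqpot.qeq import ElementElectro, ScreeningSpec
from qeqpot.potential import make_model
from qeqpot.structures import Structure


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_element_electro():
    return ElementElectro({"A": 0.4, "B": 0.5}, {"A": 1.2, "B": 1.6})


@pytest.fixture
def small_acsf():
    """Tiny descriptor set for two toy elements (fast force tests)."""
    return default_acsf_params(
        ["A", "B"], cutoff=4.0, n_radial=3, angular_etas=(0.02,), zetas=(1.0,)
    )


@pytest.fixture
def random_cluster(rng):
    pos = rng.uniform(0.0, 4.5, (8, 3))
    return Structure(["A", "B"] * 4, pos, total_charge=1.0)


@pytest.fixture
def random_periodic(rng):
    pos = rng.uniform(0.0, 5.5, (6, 3))
    return Structure(
        ["A", "B"] * 3, pos, cell=np.eye(3) * 6.0, pbc=(True, True, True), total_charge=0.0
    )


def build_toy_model(generation, small_acsf, electro, seed=1, screening=True,
                    charge_mode="scaled"):
    scr = ScreeningSpec(1.8, 4.0) if screening else None
    return make_model(
        generation,
        small_acsf,
        seed=seed,
        electro=electro if generation != "2g" else None,
        screening=scr if generation != "2g" else None,
        charge_mode=charge_mode,
    )


@pytest.fixture
def toy_model_factory(small_acsf, two_element_electro):
    def factory(generation, **kw):
        return build_toy_model(generation, small_acsf, two_element_electro, **kw)

    return factory
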