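import pytest

from fuzzfit import constructs, secondary_shifts, synthetic


@pytest.fixture(scope="session")
def registry():
    return constructs.load_registry()


@pytest.fixture(scope="session")
def fsfg_k_his(registry):
    return registry["fsfg-k-his"]


@pytest.fixture(scope="session")
def fg_n(registry):
    return registry["fg-n"]


@pytest.fixture(scope="session")
def coil_reference():
    return secondary_shifts.load_random_coil()


@pytest.fixture()
def noiseless_config():
    return synthetic.SimulationConfig(
        seed=7,
        noise=synthetic.NoiseModel(
            intensity_frac=0.0, r2_sd=0.0, noe_sd=0.0, shift_sd_frac=0.0
        ),
    )


@pytest.fixture()
def default_config():
    return synthetic.SimulationConfig(seed=7)
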