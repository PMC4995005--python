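import logging

import pytest

import soilgam as sg

logging.getLogger("soilgam").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic experiment (20 soils, full design), seed 1."""
    ds, truth = sg.generate_dataset(seed=1)
    return ds, truth


@pytest.fixture(scope="session")
def model_table(default_dataset):
    ds, _ = default_dataset
    return sg.build_model_table(ds)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free experiment with no covariate effects and no priming."""
    cfg = sg.GeneratorConfig(noise_sigma=0.0, effects=(), pe_multiplier=1.0, seed=7)
    return sg.generate_dataset(cfg)
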