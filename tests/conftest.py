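import pytest

from hdsslink import GeneratorConfig, clean_config, generate_datasets


@pytest.fixture(scope="session")
def default_config():
    """Moderate-size study population for module tests."""
    return GeneratorConfig(n_registry=1200, n_clinic=400, seed=0)


@pytest.fixture(scope="session")
def default_data(default_config):
    return generate_datasets(default_config)


@pytest.fixture(scope="session")
def clean_cfg():
    """Corruption and missingness disabled: linkage must be perfect."""
    return clean_config(n_registry=800, n_clinic=250, seed=5)


@pytest.fixture(scope="session")
def clean_data(clean_cfg):
    return generate_datasets(clean_cfg)
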