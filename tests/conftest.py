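import pytest

from netcea import DecisionModel, default_net_config, load_bundled


@pytest.fixture(scope="session")
def config():
    return default_net_config()


@pytest.fixture(scope="session")
def life_table():
    return load_bundled()


@pytest.fixture(scope="session")
def model():
    return DecisionModel()


@pytest.fixture(scope="session")
def base_results(model):
    """Base-case strategy results, computed once per session."""
    return model.run()
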