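import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from foodprint import Registry, SynthesisConfig, load_default_tables
from foodprint.synth import generate_corpus, generate_recipes, generate_registry


@pytest.fixture(scope="session")
def tables():
    return load_default_tables()


@pytest.fixture(scope="session")
def registry_tables_only():
    return Registry()


@pytest.fixture(scope="session")
def synth_config():
    return SynthesisConfig(seed=42, n_persons=12)


@pytest.fixture(scope="session")
def synth_registry(synth_config):
    return generate_registry(synth_config)


@pytest.fixture(scope="session")
def synth_corpus(synth_config, synth_registry):
    return generate_corpus(synth_config, synth_registry)


@pytest.fixture(scope="session")
def synth_recipes(synth_config, synth_registry):
    return generate_recipes(synth_config, synth_registry)
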