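import pytest

from cottonwl import GeneratorConfig, generate_dataset, load_registry

DESIGN_DURATIONS = (0, 2, 4, 6, 8, 10, 12, 14)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def noiseless_table(registry):
    """Synthetic treatment table with zero replicate noise."""
    return generate_dataset(GeneratorConfig(cv=0.0, registry=registry, seed=0))


@pytest.fixture()
def seeded_table(registry):
    return generate_dataset(GeneratorConfig(cv=0.05, registry=registry, seed=42))
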