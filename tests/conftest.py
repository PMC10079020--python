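import numpy as np
import pytest

from cranioforge.simulate import GeneratorConfig, generate_dataset, fixture_template


@pytest.fixture(scope="session")
def template():
    return fixture_template()


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced five-group synthetic dataset shared across tests."""
    return generate_dataset(GeneratorConfig(n_per_group=(6, 5, 7, 5, 6), seed=42))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-sized synthetic dataset (n = 14/10/19/13/14)."""
    return generate_dataset(GeneratorConfig(seed=7))


def rotation(theta: float) -> np.ndarray:
    return np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
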