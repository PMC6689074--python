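import numpy as np
import pytest

from hoxcrm.energy import EnergyModel
from hoxcrm.registry import default_registry
from hoxcrm.synth import make_default_models, make_fixture_suite


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def models(registry):
    return make_default_models(registry)


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite(1)


def random_model(rng: np.random.Generator, footprint: int, name: str = "rand") -> EnergyModel:
    """Anchored random energy model for property tests."""
    pen = rng.uniform(0.0, 3.0, size=(footprint, 4))
    pen -= pen.min(axis=1, keepdims=True)
    return EnergyModel(name=name, factor="test", mode="dimer", penalties=pen)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
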