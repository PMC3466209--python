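import numpy as np
import pytest

from filmsem import BeamSpec, TransportConfig, coated_film_stack
from filmsem.transport import run_transport


@pytest.fixture(scope="session")
def film_stack_50():
    """The metal-coated membrane as built: 50-nm SiN / 15-nm Ni / 10-nm Au."""
    return coated_film_stack(sin_thickness=50.0)


@pytest.fixture(scope="session")
def film_stack_60():
    """Variant with the 60-nm SiN membrane."""
    return coated_film_stack(sin_thickness=60.0)


@pytest.fixture(scope="session")
def run_4kv(film_stack_50):
    """Reference transport run: 100k electrons at 4.0 kV through the film."""
    return run_transport(
        film_stack_50,
        BeamSpec(voltage=4.0),
        TransportConfig(n_electrons=100_000, rng_seed=101),
    )


@pytest.fixture(scope="session")
def run_36kv(film_stack_50):
    """Reference transport run: 100k electrons at 3.6 kV through the film."""
    return run_transport(
        film_stack_50,
        BeamSpec(voltage=3.6),
        TransportConfig(n_electrons=100_000, rng_seed=102),
    )


@pytest.fixture(scope="session")
def run_4kv_small(film_stack_50):
    """Smaller 4-kV run for PSF-building and statistics tests."""
    return run_transport(
        film_stack_50,
        BeamSpec(voltage=4.0),
        TransportConfig(n_electrons=20_000, rng_seed=7),
    )
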