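import numpy as np
import pytest

from hsiprep import synthgen
from hsiprep.hsio import ReflectanceCube


@pytest.fixture(scope="session")
def small_spec():
    """A small two-class phantom used across the suite."""
    return synthgen.PhantomSpec(
        image_height=40,
        image_width=40,
        n_bands=32,
        class_names=("TT", "HT"),
        class_fractions=(0.25, 0.5),
        seed=7,
    )


@pytest.fixture(scope="session")
def patient(small_spec):
    return synthgen.generate_patient_cube(small_spec, "P01", seed=11)


@pytest.fixture()
def toy_cube():
    """Deterministic 5x4x6 reflectance cube on a 500-1000 nm axis."""
    rng = np.random.default_rng(3)
    values = rng.uniform(10.0, 80.0, (5, 4, 6))
    wl = np.linspace(500.0, 1000.0, 6)
    return ReflectanceCube(values, wl)
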