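import numpy as np
import pytest

from dixpol.strands import DEFAULT_STRAND_DEFS
from dixpol.synthetic import FilamentSpec, generate_filament

TOY_REGIONS = DEFAULT_STRAND_DEFS["toy"]

SEVEN_PER_TURN = -360.0 / 7.0  # left-handed, commensurate with a 7-subunit cell


@pytest.fixture(scope="session")
def single_helix():
    spec = FilamentSpec(
        rise=11.43, twist=SEVEN_PER_TURN, n_subunits=7, seed=11, subunit_atoms=40
    )
    structure, truth = generate_filament(spec)
    return spec, structure, truth


@pytest.fixture(scope="session")
def double_helix():
    spec = FilamentSpec(
        rise=11.43,
        twist=SEVEN_PER_TURN,
        n_subunits=7,
        second_strand=(180.0, 11.43 / 2.0),
        seed=13,
        subunit_atoms=40,
    )
    structure, truth = generate_filament(spec)
    return spec, structure, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
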