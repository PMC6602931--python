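import numpy as np
import pytest

from nnpkit.conformation import Conformation
from nnpkit.featurization import AEVSpec


SMALL_SPEC = AEVSpec(
    radial_shifts=tuple(np.linspace(0.9, 5.2, 4, endpoint=False)),
    angular_radial_shifts=tuple(np.linspace(0.9, 3.5, 2, endpoint=False)),
    angle_shifts=tuple(np.linspace(0.0, np.pi, 4, endpoint=False)),
)


@pytest.fixture(scope="session")
def small_spec() -> AEVSpec:
    """A reduced descriptor (feature length 56) keeping unit tests fast."""
    return SMALL_SPEC


def random_conformation(rng, n_min=2, n_max=8, spread=1.3, molecule_id="m"):
    n = int(rng.integers(n_min, n_max + 1))
    species = tuple(rng.choice(["H", "C", "N", "O"], size=n))
    coords = rng.normal(scale=spread, size=(n, 3))
    # keep atoms from sitting on top of each other
    for _ in range(50):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.6:
            break
        i, j = np.unravel_index(np.argmin(d), d.shape)
        coords[i] += rng.normal(scale=0.4, size=3)
    return Conformation(molecule_id, species, coords)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
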