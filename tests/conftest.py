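import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pentapeptide_trans():
    """All-trans toy pentaalanine."""
    from pepspec.synthetic import gen_toy_peptide

    return gen_toy_peptide(5)


@pytest.fixture(scope="session")
def dialanine():
    from pepspec.synthetic import gen_toy_peptide

    return gen_toy_peptide(2)


@pytest.fixture(scope="session")
def benzene():
    from pepspec.structures import MolecularStructure, perceive_bonds

    th = np.linspace(0, 2 * np.pi, 7)[:-1]
    c = np.c_[1.39 * np.cos(th), 1.39 * np.sin(th), np.zeros(6)]
    h = np.c_[2.48 * np.cos(th), 2.48 * np.sin(th), np.zeros(6)]
    return perceive_bonds(
        MolecularStructure(["C"] * 6 + ["H"] * 6, np.vstack([c, h]))
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
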