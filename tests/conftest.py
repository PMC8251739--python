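import numpy as np
import pytest

from vist import Molecule


@pytest.fixture
def rng():
    return np.random.default_rng(20210352)


@pytest.fixture
def benzene():
    """Regular C6H6 hexagon in the xy-plane, carbons at 1.39 A from centre,
    listed counterclockwise so the right-hand normal is +z."""
    atoms = []
    for k in range(6):
        th = 2 * np.pi * k / 6
        atoms.append(("C", [1.39 * np.cos(th), 1.39 * np.sin(th), 0.0]))
    for k in range(6):
        th = 2 * np.pi * k / 6
        atoms.append(("H", [2.48 * np.cos(th), 2.48 * np.sin(th), 0.0]))
    return Molecule(atoms=atoms)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
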