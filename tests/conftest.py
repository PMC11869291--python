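import numpy as np
import pytest

from ampmm.model import AMPModel, ModelConfig
from ampmm.surrogate import default_spec, make_system, random_shell


@pytest.fixture(scope="session")
def tiny_model():
    """Small random-weight model shared by structural tests."""
    return AMPModel(ModelConfig(node_size=32, edge_size=16,
                                n_multipole_channels=4,
                                elements=(1, 6, 7, 8), seed=3))


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture()
def solvated_system(spec):
    """The five-atom solute in a 12-charge MM shell (all coupling terms
    active: electrostatics, polarization, LJ)."""
    rng = np.random.default_rng(1)
    x = spec.positions0 + 0.05 * rng.normal(size=spec.positions0.shape)
    pos, q = random_shell(rng, x.mean(axis=0), 12)
    return make_system(spec, x, pos, q)


def random_rotation(rng) -> np.ndarray:
    """Haar-random rotation matrix via QR."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def scattered_positions(rng, n, box=6.0, min_sep=0.9) -> np.ndarray:
    """Random coordinates with a minimum separation (rejection sampling)."""
    pts = [rng.uniform(0, box, 3)]
    while len(pts) < n:
        cand = rng.uniform(0, box, 3)
        if min(np.linalg.norm(cand - p) for p in pts) >= min_sep:
            pts.append(cand)
    return np.array(pts)
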