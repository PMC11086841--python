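import numpy as np
import pytest

from cvpath.conformers import generate_toy_helix_ensemble
from cvpath.potentials import make_two_basin_potential, muller_brown


@pytest.fixture(scope="session")
def two_basin():
    """Symmetric 6 kcal/mol double well, basins 2 units apart."""
    return make_two_basin_potential(6.0, 2.0, 0.0)


@pytest.fixture(scope="session")
def two_basin_asym():
    """Tilted double well: right minimum 1 kcal/mol above the left."""
    return make_two_basin_potential(6.0, 2.0, 1.0)


@pytest.fixture(scope="session")
def mb_surface():
    return muller_brown()


@pytest.fixture(scope="session")
def clean_mixture_ensemble():
    """Noise-free 70/30 straight/kinked toy helix ensemble (rigid copies)."""
    return generate_toy_helix_ensemble(40, {"straight": 0.7, "kinked": 0.3},
                                       noise_amplitude=0.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def arc_positions(polyline: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Arc-length position of each point along a piecewise-linear polyline
    (points are assumed to lie on or near the polyline)."""
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = []
    for p in points:
        d = polyline[:-1] - p
        e = np.diff(polyline, axis=0)
        t = np.clip(np.einsum("ij,ij->i", -d, e) / np.maximum(seg**2, 1e-300),
                    0.0, 1.0)
        dist = np.linalg.norm(d + t[:, None] * e, axis=1)
        j = int(np.argmin(dist))
        out.append(cum[j] + t[j] * seg[j])
    return np.asarray(out)
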