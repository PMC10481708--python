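import numpy as np
import pytest

from fcnc import DistanceMatrix, FiltrationConfig, build_simplex_stream


@pytest.fixture
def square_distance() -> DistanceMatrix:
    """Unit square: four corners, sides 1, diagonals sqrt(2)."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ["a", "b", "c", "d"])


@pytest.fixture
def square_stream(square_distance):
    """VR stream of the unit square with t_max large enough to fill it."""
    return build_simplex_stream(
        square_distance, FiltrationConfig(d_max=2, t_max=2.0, divisions=20)
    )


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Random symmetric matrix with distinct off-diagonal entries in (0, 2)."""
    m = rng.uniform(0.05, 1.95, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(m)
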