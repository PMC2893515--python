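import numpy as np
import pytest

from examsem import ItemResponseMatrix, SimulationConfig


@pytest.fixture
def small_matrix():
    """4 candidates × 3 binary items with hand-computed alpha 0.75."""
    return ItemResponseMatrix.from_array(
        [[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]]
    )


@pytest.fixture
def default_config():
    """The headline simulation: 10,000 candidates, mean 50, SD 10,
    reliability 0.9, pass mark 60, three sittings."""
    return SimulationConfig(seed=0)


def random_matrix(rng: np.random.Generator) -> ItemResponseMatrix:
    """A random small response matrix with non-degenerate totals."""
    while True:
        n = int(rng.integers(3, 25))
        k = int(rng.integers(2, 15))
        if rng.random() < 0.7:
            responses = rng.integers(0, 2, (n, k)).astype(float)
        else:  # partial-credit marks
            responses = rng.integers(0, 5, (n, k)).astype(float)
        if responses.sum(axis=1).var() > 0:
            return ItemResponseMatrix.from_array(responses)
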