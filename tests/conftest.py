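import numpy as np
import pytest

from forestfrag import BinaryLandscape


def flood_fill_label(habitat: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Independent patch-labeling oracle: explicit-stack flood fill."""
    nrows, ncols = habitat.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((nrows, ncols), dtype=int)
    current = 0
    for r0 in range(nrows):
        for c0 in range(ncols):
            if habitat[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < nrows
                            and 0 <= cc < ncols
                            and habitat[rr, cc]
                            and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels, current


@pytest.fixture
def center_cell_landscape() -> BinaryLandscape:
    """3x3 grid of 30-m cells with a single habitat cell at the center."""
    cells = np.zeros((3, 3), dtype=np.int8)
    cells[1, 1] = 1
    return BinaryLandscape(cells, 30.0)


@pytest.fixture
def full_landscape() -> BinaryLandscape:
    return BinaryLandscape(np.ones((3, 3), dtype=np.int8), 30.0)


@pytest.fixture
def empty_landscape() -> BinaryLandscape:
    return BinaryLandscape(np.zeros((3, 3), dtype=np.int8), 30.0)


def random_landscape(rng: np.random.Generator, n: int = 20, p: float = 0.5,
                     cell_size: float = 30.0) -> BinaryLandscape:
    """Unstructured random binary grid (Bernoulli cells)."""
    return BinaryLandscape((rng.random((n, n)) < p).astype(np.int8), cell_size)
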