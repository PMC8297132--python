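import numpy as np
import pytest

import parkcap as pc
from parkcap.fixtures import micro_corridor, mini_ring, mini_tree, trap_trail


@pytest.fixture(scope="session")
def corridor():
    grid, tables = micro_corridor()
    return grid, tables


@pytest.fixture(scope="session")
def corridor_cfg(corridor):
    grid, tables = corridor
    return pc.EngineConfig(grid=grid, tables=tables, daily_total=0,
                           open_window=(8, 9), seed=1)


@pytest.fixture(scope="session")
def trap():
    return trap_trail()


@pytest.fixture(scope="session")
def trap_cfg(trap):
    grid, tables = trap
    return pc.EngineConfig(grid=grid, tables=tables, daily_total=0,
                           open_window=(8, 9), seed=1)


@pytest.fixture(scope="session")
def ring():
    return mini_ring(0)


@pytest.fixture(scope="session")
def tree():
    return mini_tree(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


def random_park(rng, h=20, w=20, p_wall=0.25, one_way=False):
    """A random small park grid with one gate; may be partly disconnected
    (useful for routing oracles, not validated)."""
    cells = np.where(rng.random((h, w)) < p_wall,
                     int(pc.CellClass.INACCESSIBLE), int(pc.CellClass.OPEN_SPACE))
    # sprinkle main path rows for preference-weighted costs
    r = int(rng.integers(0, h))
    cells[r, :] = np.where(cells[r, :] == int(pc.CellClass.OPEN_SPACE),
                           int(pc.CellClass.PATH_MAIN), cells[r, :])
    grid = pc.ParkGrid(cells=cells.astype(np.int8))
    if one_way:
        acc = [tuple(map(int, c)) for c in np.argwhere(
            cells == int(pc.CellClass.OPEN_SPACE))]
        for _ in range(3):
            if not acc:
                break
            cell = acc[int(rng.integers(0, len(acc)))]
            d = [(-1, 0), (0, -1), (0, 1), (1, 0)][int(rng.integers(0, 4))]
            grid.one_way[cell] = d
    return grid
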