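import numpy as np
import pytest

import mgpit as m

A = 0.125      # default element edge, mm
RHO = 1.7      # AZ61 density, mg/mm^3
ME = A**3 * RHO


@pytest.fixture
def toy_grid():
    """5 x 5 x 5 intact block at the default element size."""
    return m.build_specimen(5 * A, 5 * A, 5 * A, A, RHO)


@pytest.fixture(scope="session")
def default_grid():
    """The reference 15 x 15 x 2 mm specimen (230,400 elements)."""
    return m.build_specimen(15.0, 15.0, 2.0, A, RHO)


@pytest.fixture
def two_weight_grid():
    """A 2 x 1 x 1 grid with OA = {0.07, 1.0} — the two-element CP example.

    Both elements are surface (EA = 5 each), so CA is proportional to OA
    and the exact selection probabilities are 0.07/1.07 and 1/1.07.
    """
    g = m.build_specimen(2 * A, A, A, A, RHO)
    g.oa[0, 0, 0] = 0.07
    g.oa[1, 0, 0] = 1.0
    return g


def brute_force_exposure(grid):
    """Independent triple-loop EA oracle (small grids only)."""
    nx, ny, nz = grid.shape
    ea = np.zeros(grid.shape, dtype=int)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if grid.state[i, j, k] == m.VOID:
                    continue
                count = 0
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                        count += 1
                    elif grid.state[ii, jj, kk] == m.VOID:
                        count += 1
                ea[i, j, k] = count
    return ea


def random_corroded_grid(rng, max_side=10, removal_fraction=0.4):
    """A small random grid with a random surface-respecting removal history."""
    nx, ny, nz = rng.integers(2, max_side + 1, size=3)
    grid = m.build_specimen(nx * A, ny * A, nz * A, A, RHO)
    n_target = int(removal_fraction * grid.n)
    removed = 0
    while removed < n_target:
        candidates = np.argwhere((grid.state != m.VOID) & (grid.ea > 0))
        if candidates.shape[0] == 0:
            break
        take = min(rng.integers(1, 8), candidates.shape[0], n_target - removed)
        pick = rng.choice(candidates.shape[0], size=take, replace=False)
        m.apply_removals(grid, candidates[pick])
        removed += take
    return grid
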