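import numpy as np
import pytest

import larvaldrift as ld


@pytest.fixture(scope="session")
def grid():
    return ld.GridSpec(-1.0, 1.0, 15.0, 17.0, 0.02)


@pytest.fixture(scope="session")
def archipelago(grid):
    """Three islands with mixed substrate, deterministic."""
    return ld.make_archipelago(3, grid, seed=7)


@pytest.fixture(scope="session")
def gyre_field(grid, archipelago):
    """Single-gyre field with a weak mean flow, no noise."""
    return ld.make_current_field(
        grid,
        duration_days=10.0,
        gyres=[((0.0, 16.0), 0.3, 0.5)],
        mean_flow=(0.05, 0.02),
        seed=1,
        land_mask=archipelago.land,
    )


@pytest.fixture(scope="session")
def open_ocean_field():
    """Uniform eastward flow over a land-free grid."""
    return ld.make_current_field(
        ld.GridSpec(-2.0, 2.0, 15.0, 17.0, 0.05), duration_days=10.0, mean_flow=(0.1, 0.0)
    )


@pytest.fixture(scope="session")
def table2():
    return ld.load_table2()


@pytest.fixture(scope="session")
def table3():
    return ld.load_table3()


def brute_force_max_modularity(W):
    """Exhaustive maximum-modularity search over all set partitions (n <= 9)."""

    def partitions(items):
        if len(items) == 1:
            yield [items]
            return
        first = items[0]
        for smaller in partitions(items[1:]):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
            yield [[first]] + smaller

    n = len(W)
    best = -np.inf
    for part in partitions(list(range(n))):
        memb = np.empty(n, dtype=int)
        for ci, block in enumerate(part):
            memb[block] = ci
        q = ld.modularity(W, memb)
        if q > best:
            best = q
    return best
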