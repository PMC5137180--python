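import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardiosim.cell_core import make_passive_cell, make_reference_cell
from cardiosim.tissue import FiberGeometry, GridGeometry, make_node

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def refcell():
    return make_reference_cell()


@pytest.fixture
def passive():
    return make_passive_cell()


def passive_fiber(n, **kw) -> FiberGeometry:
    kw.setdefault("dx", 0.01)
    kw.setdefault("d", 0.0012)
    kw.setdefault("Ri", 0.15)
    return FiberGeometry([make_node(make_passive_cell()) for _ in range(n)], **kw)


def passive_grid(nrows, ncols, **kw) -> GridGeometry:
    kw.setdefault("dx", 0.01)
    kw.setdefault("dy", 0.01)
    kw.setdefault("d", 0.0012)
    kw.setdefault("Ri", 0.15)
    return GridGeometry(
        [[make_node(make_passive_cell()) for _ in range(ncols)] for _ in range(nrows)],
        **kw,
    )


def set_fiber_vm(fiber, values) -> None:
    for nd, v in zip(fiber.nodes, np.asarray(values, dtype=float)):
        nd.state.vm = float(v)


def set_grid_vm(grid, values) -> None:
    arr = np.asarray(values, dtype=float)
    for r, row in enumerate(grid.nodes):
        for c, nd in enumerate(row):
            nd.state.vm = float(arr[r, c])
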