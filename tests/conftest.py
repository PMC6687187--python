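import numpy as np
import pytest

from latticetumour import engine
from latticetumour.params import SimulationParams


def small_run(seed, max_cells, *, u=5.0, a=1.0, d=0.0, t_driver=float("inf"),
              s=0.0, grid=251, **kw):
    params = SimulationParams(
        seed=seed, max_cells=max_cells, u=u, a=a, d=d,
        t_driver=t_driver, s=s, grid_extent=grid, **kw
    )
    return engine.run_with_restarts(params)


@pytest.fixture(scope="session")
def neutral_state():
    """A neutral homogeneous tumour (u=5, d=0, a=1), ~3000 cells."""
    return small_run(seed=11, max_cells=3000)


@pytest.fixture(scope="session")
def neutral_state_u10():
    """A neutral homogeneous tumour with the reference mutation rate u=10."""
    return small_run(seed=12, max_cells=5000, u=10.0, t_driver=4.0)


@pytest.fixture(scope="session")
def selective_state():
    """Homogeneous growth with a selected subclone captured mid-sweep:
    driver at the same population fraction as the full-size reference
    setting (t=8 at ~80k cells -> t=5.7 at 8k cells), s=3."""
    return small_run(seed=403, max_cells=8000, u=10.0, t_driver=5.7, s=3.0)


@pytest.fixture(scope="session")
def boundary_state():
    """Boundary-driven growth (a=0.025), ~2000 cells."""
    return small_run(seed=21, max_cells=2000, u=10.0, a=0.025, t_driver=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
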