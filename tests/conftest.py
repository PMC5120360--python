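import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gliovasc import (
    ModelParameters,
    SimulationState,
    Trajectory,
    Variant,
    build_grid,
)


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse, short domain for fast integration tests."""
    return build_grid(50.0, 501)


def make_tanh_trajectory(
    centers, times, width=5.0, N=100.0, L=200.0, nx=2001, params=None
) -> Trajectory:
    """Synthetic trajectory of tanh fronts at prescribed centre positions."""
    grid = build_grid(L, nx)
    p = params or ModelParameters(L=L, T_f=float(times[-1]) if times[-1] > 0 else 1.0)
    traj = Trajectory(grid=grid, params=p, variant=Variant.I)
    for t, c in zip(times, centers):
        rho = N * (1.0 - np.tanh((grid.x - c) / width)) / 2.0
        traj.snapshots.append(
            SimulationState(
                t=float(t),
                rho=rho,
                v=np.full(nx, p.v0),
                sigma=np.full(nx, p.sigma0),
            )
        )
    return traj
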