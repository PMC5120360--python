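"""Method-of-lines discretisation and time integration of the 1-D system.

The coupled PDEs are discretised on a uniform grid with 3-point central
second differences and zero-flux (Neumann) boundaries enforced by ghost-node
reflection.  Glioma diffusion acts on the composite field
``D_rho * alpha(sigma) * rho`` -- the migratory subpopulation diffuses
Fickianly, so summing the two phenotype equations puts the oxygen-dependent
mobility inside the Laplacian.  Time integration uses LSODA with a banded
Jacobian (fields interleaved per node), which handles the stiffness induced
by fast oxygen relaxation relative to cell motility.

Runs are deterministic: no randomness anywhere, bit-reproducible for fixed
inputs and library versions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    DomainError,
    ModelParameters,
    Variant,
    occlusion_rate,
    smooth_heaviside,
    switch_fractions,
)

__all__ = [
    "Grid1D",
    "SimulationState",
    "Trajectory",
    "IntegrationError",
    "build_grid",
    "laplacian_neumann",
    "initial_state",
    "integrate",
    "default_output_times",
]

# Relative bound-violation tolerance on fields at output times.
STATE_BOUND_TOL = 1e-6
# Undershoot below zero up to ~10x the solver's absolute tolerance is
# integration roundoff and clipped; anything larger flags instability.
UNDERSHOOT_ABS = 1e-8

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9
# Default spatial resolution (dx = 0.1 mm on the default 200 mm domain).
DEFAULT_NX = 2001


class IntegrationError(RuntimeError):
    """The time integration failed or produced an inadmissible state."""


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D grid of ``nx`` nodes spanning [0, L]."""

    L: float
    nx: int
    dx: float
    x: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))


@dataclass
class SimulationState:
    """The three fields at one instant on a shared grid."""

    t: float
    rho: np.ndarray
    v: np.ndarray
    sigma: np.ndarray

    def copy(self) -> "SimulationState":
        return SimulationState(self.t, self.rho.copy(), self.v.copy(), self.sigma.copy())


@dataclass
class Trajectory:
    """Time-ordered snapshots of one simulation run."""

    grid: Grid1D
    params: ModelParameters
    variant: Variant
    snapshots: list[SimulationState] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    def state_at(self, t: float) -> SimulationState:
        times = self.times
        i = int(np.argmin(np.abs(times - t)))
        return self.snapshots[i]

    @property
    def final(self) -> SimulationState:
        return self.snapshots[-1]

    def save_npz(self, path) -> None:
        """Self-describing array container: fields, grid, times, parameters."""
        from dataclasses import asdict

        p = asdict(self.params)
        np.savez(
            path,
            x=self.grid.x,
            times=self.times,
            rho=np.stack([s.rho for s in self.snapshots]),
            v=np.stack([s.v for s in self.snapshots]),
            sigma=np.stack([s.sigma for s in self.snapshots]),
            variant=np.array(self.variant.value),
            param_names=np.array(list(p.keys())),
            param_values=np.array([float(v) for v in p.values()]),
        )

    @classmethod
    def load_npz(cls, path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as data:
            names = [str(n) for n in data["param_names"]]
            values = data["param_values"]
            kwargs = dict(zip(names, (float(v) for v in values)))
            kwargs["n"] = int(kwargs["n"])
            params = ModelParameters(**kwargs)
            x = data["x"]
            grid = build_grid(float(x[-1]), len(x))
            traj = cls(grid=grid, params=params, variant=Variant.coerce(str(data["variant"])))
            for i, t in enumerate(data["times"]):
                traj.snapshots.append(
                    SimulationState(
                        t=float(t),
                        rho=data["rho"][i].copy(),
                        v=data["v"][i].copy(),
                        sigma=data["sigma"][i].copy(),
                    )
                )
        return traj


def build_grid(L: float, nx: int) -> Grid1D:
    """Uniform grid on [0, L] with nx nodes (nx >= 16)."""
    if not (math.isfinite(L) and L > 0):
        raise ValueError(f"domain length must be positive and finite, got {L!r}")
    if nx < 16:
        raise ValueError(f"need at least 16 grid nodes, got {nx!r}")
    x = np.linspace(0.0, L, nx)
    return Grid1D(L=float(L), nx=int(nx), dx=float(L) / (nx - 1), x=x)


def laplacian_neumann(f: np.ndarray, grid: Grid1D) -> np.ndarray:
    """3-point second difference with zero-flux ghost-node boundaries."""
    f = np.asarray(f, dtype=float)
    if f.shape != (grid.nx,):
        raise ValueError(f"field length {f.shape} does not match grid nx={grid.nx}")
    out = np.empty_like(f)
    inv_dx2 = 1.0 / grid.dx**2
    out[1:-1] = (f[2:] - 2.0 * f[1:-1] + f[:-2]) * inv_dx2
    # ghost reflection f[-1] := f[1], f[nx] := f[nx-2]
    out[0] = 2.0 * (f[1] - f[0]) * inv_dx2
    out[-1] = 2.0 * (f[-2] - f[-1]) * inv_dx2
    return out


def initial_state(params: ModelParameters, grid: Grid1D) -> SimulationState:
    """Left-seeded tumour: a smoothed indicator of [0, eps] at height rho0.

    rho(x) = rho0 * H_gamma(x - eps); v and sigma start uniform at the
    normal-tissue values v0 and sigma0.
    """
    p = params
    if p.eps >= grid.L:
        raise ValueError(f"initial segment eps={p.eps!r} must fit inside L={grid.L!r}")
    rho = p.rho0 * smooth_heaviside(grid.x - p.eps, p.gamma)
    v = np.full(grid.nx, p.v0)
    sigma = np.full(grid.nx, p.sigma0)
    return SimulationState(t=0.0, rho=rho, v=v, sigma=sigma)


def default_output_times(params: ModelParameters, every: float = 10.0) -> np.ndarray:
    """Snapshot times 0, every, 2*every, ..., T_f."""
    n = int(round(params.T_f / every))
    times = np.linspace(0.0, n * every, n + 1)
    if times[-1] < params.T_f:
        times = np.append(times, params.T_f)
    return times[times <= params.T_f]


def divergence_flux_neumann(mobility: np.ndarray, f: np.ndarray, grid: Grid1D) -> np.ndarray:
    """div(mobility * grad f) with zero boundary flux (gradient-flux form).

    Face mobilities are arithmetic means of the node values; the boundary
    faces carry zero flux.
    """
    dx = grid.dx
    flux = np.zeros(grid.nx + 1)  # faces, flux[0] = flux[-1] = 0
    mob_face = 0.5 * (mobility[1:] + mobility[:-1])
    flux[1:-1] = mob_face * (f[1:] - f[:-1]) / dx
    return (flux[1:] - flux[:-1]) / dx


def _rhs_factory(
    params: ModelParameters,
    variant: Variant,
    grid: Grid1D,
    flux_form: str = "composite",
    occlusion_gate: bool = False,
):
    """Build the method-of-lines RHS over an interleaved state vector.

    Interleaving the fields per node keeps the Jacobian banded (bandwidth =
    number of fields), which LSODA exploits.  Variant I evolves rho only;
    variant II evolves (rho, sigma); variant III evolves (rho, v, sigma).

    ``flux_form`` selects the glioma diffusion discretisation: "composite"
    (default) applies the Laplacian to D_rho*alpha(sigma)*rho, the form
    obtained by summing the phenotype equations; "gradient" uses the
    conservative flux div(D_rho*alpha(sigma) grad rho) as a sensitivity
    variant.
    """
    if flux_form not in ("composite", "gradient"):
        raise ValueError(f"flux_form must be 'composite' or 'gradient', got {flux_form!r}")
    p = params
    alpha0, beta0 = switch_fractions(p.sigma0, p)
    D_rho = p.D / alpha0
    b_rho = p.b / beta0
    nx = grid.nx
    lam1, lam2 = p.lambda1, p.lambda2
    clamp_hi = lam1 - 1e-12

    def rho_sigma_terms(rho, sigma):
        rho = np.clip(rho, 0.0, None)
        s = np.clip(sigma, 0.0, clamp_hi)
        f21 = lam1 - s
        alpha = f21 / (f21 + lam2 * s)
        beta = 1.0 - alpha
        if flux_form == "composite":
            diff = laplacian_neumann(D_rho * alpha * rho, grid)
        else:
            diff = divergence_flux_neumann(D_rho * alpha, rho, grid)
        drho = diff + b_rho * beta * rho * (1.0 - rho / p.N)
        return rho, s, drho

    if variant is Variant.I:
        def rhs(t, y):
            rho = np.clip(y, 0.0, None)
            return laplacian_neumann(p.D * rho, grid) + p.b * rho * (1.0 - rho / p.N)
        return rhs, 1

    if variant is Variant.II:
        v_const = p.v0

        def rhs(t, y):
            rho = y[0::2]
            sigma = y[1::2]
            rho, s, drho = rho_sigma_terms(rho, sigma)
            dsig = (
                p.D_sigma * laplacian_neumann(sigma, grid)
                + p.h1 * v_const * (p.sigma0 - s)
                - p.h2 * rho * s
            )
            out = np.empty(2 * nx)
            out[0::2] = drho
            out[1::2] = dsig
            return out

        return rhs, 2

    def rhs(t, y):  # variant III
        rho = y[0::3]
        v = np.clip(y[1::3], 0.0, 1.0)
        sigma = y[2::3]
        rho, s, drho = rho_sigma_terms(rho, sigma)
        production = rho * smooth_heaviside(s - p.sigma_hat, p.theta)
        denom = production + p.K * v
        m = np.where(denom > 0, production / np.where(denom > 0, denom, 1.0), 0.0)
        dv = (
            p.D_v * laplacian_neumann(v, grid)
            + p.g1 * m * v * (1.0 - v)
            - occlusion_rate(rho, v, p, occlusion_gate)
        )
        dsig = (
            p.D_sigma * laplacian_neumann(sigma, grid)
            + p.h1 * v * (p.sigma0 - s)
            - p.h2 * rho * s
        )
        out = np.empty(3 * nx)
        out[0::3] = drho
        out[1::3] = dv
        out[2::3] = dsig
        return out

    return rhs, 3


def _check_bounds(state: SimulationState, params: ModelParameters, t: float) -> None:
    """Clip roundoff-scale undershoot; raise on genuine range violations.

    Negative excursions within the integrator's error floor
    (``UNDERSHOOT_ABS``, ~10x the absolute tolerance) are clipped to zero;
    larger ones, or overshoot above the upper bound beyond 0.1% of the
    scale, indicate numerical instability.
    """
    p = params
    checks = (
        ("rho", state.rho, p.N),
        ("v", state.v, 1.0),
        ("sigma", state.sigma, p.sigma0),
    )
    for name, arr, hi in checks:
        lo_violation = -float(arr.min())
        hi_violation = float(arr.max()) - hi
        if lo_violation > max(UNDERSHOOT_ABS, 1e-10 * hi) or hi_violation > 1e-3 * hi:
            raise IntegrationError(
                f"field {name} left its admissible range at t={t:.6g}: "
                f"min={arr.min():.6g}, max={arr.max():.6g} (bound {hi:.6g})"
            )
        if lo_violation > 0:
            np.clip(arr, 0.0, None, out=arr)


def integrate(
    params: ModelParameters,
    variant: Variant | str,
    grid: Grid1D | None = None,
    output_times: Sequence[float] | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    init: SimulationState | None = None,
    flux_form: str = "composite",
    occlusion_gate: bool = False,
) -> Trajectory:
    """Integrate a model variant to T_f and return the trajectory.

    Parameters
    ----------
    params
        Model constants and run settings; ``params.T_f`` bounds the run.
    variant
        Model tag ("I", "II" or "III").
    grid
        Spatial grid; defaults to ``nx = 2001`` nodes on [0, params.L].
    output_times
        Snapshot times inside [0, T_f]; defaults to every 10 days.
    init
        Optional resume state (defaults to the standard initial condition).

    Raises
    ------
    IntegrationError
        On solver failure or a field leaving its admissible range.
    """
    variant = Variant.coerce(variant)
    p = params
    if grid is None:
        grid = build_grid(p.L, DEFAULT_NX)
    if output_times is None:
        output_times = default_output_times(p)
    output_times = np.asarray(output_times, dtype=float)
    if output_times.ndim != 1 or len(output_times) < 2:
        raise ValueError("need at least two output times")
    if np.any(np.diff(output_times) <= 0):
        raise ValueError("output times must be strictly increasing")
    if output_times[0] < 0 or output_times[-1] > p.T_f * (1 + 1e-12):
        raise ValueError("output times must lie inside [0, T_f]")

    state0 = initial_state(p, grid) if init is None else init
    rhs, nfields = _rhs_factory(p, variant, grid, flux_form, occlusion_gate)

    if variant is Variant.I:
        y0 = state0.rho.copy()
    elif variant is Variant.II:
        y0 = np.empty(2 * grid.nx)
        y0[0::2] = state0.rho
        y0[1::2] = state0.sigma
    else:
        y0 = np.empty(3 * grid.nx)
        y0[0::3] = state0.rho
        y0[1::3] = state0.v
        y0[2::3] = state0.sigma

    t0 = float(output_times[0])
    sol = solve_ivp(
        rhs,
        (t0, float(output_times[-1])),
        y0,
        method="LSODA",
        t_eval=output_times,
        rtol=rtol,
        atol=atol,
        lband=nfields,
        uband=nfields,
    )
    if not sol.success:
        raise IntegrationError(f"time integration failed: {sol.message}")

    traj = Trajectory(grid=grid, params=p, variant=variant)
    for j, t in enumerate(sol.t):
        y = sol.y[:, j]
        if variant is Variant.I:
            rho = y
            v = np.full(grid.nx, p.v0)
            sigma = np.full(grid.nx, p.sigma0)
        elif variant is Variant.II:
            rho = y[0::2]
            sigma = y[1::2]
            v = np.full(grid.nx, p.v0)
        else:
            rho = y[0::3]
            v = y[1::3]
            sigma = y[2::3]
        state = SimulationState(
            t=float(t),
            rho=rho.copy(),
            v=v.copy(),
            sigma=sigma.copy(),
        )
        _check_bounds(state, p, float(t))
        traj.snapshots.append(state)
    return traj
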