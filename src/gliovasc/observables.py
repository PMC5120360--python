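"""Tumour-invasion metrics extracted from simulated trajectories.

Four observables characterise a run at its final time ``T_f``:

* **front position / speed** -- the tumour front is the point of maximum
  (negative) spatial slope of the cell density profile; its speed is the
  slope of a least-squares line through the front positions over the last
  quarter of the run.
* **infiltration width** -- the distance between the points where the
  density falls to 80% and to 2% of its maximum, a proxy for how diffusely
  the tumour infiltrates the tissue.
* **effective diffusion and proliferation rates** -- domain averages of the
  oxygen-modulated motility ``D_rho * alpha(sigma)`` and growth
  ``b_rho * beta(sigma)``; they collapse to the intrinsic ``D`` and ``b``
  when oxygen sits at the physiological level everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ModelParameters, switch_fractions
from .solver import SimulationState, Trajectory

__all__ = [
    "ObservableSet",
    "FrontError",
    "front_position",
    "front_speed",
    "infiltration_width",
    "effective_rates",
    "observables_from_trajectory",
]

# Gradient below this fraction of N/L counts as a flat (front-less) profile.
FLAT_GRADIENT_TOL = 1e-9
# Fraction of the run over which the front speed is fitted.
SPEED_WINDOW = 0.25
# Fractions of the maximum density defining the infiltration width.
WIDTH_UPPER_LEVEL = 0.80
WIDTH_LOWER_LEVEL = 0.02
# Front may not enter the last 5% of the domain during the speed window.
BOUNDARY_MARGIN = 0.05


class FrontError(RuntimeError):
    """No well-defined tumour front exists in the profile."""


@dataclass(frozen=True)
class ObservableSet:
    """Invasion metrics for one completed run, evaluated at T_f."""

    front_speed: float          # mm/day
    infiltration_width: float   # mm
    D_eff: float                # mm^2/day
    b_eff: float                # 1/day
    t_eval: float               # day
    speed_residual: float = 0.0  # RMS residual of the front-position fit, mm


def _rightward_front_slice(rho: np.ndarray) -> slice:
    """Indices of the decreasing front right of the density maximum."""
    peak = int(np.argmax(rho))
    return slice(peak, len(rho))


def front_position(state: SimulationState, grid=None, x: np.ndarray | None = None) -> float:
    """Location of the steepest descent of the density profile.

    The discrete-gradient maximum on the rightward (invading) front is
    refined by quadratic interpolation through the three neighbouring
    gradient magnitudes, giving sub-grid accuracy for smooth profiles.
    """
    if x is None:
        if grid is None:
            raise ValueError("pass either a grid or node coordinates x")
        x = grid.x
    rho = np.asarray(state.rho, dtype=float)
    if len(x) != len(rho):
        raise ValueError("coordinate/field length mismatch")
    dx = x[1] - x[0]
    L = x[-1] - x[0]
    grad = np.gradient(rho, dx)
    sl = _rightward_front_slice(rho)
    g = -grad[sl]  # descending slope is positive here
    scale = rho.max() / L if rho.max() > 0 else 0.0
    if g.size == 0 or g.max() < max(FLAT_GRADIENT_TOL * scale, 1e-300):
        raise FrontError("profile is flat: no invading front to locate")
    k = int(np.argmax(g))
    i = sl.start + k
    if 0 < i < len(x) - 1:
        y0, y1, y2 = -grad[i - 1], -grad[i], -grad[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            return float(x[i] + shift * dx)
    return float(x[i])


def front_speed(
    trajectory: Trajectory, window: float = SPEED_WINDOW
) -> tuple[float, float]:
    """Front speed: least-squares slope of front position over the window.

    The window is the final ``window`` fraction of the run (default 25%),
    requiring at least 4 output times.  Returns ``(speed, rms_residual)``.

    Raises
    ------
    FrontError
        If too few outputs fall in the window, or the front reaches within
        5% of the right boundary (boundary-contaminated speed).
    """
    times = trajectory.times
    t_cut = times[-1] - window * (times[-1] - times[0])
    idx = np.nonzero(times >= t_cut - 1e-9)[0]
    if len(idx) < 4:
        raise FrontError(
            f"need >= 4 output times in the final {window:.0%} of the run, got {len(idx)}"
        )
    x = trajectory.grid.x
    positions = np.array(
        [front_position(trajectory.snapshots[i], x=x) for i in idx]
    )
    if positions.max() > (1.0 - BOUNDARY_MARGIN) * trajectory.grid.L:
        raise FrontError(
            f"front reached {positions.max():.3g} mm, within 5% of the domain "
            f"boundary (L={trajectory.grid.L:.3g} mm); enlarge the domain"
        )
    t_win = times[idx]
    coeffs, res = np.polyfit(t_win, positions, 1, full=True)[:2]
    speed = float(coeffs[0])
    rms = float(np.sqrt(res[0] / len(idx))) if len(res) else 0.0
    return speed, rms


def infiltration_width(state: SimulationState, grid=None, x: np.ndarray | None = None) -> float:
    """Distance between the 80% and 2% density levels on the invading front.

    Each crossing is located by linear interpolation between the bracketing
    nodes of the monotone front segment right of the density maximum.
    """
    if x is None:
        if grid is None:
            raise ValueError("pass either a grid or node coordinates x")
        x = grid.x
    rho = np.asarray(state.rho, dtype=float)
    rho_max = rho.max()
    if rho_max <= 0:
        raise FrontError("empty profile: infiltration width undefined")
    sl = _rightward_front_slice(rho)
    seg = rho[sl]
    xseg = x[sl]

    def crossing(level: float) -> float:
        below = np.nonzero(seg <= level)[0]
        if len(below) == 0 or below[0] == 0:
            raise FrontError(
                f"density never falls to {level:.3g} on the front "
                "(front beyond domain or tumour too small)"
            )
        j = below[0]
        x0, x1 = xseg[j - 1], xseg[j]
        y0, y1 = seg[j - 1], seg[j]
        return float(x0 + (y0 - level) * (x1 - x0) / (y0 - y1))

    x_hi = crossing(WIDTH_UPPER_LEVEL * rho_max)
    x_lo = crossing(WIDTH_LOWER_LEVEL * rho_max)
    return max(x_lo - x_hi, 0.0)


def effective_rates(
    state: SimulationState,
    params: ModelParameters,
    grid=None,
    x: np.ndarray | None = None,
    density_weighted: bool = False,
) -> tuple[float, float]:
    """Domain-averaged oxygen-modulated diffusion and proliferation rates.

    D_eff = (1/L) \\int D_rho * alpha(sigma(x)) dx and
    b_eff = (1/L) \\int b_rho * beta(sigma(x)) dx by trapezoidal quadrature.
    With sigma == sigma0 everywhere these equal the intrinsic (D, b) by the
    normalisation D_rho = D/alpha(sigma0), b_rho = b/beta(sigma0).

    ``density_weighted=True`` weights the averages by rho(x) instead of
    uniformly (sensitivity variant).
    """
    if x is None:
        if grid is None:
            raise ValueError("pass either a grid or node coordinates x")
        x = grid.x
    p = params
    alpha0, beta0 = switch_fractions(p.sigma0, p)
    alpha, beta = switch_fractions(state.sigma, p)
    D_field = (p.D / alpha0) * np.asarray(alpha)
    b_field = (p.b / beta0) * np.asarray(beta)
    if density_weighted:
        w = np.asarray(state.rho, dtype=float)
        norm = np.trapezoid(w, x)
        if norm <= 0:
            raise FrontError("cannot density-weight: zero total density")
        return (
            float(np.trapezoid(D_field * w, x) / norm),
            float(np.trapezoid(b_field * w, x) / norm),
        )
    L = x[-1] - x[0]
    return (
        float(np.trapezoid(D_field, x) / L),
        float(np.trapezoid(b_field, x) / L),
    )


def observables_from_trajectory(
    trajectory: Trajectory, window: float = SPEED_WINDOW
) -> ObservableSet:
    """Evaluate the full observable set on a completed trajectory."""
    speed, rms = front_speed(trajectory, window=window)
    final = trajectory.final
    width = infiltration_width(final, grid=trajectory.grid)
    D_eff, b_eff = effective_rates(final, trajectory.params, grid=trajectory.grid)
    return ObservableSet(
        front_speed=speed,
        infiltration_width=width,
        D_eff=D_eff,
        b_eff=b_eff,
        t_eval=final.t,
        speed_residual=rms,
    )
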