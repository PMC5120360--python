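"""Reaction kinetics of the glioma--vasculature interplay model.

The model couples three fields on a 1-D tissue domain:

* ``rho`` -- total glioma cell density (cells/mm), the sum of a migratory
  (hypoxic) and a proliferative (normoxic) subpopulation that interconvert
  through oxygen-dependent linear switching rates ``f21 = lambda1 - sigma``
  (proliferative -> migratory) and ``f12 = lambda2 * sigma`` (migratory ->
  proliferative).  Because phenotype switching is fast relative to motility
  and division, the two subpopulations are in quasi-steady state and the
  migratory/proliferative fractions reduce to closed forms ``alpha(sigma)``
  and ``beta(sigma)`` with ``alpha + beta = 1``.
* ``v`` -- functional (perfused) tumour vasculature, dimensionless in
  [0, 1]; normal tissue sits at 1/2.  Vessels form logistically at a rate
  gated by a Michaelis--Menten response to the (quasi-steady) pro-angiogenic
  factor concentration that hypoxic cells secrete, and are occluded at high
  cell density through a power-law sink ``g2 * v * rho**n``.
* ``sigma`` -- oxygen concentration (nmol/mm), supplied by functional
  vessels proportionally to the deficit from the physiological level
  ``sigma0`` and consumed by glioma cells by mass action.

Three nested model variants form a hierarchy: variant I (Fisher--KPP limit,
``sigma`` and ``v`` held constant), variant II (dynamic oxygen, constant
vasculature: ``g1 = g2 = 0``), and variant III (the full system).

This module owns the parameter container, the phenotype-switch fractions,
the smoothed Heaviside gate, the non-diffusive reaction terms of every
variant, and closed-form steady-state helpers used as test oracles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields, replace
from typing import NamedTuple

import numpy as np
from scipy.special import expit

__all__ = [
    "Variant",
    "ModelParameters",
    "SwitchFractions",
    "ReactionRates",
    "ParameterError",
    "DomainError",
    "switch_fractions",
    "smooth_heaviside",
    "angiogenic_activation",
    "occlusion_rate",
    "reaction_terms",
    "homogeneous_oxygen_steady_state",
]

# Relative oxygen overshoot (fraction of sigma0) tolerated before the switch
# fractions refuse to evaluate: larger excursions indicate solver blow-up.
SIGMA_OVERSHOOT_TOL = 0.01
# Clamp guard keeping sigma strictly below lambda1 when evaluating fractions.
_SIGMA_CLAMP_DELTA = 1e-12


class ParameterError(ValueError):
    """A model parameter violates its physical constraints."""


class DomainError(ValueError):
    """A field value lies outside the model's admissible range."""


class Variant(enum.Enum):
    """Model-hierarchy tag.

    I   : Fisher--KPP limit, constant oxygen and vasculature.
    II  : dynamic oxygen, constant vasculature (no formation/occlusion).
    III : full glioma--vasculature interplay.
    """

    I = "I"
    II = "II"
    III = "III"

    @classmethod
    def coerce(cls, value: "Variant | str") -> "Variant":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(
                f"unknown model variant {value!r}; expected one of I, II, III"
            ) from None


@dataclass(frozen=True)
class ModelParameters:
    """All rate and threshold constants of the model plus run settings.

    Units follow the 1-D formulation: densities are per mm of tissue,
    concentrations nmol/mm, rates per day.  Defaults follow the glioma-modelling
    literature; the intrinsic diffusion ``D``, proliferation ``b``,
    oxygen consumption ``h2`` and vaso-occlusion ``g2`` rates default to
    representative values inside their literature ranges (geometric midpoints
    for the two-decade ``D`` and ``b`` spans).
    """

    D: float = 2.73e-2          # intrinsic glioma diffusion, mm^2/day
    b: float = 2.73e-3          # intrinsic glioma proliferation, 1/day
    N: float = 1.0e2            # tissue carrying capacity, cells/mm
    sigma0: float = 1.0         # physiological oxygen, nmol/mm
    lambda1: float = 2.0        # switching parameter (prolif -> migr), nmol/mm
    lambda2: float = 1.0        # switching parameter (migr -> prolif), unitless
    D_sigma: float = 1.51e2     # oxygen diffusion, mm^2/day
    h1: float = 3.37e-1         # oxygen supply rate, 1/day
    h2: float = 5.73e-3         # cell oxygen consumption, mm/(cell day)
    D_v: float = 5.0e-4         # vasculature dispersal, mm^2/day
    g1: float = 1.0e-1          # vasculature formation rate, 1/day
    sigma_hat: float = 2.5e-1   # hypoxic oxygen threshold, nmol/mm
    K: float = 1.0              # half-maximal pro-angiogenic factor, nmol/mm
    g2: float = 5.0e-12         # vaso-occlusion rate, mm^n/(cell^n day)
    n: int = 6                  # vaso-occlusion degree, integer >= 1
    theta: float = 1.0e-2       # smoothed-Heaviside steepness, nmol/mm
    v0: float = 0.5             # normal functional vasculature, in (0, 1]
    rho0: float = 1.0e1         # initial glioma density amplitude, cells/mm
    eps: float = 2.0            # initial tumour segment length, mm
    gamma: float = 1.0e-1       # initial-condition steepness, mm
    L: float = 2.0e2            # domain length, mm
    T_f: float = 4.0e2          # final simulation time, day

    def __post_init__(self) -> None:
        problems: list[str] = []
        may_be_zero = {"g1", "g2", "h2"}
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                problems.append(f"{f.name} must be finite, got {value!r}")
            elif f.name in may_be_zero:
                if value < 0:
                    problems.append(f"{f.name} must be >= 0, got {value!r}")
            elif value <= 0:
                problems.append(f"{f.name} must be > 0, got {value!r}")
        if self.lambda1 <= self.sigma0:
            problems.append(
                f"lambda1 > sigma0 required (f21 = lambda1 - sigma must stay "
                f"positive on [0, sigma0]), got lambda1={self.lambda1!r}, "
                f"sigma0={self.sigma0!r}"
            )
        if not 0 < self.v0 <= 1:
            problems.append(f"v0 must lie in (0, 1], got {self.v0!r}")
        if not 0 < self.rho0 <= self.N:
            problems.append(f"rho0 must lie in (0, N], got {self.rho0!r}")
        if int(self.n) != self.n or self.n < 1:
            problems.append(f"n must be an integer >= 1, got {self.n!r}")
        if self.eps >= self.L:
            problems.append(
                f"initial segment eps={self.eps!r} must be shorter than "
                f"the domain L={self.L!r}"
            )
        if problems:
            raise ParameterError("; ".join(problems))

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced (revalidated)."""
        return replace(self, **kwargs)


class SwitchFractions(NamedTuple):
    """Quasi-steady migratory/proliferative population split.

    ``alpha`` is the migratory (hypoxic) fraction, ``beta`` the
    proliferative (normoxic) fraction; ``alpha + beta == 1`` exactly.
    """

    alpha: np.ndarray | float
    beta: np.ndarray | float


@dataclass(frozen=True)
class ReactionRates:
    """Non-diffusive right-hand sides for each field on the grid."""

    rho: np.ndarray
    v: np.ndarray
    sigma: np.ndarray


def switch_fractions(sigma, params: ModelParameters) -> SwitchFractions:
    """Oxygen-dependent migratory/proliferative fractions.

    alpha(sigma) = f21 / (f12 + f21) = (lambda1 - sigma) /
    ((lambda1 - sigma) + lambda2 * sigma), beta = 1 - alpha.  alpha is
    strictly decreasing in sigma on [0, lambda1): low oxygen pushes cells
    into the migratory phenotype.

    Raises
    ------
    DomainError
        If sigma lies outside [0, lambda1] beyond a small clamp guard
        (1% of sigma0) -- the signature of a solver blow-up.
    """
    sigma = np.asarray(sigma, dtype=float)
    p = params
    tol = SIGMA_OVERSHOOT_TOL * p.sigma0
    if np.any(sigma < -tol) or np.any(sigma > p.lambda1 + tol):
        raise DomainError(
            f"oxygen concentration outside [0, lambda1]={p.lambda1!r} beyond "
            f"tolerance: range [{sigma.min()!r}, {sigma.max()!r}]"
        )
    s = np.clip(sigma, 0.0, p.lambda1 - _SIGMA_CLAMP_DELTA)
    f21 = p.lambda1 - s
    f12 = p.lambda2 * s
    alpha = f21 / (f12 + f21)
    beta = 1.0 - alpha
    if sigma.ndim == 0:
        return SwitchFractions(float(alpha), float(beta))
    return SwitchFractions(alpha, beta)


def smooth_heaviside(xi, theta: float):
    """Logistic approximation of the decreasing Heaviside step.

    H(xi) -> 1 for xi << 0, -> 0 for xi >> 0, equals 1/2 at xi = 0 and
    converges pointwise (xi != 0) to the sharp step as theta -> 0.
    """
    if theta <= 0:
        raise ParameterError(f"Heaviside steepness theta must be > 0, got {theta!r}")
    xi = np.asarray(xi, dtype=float)
    out = expit(-xi / theta)  # overflow-safe on both tails
    if out.ndim == 0:
        return float(out)
    return out


def angiogenic_activation(rho, sigma, v, params: ModelParameters):
    """Michaelis--Menten activation M of vessel formation.

    M = rho*H(sigma - sigma_hat) / (rho*H(sigma - sigma_hat) + K*v), the
    saturating response to the quasi-steady pro-angiogenic factor
    concentration secreted by hypoxic cells (production k1*rho*H balanced by
    endothelial uptake k2*v, with natural decay negligible against uptake;
    K = mu*k2/k1 folds the kinetic constants into one half-saturation
    scale).  Defined as 0 at the degenerate point rho*H = 0, v = 0 (no
    factors and no vessels -> no formation).
    """
    rho = np.asarray(rho, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    v = np.asarray(v, dtype=float)
    production = rho * smooth_heaviside(sigma - params.sigma_hat, params.theta)
    denom = production + params.K * v
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(denom > 0, production / np.where(denom > 0, denom, 1.0), 0.0)
    if m.ndim == 0:
        return float(m)
    return m


# Steepness of the optional density gate on the occlusion term, as a
# fraction of the carrying capacity.
OCCLUSION_GATE_STEEPNESS = 0.02


def occlusion_rate(rho, v, params: ModelParameters, gate: bool = False):
    """Vaso-occlusion sink g2 * v * rho**n.

    With ``gate=True`` the sink is additionally multiplied by a smoothed
    step H(N/2 - rho) switching on above half the carrying capacity -- a
    sensitivity variant; the default power law alone already confines
    occlusion to near-capacity densities.
    """
    p = params
    rate = p.g2 * np.asarray(v, dtype=float) * np.asarray(rho, dtype=float) ** p.n
    if gate:
        rate = rate * smooth_heaviside(
            p.N / 2 - np.asarray(rho, dtype=float), OCCLUSION_GATE_STEEPNESS * p.N
        )
    return rate


def reaction_terms(
    state, params: ModelParameters, variant, occlusion_gate: bool = False
) -> ReactionRates:
    """Non-diffusive right-hand sides of the coupled system.

    rho: b_rho * beta(sigma) * rho * (1 - rho/N) with the normalisation
    b_rho = b / beta(sigma0), so that at physiological oxygen the logistic
    rate is exactly the intrinsic ``b``.  Variant I freezes beta at
    beta(sigma0), recovering plain logistic growth b*rho*(1 - rho/N).

    v (variant III only): g1 * M(rho, sigma, v) * v * (1 - v)
    - g2 * v * rho**n.  The power-law sink models pressure-driven
    vaso-occlusion; with n = 6 it is negligible below N/2 and strong above.

    sigma (variants II, III): h1 * v * (sigma0 - sigma) - h2 * rho * sigma.

    ``state`` needs attributes ``rho``, ``v``, ``sigma`` (arrays or scalars
    broadcast to a common shape).
    """
    variant = Variant.coerce(variant)
    p = params
    rho = np.atleast_1d(np.asarray(state.rho, dtype=float))
    v = np.atleast_1d(np.asarray(state.v, dtype=float))
    sigma = np.atleast_1d(np.asarray(state.sigma, dtype=float))
    rho, v, sigma = np.broadcast_arrays(rho, v, sigma)
    if rho.min() < 0 or v.min() < 0 or sigma.min() < 0:
        raise DomainError("negative field values passed to reaction_terms")

    beta0 = switch_fractions(p.sigma0, p).beta
    b_rho = p.b / beta0
    if variant is Variant.I:
        beta_eff = beta0
    else:
        beta_eff = switch_fractions(sigma, p).beta
    rho_rate = b_rho * beta_eff * rho * (1.0 - rho / p.N)

    if variant is Variant.III:
        m = angiogenic_activation(rho, sigma, v, p)
        v_rate = p.g1 * m * v * (1.0 - v) - occlusion_rate(rho, v, p, occlusion_gate)
    else:
        v_rate = np.zeros_like(rho)

    if variant is Variant.I:
        sigma_rate = np.zeros_like(rho)
    else:
        sigma_rate = p.h1 * v * (p.sigma0 - sigma) - p.h2 * rho * sigma

    return ReactionRates(rho=rho_rate, v=np.asarray(v_rate), sigma=sigma_rate)


def homogeneous_oxygen_steady_state(rho: float, v: float, params: ModelParameters) -> float:
    """Fixed point of the spatially uniform oxygen dynamics.

    With constant (rho, v) the oxygen equation relaxes to
    sigma* = h1*v*sigma0 / (h1*v + h2*rho) -- the balance of vascular
    supply and cellular consumption.  Used as a closed-form oracle for the
    solver's long-time behaviour.
    """
    p = params
    supply = p.h1 * v
    consumption = p.h2 * rho
    if supply + consumption <= 0:
        raise DomainError(
            "degenerate input: zero supply and consumption leave oxygen "
            "dynamics frozen (no steady state selected)"
        )
    return supply * p.sigma0 / (supply + consumption)
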