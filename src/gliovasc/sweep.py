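"""(D, b)-plane simulation maps and critical-threshold estimation.

A sweep integrates the model over a grid of intrinsic diffusion/proliferation
rates at several levels of a varied intervention parameter (oxygen
consumption ``h2`` or vaso-occlusion ``g2``), collects the invasion
observables per cell, forms difference maps between consecutive levels, and
estimates the critical thresholds that separate qualitatively different
responses:

* ``b*``  -- critical proliferation rate (h2 sweeps): front speed increases
  with h2 for b < b*, decreases for b > b*.
* ``b+``  -- smallest proliferation rate at which increased vaso-occlusion
  speeds the front up anywhere (g2 sweeps).
* ``Lambda+ = b/D`` -- critical proliferation/diffusion ratio: the sign
  boundary of the speed response in the (D, b) plane is approximately the
  line b = Lambda+ * D for b > b+.

Threshold estimators operate on sign brackets of the difference maps, with a
dead zone absorbing numerical noise: a speed change below 0.5% of the cell's
base speed counts as "no change".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import ModelParameters, Variant
from .observables import FrontError, observables_from_trajectory
from .solver import Grid1D, IntegrationError, build_grid, default_output_times, integrate

__all__ = [
    "SweepSpec",
    "SweepResult",
    "ThresholdEstimate",
    "LambdaEstimate",
    "SweepError",
    "run_sweep",
    "diff_maps",
    "estimate_critical_b",
    "estimate_lambda_plus",
]

# |delta speed| below this fraction of the cell's base speed is "no change".
DEAD_ZONE = 0.005

OBSERVABLE_COLUMNS = ["front_speed", "infiltration_width", "D_eff", "b_eff"]


class SweepError(RuntimeError):
    """A sweep-level failure (aggregate of per-cell errors or bad inputs)."""


@dataclass(frozen=True)
class SweepSpec:
    """Declarative description of a (D, b) x varied-parameter sweep."""

    D_values: tuple
    b_values: tuple
    varied_name: str            # "h2" or "g2" ("" for a single-level sweep)
    varied_values: tuple
    base: ModelParameters
    variant: Variant
    nx: int | None = None       # grid nodes; default from solver
    output_every: float = 10.0  # days between snapshots

    def __post_init__(self):
        object.__setattr__(self, "D_values", tuple(float(d) for d in self.D_values))
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        object.__setattr__(
            self, "varied_values", tuple(float(v) for v in self.varied_values)
        )
        object.__setattr__(self, "variant", Variant.coerce(self.variant))
        for name, vals in (("D_values", self.D_values), ("b_values", self.b_values)):
            if len(vals) < 1 or np.any(np.diff(vals) <= 0):
                raise ValueError(f"{name} must be non-empty and strictly increasing")
        if self.varied_name not in ("h2", "g2", ""):
            raise ValueError(f"varied_name must be 'h2' or 'g2', got {self.varied_name!r}")
        if self.varied_name == "" and len(self.varied_values) > 0:
            raise ValueError("varied_values given without a varied_name")
        if self.variant is Variant.II and self.varied_name == "g2":
            raise ValueError("variant II has no vasculature dynamics: cannot vary g2")
        if self.variant is Variant.I and self.varied_name:
            raise ValueError("variant I has no oxygen or vasculature dynamics")

    @property
    def levels(self) -> tuple:
        """Varied-parameter levels; a single implicit level if none varied."""
        return self.varied_values if self.varied_name else (float("nan"),)


@dataclass
class ThresholdEstimate:
    """Bracketed critical proliferation rate b* from an h2 sweep."""

    b_lo: float | None
    b_hi: float | None
    per_column: list = field(default_factory=list)  # (D, lo, hi) per D column
    ambiguous_columns: list = field(default_factory=list)
    no_crossing: bool = False

    @property
    def midpoint(self) -> float | None:
        if self.no_crossing or self.b_lo is None:
            return None
        return float(np.sqrt(self.b_lo * self.b_hi))  # log-scale midpoint


@dataclass
class LambdaEstimate:
    """Critical rate b+ and ratio boundary Lambda+ = b/D from a g2 sweep."""

    b_plus: float | None
    lambda_plus: float | None
    boundary_points: list = field(default_factory=list)  # (D_mid, b) midpoints
    residual: float | None = None  # RMS of log-b misfit, grid-cell units
    no_region: bool = False


@dataclass
class SweepResult:
    """Tidy per-cell observables plus the spec that produced them."""

    spec: SweepSpec
    table: pd.DataFrame  # columns: D, b, varied_name, varied_value, observables, status

    def pivot(self, observable: str, level: float) -> pd.DataFrame:
        """(b x D) matrix of one observable at one varied level.

        Levels are matched exactly (they are the floats of the spec); NaN
        stands for the implicit single level of an unvaried sweep.  With
        repeated identical levels the first occurrence is used.
        """
        levels = np.asarray(self.spec.levels, dtype=float)
        if np.isnan(level):
            matches = np.nonzero(np.isnan(levels))[0]
        else:
            matches = np.nonzero(levels == level)[0]
        if len(matches) == 0:
            raise KeyError(f"level {level!r} not in sweep levels {levels!r}")
        return self.pivot_by_index(observable, int(matches[0]))

    def pivot_by_index(self, observable: str, k: int) -> pd.DataFrame:
        """(b x D) matrix of one observable at the k-th varied level."""
        sub = self.table[self.table["level_index"] == k]
        return sub.pivot(index="b", columns="D", values=observable)

    @property
    def failures(self) -> pd.DataFrame:
        return self.table[self.table["status"] != "ok"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def thresholds_to_json(self, path, **estimates) -> None:
        def encode(obj):
            if isinstance(obj, (ThresholdEstimate, LambdaEstimate)):
                return {k: v for k, v in vars(obj).items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(f"not JSON-serialisable: {type(obj)}")

        with open(path, "w") as fh:
            json.dump(estimates, fh, indent=2, default=encode)


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Run every (D, b, level) cell and collect observables.

    Cells run with identical numerical settings; a failing cell carries a
    typed status marker (never a silent default).  Execution order cannot
    affect results -- each cell is an independent deterministic integration.
    """
    base = spec.base
    grid: Grid1D | None = None
    if spec.nx is not None:
        grid = build_grid(base.L, spec.nx)
    rows = []
    for k, level in enumerate(spec.levels):
        for D in spec.D_values:
            for b in spec.b_values:
                updates = {"D": D, "b": b}
                if spec.varied_name:
                    updates[spec.varied_name] = level
                params = base.with_updates(**updates)
                row = {
                    "D": D,
                    "b": b,
                    "varied_name": spec.varied_name,
                    "varied_value": level,
                    "level_index": k,
                }
                try:
                    traj = integrate(
                        params,
                        spec.variant,
                        grid=grid,
                        output_times=default_output_times(params, spec.output_every),
                    )
                    obs = observables_from_trajectory(traj)
                except (IntegrationError, FrontError) as exc:
                    row.update(
                        {c: np.nan for c in OBSERVABLE_COLUMNS},
                        status=f"{type(exc).__name__}: {exc}",
                    )
                else:
                    row.update(
                        front_speed=obs.front_speed,
                        infiltration_width=obs.infiltration_width,
                        D_eff=obs.D_eff,
                        b_eff=obs.b_eff,
                        status="ok",
                    )
                rows.append(row)
                if progress:
                    print(
                        f"  cell D={D:.3g} b={b:.3g} {spec.varied_name}={level:.3g} "
                        f"-> {row['status']}"
                    )
    return SweepResult(spec=spec, table=pd.DataFrame(rows))


def diff_maps(result: SweepResult, observable: str) -> list[pd.DataFrame]:
    """Differences of one observable between consecutive varied levels.

    Element k is pivot(level[k+1]) - pivot(level[k]), a (b x D) frame.
    """
    levels = result.spec.levels
    if len(levels) < 2:
        raise SweepError("need at least two varied levels to form difference maps")
    pivots = [result.pivot_by_index(observable, k) for k in range(len(levels))]
    return [pivots[k + 1] - pivots[k] for k in range(len(pivots) - 1)]


def _sign_map(result: SweepResult, dead_zone: float = DEAD_ZONE) -> pd.DataFrame:
    """Sign of the front-speed change (last vs first level), with dead zone.

    +1 / -1 where |delta| exceeds ``dead_zone`` times the base (first-level)
    speed, 0 inside the dead zone, NaN where either run failed.
    """
    levels = result.spec.levels
    base = result.pivot_by_index("front_speed", 0)
    high = result.pivot_by_index("front_speed", len(levels) - 1)
    delta = high - base
    out = pd.DataFrame(0.0, index=base.index, columns=base.columns)
    out[delta > dead_zone * base] = 1.0
    out[delta < -dead_zone * base] = -1.0
    out[base.isna() | high.isna()] = np.nan
    return out


def estimate_critical_b(
    result: SweepResult, observable: str = "front_speed", dead_zone: float = DEAD_ZONE
) -> ThresholdEstimate:
    """Bracket the critical proliferation rate b* from an h2 sweep.

    In each D column, the speed change (highest vs lowest h2 level) flips
    from positive at low b to negative at high b; the flip is bracketed
    between adjacent grid values.  Returns the median bracket across columns
    with the min/max spread in ``per_column``; columns with multiple
    crossings are reported in ``ambiguous_columns``.
    """
    if observable != "front_speed":
        raise ValueError("b* is defined on the front-speed response")
    if result.spec.varied_name != "h2" or len(result.spec.levels) < 2:
        raise SweepError("b* estimation requires an h2 sweep with >= 2 levels")
    signs = _sign_map(result, dead_zone)
    b_vals = signs.index.to_numpy()
    per_column: list[tuple[float, float, float]] = []
    ambiguous = []
    for D in signs.columns:
        col = signs[D].to_numpy()
        # positions where the sign transitions from >=0 to <0 (zero cells
        # inside the dead zone are carried over the previous definite sign)
        brackets = []
        last_def = None
        last_def_b = None
        for bv, s in zip(b_vals, col):
            if np.isnan(s) or s == 0:
                continue
            if last_def is not None and s != last_def:
                brackets.append((last_def_b, bv))
            last_def = s
            last_def_b = bv
        if len(brackets) > 1:
            ambiguous.append((float(D), brackets))
        if brackets:
            lo, hi = brackets[0]
            per_column.append((float(D), float(lo), float(hi)))
    est = ThresholdEstimate(b_lo=None, b_hi=None, per_column=per_column,
                            ambiguous_columns=ambiguous)
    if not per_column:
        est.no_crossing = True
        return est
    los = np.array([p[1] for p in per_column])
    his = np.array([p[2] for p in per_column])
    est.b_lo = float(np.median(los))
    est.b_hi = float(np.median(his))
    return est


def estimate_lambda_plus(
    result: SweepResult, dead_zone: float = DEAD_ZONE
) -> LambdaEstimate:
    """Estimate (b+, Lambda+) from a g2 sweep.

    Cells are classified by the sign of the front-speed change between the
    lowest and highest g2 level.  ``b+`` is the smallest b whose row holds a
    positive cell.  Within rows b > b+ (and the b+ row itself), the sign
    boundary along D is located and its log-midpoint collected; the line
    b = Lambda+ * D is fitted through the boundary points by least squares
    in log space (slope fixed at 1, intercept = log Lambda+).

    Raises
    ------
    SweepError
        If fewer than 3 boundary points are resolvable.
    """
    if result.spec.varied_name != "g2" or len(result.spec.levels) < 2:
        raise SweepError("Lambda+ estimation requires a g2 sweep with >= 2 levels")
    signs = _sign_map(result, dead_zone)
    b_vals = signs.index.to_numpy()
    D_vals = signs.columns.to_numpy()
    rows_with_pos = [bv for bv in b_vals if (signs.loc[bv] == 1).any()]
    if not rows_with_pos:
        return LambdaEstimate(b_plus=None, lambda_plus=None, no_region=True)
    b_plus = float(min(rows_with_pos))

    boundary = []
    for bv in b_vals:
        if bv < b_plus:
            continue
        col = signs.loc[bv].to_numpy()
        # scan along D: speed response flips from negative (low D, high b/D)
        # to positive (high D, low b/D) at the Lambda+ line
        last_def = None
        last_def_D = None
        for Dv, s in zip(D_vals, col):
            if np.isnan(s) or s == 0:
                continue
            if last_def is not None and s != last_def and last_def < 0 < s:
                boundary.append((float(np.sqrt(last_def_D * Dv)), float(bv)))
            last_def = s
            last_def_D = Dv
    if len(boundary) < 3:
        raise SweepError(
            f"only {len(boundary)} sign-boundary points resolved; the sweep "
            "grid is too coarse to fit the Lambda+ line"
        )
    D_mid = np.array([p[0] for p in boundary])
    b_at = np.array([p[1] for p in boundary])
    # least squares on log b = log Lambda+ + log D (unit slope)
    log_lambda = float(np.mean(np.log(b_at) - np.log(D_mid)))
    lam = float(np.exp(log_lambda))
    misfit = np.log(b_at) - (log_lambda + np.log(D_mid))
    # express residual in grid-cell units of the (log-spaced) b axis
    if len(b_vals) > 1:
        cell = float(np.mean(np.diff(np.log(b_vals))))
    else:
        cell = 1.0
    rms = float(np.sqrt(np.mean(misfit**2)) / cell)
    return LambdaEstimate(
        b_plus=b_plus,
        lambda_plus=lam,
        boundary_points=boundary,
        residual=rms,
    )
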