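"""Window-restricted least-squares fitting of pair potentials.

Points are restricted to an energy window around the well (by default
E ≤ 20 kJ/mol on the repulsive wall and |E| ≥ 10 % of the well depth in
the tail), the unweighted sum of squared energy residuals is minimized
by a bounded trust-region least-squares solver with seeded
Latin-hypercube multi-starts, and the RMSE over the windowed points is
reported.  Bounds are curve-adaptive by default and user-overridable;
loosely chosen bounds can trap the optimizer, which is why every result
records the bounds and seed actually used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import qmc

from .curves import CurveError, DissociationCurve
from .potentials import (
    FAMILY_PARAMS,
    PotentialError,
    PotentialModel,
    evaluate_energy,
)


class FitError(ValueError):
    """Fitting preconditions violated or no restart converged."""


@dataclass(frozen=True)
class EnergyWindow:
    """Repulsive inclusion limit (kJ/mol) and tail cut as a fraction of
    the curve's well depth."""

    upper_cut: float = 20.0
    lower_frac: float = 0.10

    def __post_init__(self):
        if self.upper_cut <= 0:
            raise FitError("upper_cut must be positive")
        if not (0 < self.lower_frac < 1):
            raise FitError("lower_frac must be in (0, 1)")


def refined_depth(curve: DissociationCurve) -> tuple[float, float]:
    """Well position and depth of a tabulated curve, spline-refined.

    Coarse grids misplace shallow minima; the cubic-spline minimum near
    the grid minimum is used instead of the raw grid value.
    """
    i = int(np.argmin(curve.energy))
    if curve.energy[i] >= 0:
        raise CurveError("curve has no negative point")
    if len(curve) >= 4 and 0 < i < len(curve) - 1:
        cs = curve.spline()
        res = minimize_scalar(
            cs, bounds=(curve.r[max(i - 1, 0)], curve.r[min(i + 1, len(curve) - 1)]),
            method="bounded", options={"xatol": 1e-10},
        )
        if res.fun < curve.energy[i]:
            return float(res.x), float(-res.fun)
    return float(curve.r[i]), float(-curve.energy[i])


def select_window(curve: DissociationCurve, window: EnergyWindow) -> DissociationCurve:
    """Subset of points with E ≤ upper_cut and |E| ≥ lower_frac·depth.

    The depth is the spline-refined magnitude of the curve's minimum;
    retained points keep their original grid values.
    """
    _, depth = refined_depth(curve)
    mask = (curve.energy <= window.upper_cut) & (
        np.abs(curve.energy) >= window.lower_frac * depth
    )
    if not mask.any():
        raise FitError("energy window retains no points")
    return curve.subset(mask)


@dataclass
class FitResult:
    model: PotentialModel
    window: EnergyWindow
    n_points: int
    residuals: np.ndarray
    rmse: float
    bounds_used: dict[str, tuple[float, float]]
    converged: bool
    seed: int | None = None
    cost_trace: list = field(default_factory=list)


def curve_rmse(model: PotentialModel, curve_subset: DissociationCurve) -> float:
    """Root-mean-square energy deviation of a model over a point subset."""
    if len(curve_subset) == 0:
        raise FitError("empty curve subset")
    pred = evaluate_energy(model, curve_subset.r)
    return float(np.sqrt(np.mean((pred - curve_subset.energy) ** 2)))


# --------------------------------------------------------------------------
# default bounds

#: fixed per-family boxes for the dimensionless shape parameters
_SHAPE_BOUNDS = {
    "MRS": {"gamma": (2.0, 30.0)},
    "WBH": {"gamma": (2.0, 40.0)},
    "MBH": {"gamma": (6.5, 40.0)},
    "GBH": {"gamma": (7.0, 40.0), "delta": (3.0, 6.95)},
    "LJ14-7": {"gamma": (1e-3, 5.0), "delta": (1e-3, 5.0)},
    "TT": {
        "A": (1.0, 1e8),
        "b": (3.0, 30.0),
        "C6": (0.0, 10.0),
        "C8": (0.0, 10.0),
        "C10": (0.0, 10.0),
    },
}


def default_bounds(family: str, curve: DissociationCurve) -> dict[str, tuple[float, float]]:
    """Curve-adaptive parameter boxes: σ within a factor 2 of the well
    position, ε within a factor 10 of the well depth, generous physical
    boxes for shape parameters."""
    r_well, depth = refined_depth(curve)
    b: dict[str, tuple[float, float]] = {}
    names = FAMILY_PARAMS[family]
    if "sigma" in names:
        b["sigma"] = (0.5 * r_well, 2.0 * r_well)
    if "epsilon" in names:
        b["epsilon"] = (0.1 * depth, 10.0 * depth)
    if family == "BHA":
        c6_scale = depth * r_well**6
        b["A"] = (depth, 1e7 * depth)
        b["b"] = (0.5, 10.0)
        b["C6"] = (0.05 * c6_scale, 100.0 * c6_scale)
    b.update(_SHAPE_BOUNDS.get(family, {}))
    return b


def _initial_guess(family, r_well, depth, bounds):
    guess = {
        "sigma": r_well,
        "epsilon": depth,
        "gamma": {"LJ14-7": 0.15}.get(family, 12.0),
        "delta": {"LJ14-7": 0.1, "GBH": 6.0}.get(family, 6.0),
        "A": 1e4 * depth if family == "BHA" else 50.0,
        "b": 12.0 / r_well if family == "BHA" else 8.0,
        "C6": 2.0 * depth * r_well**6 if family == "BHA" else 1.2,
        "C8": 0.5,
        "C10": 0.2,
    }
    x0 = []
    for name in FAMILY_PARAMS[family]:
        lo, hi = bounds[name]
        x0.append(min(max(guess[name], lo), hi))
    return np.array(x0)


def fit_potential(
    family: str,
    curve: DissociationCurve,
    window: EnergyWindow | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 16,
    constants: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit one potential family to a dissociation curve.

    Bounded least squares from ``n_starts`` seeded Latin-hypercube
    starting points plus one heuristic start; the lowest objective wins
    (ties by first found).  For the TT family, Re and De are held fixed
    as ``constants`` and only the five dimensionless parameters are
    adjusted; if not given they default to the curve's spline-refined
    well position and depth.
    """
    if window is None:
        window = EnergyWindow()
    sub = select_window(curve, window)
    names = FAMILY_PARAMS[family]
    if len(sub) < len(names):
        raise FitError(
            f"windowed subset has {len(sub)} points, fewer than the "
            f"{len(names)} free parameters of {family}"
        )
    r_well, depth = refined_depth(curve)
    box = dict(default_bounds(family, curve))
    if bounds:
        box.update({k: tuple(v) for k, v in bounds.items()})
    for name in names:
        lo, hi = box[name]
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise FitError(f"invalid bounds for {name}: {(lo, hi)}")
    consts = dict(constants) if constants else {}
    if family == "TT" and not consts:
        consts = {"Re": r_well, "De": depth}

    lo = np.array([box[n][0] for n in names])
    hi = np.array([box[n][1] for n in names])
    log_mask = np.array(
        [box[n][0] > 0 and box[n][1] / box[n][0] > 100 for n in names]
    )

    def residuals(x):
        try:
            m = PotentialModel(family, dict(zip(names, x)), consts)
            pred = evaluate_energy(m, sub.r)
        except PotentialError:
            return np.full(len(sub), 1e6)
        res = pred - sub.energy
        return np.where(np.isfinite(res), res, 1e6)

    starts = [_initial_guess(family, r_well, depth, box)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        unit = sampler.random(n_starts - 1)
        for row in unit:
            x = np.empty(len(names))
            for j in range(len(names)):
                if log_mask[j]:
                    x[j] = lo[j] * (hi[j] / lo[j]) ** row[j]
                else:
                    x[j] = lo[j] + row[j] * (hi[j] - lo[j])
            starts.append(x)

    best = None
    trace = []
    eps_lo = np.nextafter(lo, hi)
    for x0 in starts:
        x0c = np.clip(x0, eps_lo, hi)
        try:
            sol = least_squares(
                residuals, x0c, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:
            continue
        trace.append(float(sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all restarts diverged")

    model = PotentialModel(family, dict(zip(names, best.x)), consts)
    res = evaluate_energy(model, sub.r) - sub.energy
    return FitResult(
        model=model,
        window=window,
        n_points=len(sub),
        residuals=res,
        rmse=float(np.sqrt(np.mean(res**2))),
        bounds_used={n: tuple(box[n]) for n in names},
        converged=bool(best.success),
        seed=seed,
        cost_trace=trace,
    )
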