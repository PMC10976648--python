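"""Analytic van der Waals pair-potential families.

Nine families are implemented, all returning pair interaction energies in
kJ/mol for separations in Å:

``LJ12-6``
    E = 4ε[(σ/r)¹² − (σ/r)⁶], σ the zero-crossing, minimum at 2^{1/6}σ.
``LJ8-6``
    E = ε[3(σ/r)⁸ − 4(σ/r)⁶], σ the minimum position, depth ε.
``LJ14-7``
    Buffered 14-7 (Halgren), x = r/σ:
    E = ε ((1+δ)/(x+δ))⁷ ((1+γ)/(x⁷+γ) − 2), γ and δ dimensionless
    buffering constants treated as free parameters.
``MRS``
    Morse with dimensionless steepness γ:
    E = ε[e^{2γ(1−r/σ)} − 2 e^{γ(1−r/σ)}], minimum (σ, −ε).
``BHA``
    Original Buckingham, E = A e^{−br} − C6/r⁶ (A kJ/mol, b 1/Å,
    C6 kJ Å⁶/mol).  Diverges to −∞ at r → 0 for C6 > 0.
``MBH``
    Modified Buckingham (exp-6) in well form, requires γ > 6:
    E = ε/(1 − 6/γ) [(6/γ) e^{γ(1−r/σ)} − (σ/r)⁶]; algebraically
    identical to BHA under the conversion in :func:`mbh_to_bha`.
``WBH``
    Wang–Buckingham, an exp-6 with the r → 0 divergence removed by a
    buffered dispersion:
    E = 2ε/(1 − 3/(γ+3)) · σ⁶/(σ⁶+r⁶) · [(3/(γ+3)) e^{γ(1−r/σ)} − 1].
    Finite at r = 0, minimum (σ, −ε).
``GBH``
    Generalized four-parameter Buckingham with adjustable long-range
    attraction exponent δ (γ > δ):
    E = ε/(1 − δ/γ) [(δ/γ) e^{γ(1−r/σ)} − (σ/r)^δ].
``TT``
    Tang–Toennies in dimensionless notation, x = r/R_e:
    E = D_e [A* e^{−b x} − Σ_{n=3..5} f_{2n}(b x) C*_{2n} x^{−2n}],
    f_{2n}(y) = 1 − e^{−y} Σ_{k≤2n} yᵏ/k! the incomplete-gamma damping.
    R_e (Å) and D_e (kJ/mol) are fixed constants, not fitted.

The canonical parameter order of each family (used for rule notation and
report columns) follows the convention epsilon/sigma first, then the
shape parameters; for BHA it is (A, C6, b), for TT (A, b, C6, C8, C10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import yaml
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammainc


class PotentialError(ValueError):
    """Invalid potential parameters or evaluation domain."""


class NoMinimumError(PotentialError):
    """The potential has no bound minimum."""


#: canonical parameter order per family
FAMILY_PARAMS: dict[str, tuple[str, ...]] = {
    "LJ12-6": ("epsilon", "sigma"),
    "LJ8-6": ("epsilon", "sigma"),
    "WBH": ("epsilon", "sigma", "gamma"),
    "MBH": ("epsilon", "sigma", "gamma"),
    "MRS": ("epsilon", "sigma", "gamma"),
    "BHA": ("A", "C6", "b"),
    "GBH": ("epsilon", "sigma", "gamma", "delta"),
    "LJ14-7": ("epsilon", "sigma", "gamma", "delta"),
    "TT": ("A", "b", "C6", "C8", "C10"),
}

#: families listed in the conventional report column order
FAMILIES: tuple[str, ...] = (
    "LJ12-6",
    "LJ8-6",
    "WBH",
    "MBH",
    "MRS",
    "BHA",
    "GBH",
    "LJ14-7",
    "TT",
)

#: families whose derivatives are evaluated from closed forms
ANALYTIC_DERIVATIVE_FAMILIES = frozenset({"LJ12-6", "LJ8-6", "MRS", "BHA", "MBH"})


@dataclass(frozen=True)
class PotentialModel:
    """A potential family plus its named parameter vector.

    Parameters live in ``params`` keyed by the names in
    :data:`FAMILY_PARAMS`; the TT family additionally requires the fixed
    well constants ``Re`` (Å) and ``De`` (kJ/mol) in ``constants``.
    """

    family: str
    params: Mapping[str, float]
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILY_PARAMS:
            raise PotentialError(
                f"unknown family {self.family!r}; known: {sorted(FAMILY_PARAMS)}"
            )
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "constants", dict(self.constants))
        names = FAMILY_PARAMS[self.family]
        missing = set(names) - set(self.params)
        if missing:
            raise PotentialError(f"{self.family}: missing parameters {sorted(missing)}")
        extra = set(self.params) - set(names)
        if extra:
            raise PotentialError(f"{self.family}: unknown parameters {sorted(extra)}")
        for k, v in self.params.items():
            if not math.isfinite(v):
                raise PotentialError(f"{self.family}: parameter {k} is not finite")
        _validate_params(self.family, self.params, self.constants)

    @property
    def param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in FAMILY_PARAMS[self.family]])

    def with_params(self, values: Iterable[float]) -> "PotentialModel":
        names = FAMILY_PARAMS[self.family]
        return PotentialModel(self.family, dict(zip(names, values)), self.constants)


def _validate_params(family, p, consts):
    def positive(*names):
        for n in names:
            if p[n] <= 0:
                raise PotentialError(f"{family}: parameter {n} must be > 0")

    if family in ("LJ12-6", "LJ8-6", "WBH", "MRS"):
        positive("epsilon", "sigma")
    if family == "WBH":
        positive("gamma")
    if family == "MRS":
        positive("gamma")
    if family == "MBH":
        positive("epsilon", "sigma")
        if p["gamma"] <= 6:
            raise PotentialError("MBH: gamma must exceed 6 (exp-6 diverges otherwise)")
    if family == "BHA":
        positive("A", "b")
        if p["C6"] < 0:
            raise PotentialError("BHA: C6 must be >= 0")
    if family == "GBH":
        positive("epsilon", "sigma", "gamma", "delta")
        if p["gamma"] <= p["delta"]:
            raise PotentialError("GBH: gamma must exceed delta")
    if family == "LJ14-7":
        positive("epsilon", "sigma", "gamma", "delta")
    if family == "TT":
        positive("A", "b")
        for n in ("C6", "C8", "C10"):
            if p[n] < 0:
                raise PotentialError(f"TT: {n} must be >= 0")
        for c in ("Re", "De"):
            if c not in consts or consts[c] <= 0:
                raise PotentialError("TT: constants Re > 0 and De > 0 are required")


# --------------------------------------------------------------------------
# energies


def _e_lj12_6(p, r):
    sr6 = (p["sigma"] / r) ** 6
    return 4.0 * p["epsilon"] * (sr6 * sr6 - sr6)


def _e_lj8_6(p, r):
    sr2 = (p["sigma"] / r) ** 2
    sr6 = sr2**3
    return p["epsilon"] * (3.0 * sr6 * sr2 - 4.0 * sr6)


def _e_lj14_7(p, r):
    x = r / p["sigma"]
    g, d = p["gamma"], p["delta"]
    buf = ((1.0 + d) / (x + d)) ** 7
    return p["epsilon"] * buf * ((1.0 + g) / (x**7 + g) - 2.0)


def _e_mrs(p, r):
    g = p["gamma"]
    t = np.exp(g * (1.0 - r / p["sigma"]))
    return p["epsilon"] * (t * t - 2.0 * t)


def _e_bha(p, r):
    return p["A"] * np.exp(-p["b"] * r) - p["C6"] / r**6


def _e_mbh(p, r):
    g = p["gamma"]
    pref = p["epsilon"] / (1.0 - 6.0 / g)
    return pref * ((6.0 / g) * np.exp(g * (1.0 - r / p["sigma"])) - (p["sigma"] / r) ** 6)


def _e_wbh(p, r):
    g = p["gamma"]
    s6 = p["sigma"] ** 6
    k = 3.0 / (g + 3.0)
    pref = 2.0 * p["epsilon"] / (1.0 - k)
    return pref * s6 / (s6 + r**6) * (k * np.exp(g * (1.0 - r / p["sigma"])) - 1.0)


def _e_gbh(p, r):
    g, d = p["gamma"], p["delta"]
    pref = p["epsilon"] / (1.0 - d / g)
    return pref * ((d / g) * np.exp(g * (1.0 - r / p["sigma"])) - (p["sigma"] / r) ** d)


def tt_damping(n2: int, y):
    """Tang–Toennies damping f_{2n}(y) = 1 − e^{−y} Σ_{k≤2n} yᵏ/k!.

    Evaluated as the regularized lower incomplete gamma function
    P(2n+1, y), which is free of the catastrophic cancellation the
    subtracted form suffers at small y.
    """
    return gammainc(n2 + 1, y)


def _e_tt(p, r, consts):
    x = np.asarray(r, dtype=float) / consts["Re"]
    y = p["b"] * x
    u = p["A"] * np.exp(-y)
    for n2, key in ((6, "C6"), (8, "C8"), (10, "C10")):
        c = p[key]
        if c:
            u = u - tt_damping(n2, y) * c / x**n2
    return consts["De"] * u


_ENERGY: dict[str, Callable] = {
    "LJ12-6": _e_lj12_6,
    "LJ8-6": _e_lj8_6,
    "LJ14-7": _e_lj14_7,
    "MRS": _e_mrs,
    "BHA": _e_bha,
    "MBH": _e_mbh,
    "WBH": _e_wbh,
    "GBH": _e_gbh,
}


def evaluate_energy(model: PotentialModel, r):
    """Pair interaction energy in kJ/mol at separation(s) ``r`` (Å).

    ``r`` must be positive for every family except WBH, which is finite
    (and defined) at r = 0.
    """
    arr = np.asarray(r, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if model.family == "WBH":
        if np.any(arr < 0):
            raise PotentialError("WBH: separation must be >= 0")
    elif np.any(arr <= 0):
        raise PotentialError(f"{model.family}: separation must be > 0")
    if model.family == "TT":
        e = _e_tt(model.params, arr, model.constants)
    else:
        e = _ENERGY[model.family](model.params, arr)
    e = np.asarray(e, dtype=float)
    if not np.all(np.isfinite(e)):
        bad = arr[~np.isfinite(e)]
        raise PotentialError(
            f"{model.family}: non-finite energy at r = {bad[:5].tolist()}"
        )
    return float(e[0]) if scalar else e


# --------------------------------------------------------------------------
# derivatives


def _d_lj12_6(p, r, k):
    s, e = p["sigma"], p["epsilon"]
    out = 0.0 * r
    for n, c in ((12, 4 * e), (6, -4 * e)):
        fac = c * s**n * math.prod(range(n, n + k)) * (-1) ** k
        out = out + fac / r ** (n + k)
    return out


def _d_lj8_6(p, r, k):
    s, e = p["sigma"], p["epsilon"]
    out = 0.0 * r
    for n, c in ((8, 3 * e), (6, -4 * e)):
        fac = c * s**n * math.prod(range(n, n + k)) * (-1) ** k
        out = out + fac / r ** (n + k)
    return out


def _d_mrs(p, r, k):
    g, s, e = p["gamma"], p["sigma"], p["epsilon"]
    t = np.exp(g * (1.0 - r / s))
    a = -g / s
    return e * ((2 * a) ** k * t * t - 2.0 * a**k * t)


def _d_bha(p, r, k):
    n, c = 6, -p["C6"]
    disp = c * math.prod(range(n, n + k)) * (-1) ** k / r ** (n + k)
    return p["A"] * (-p["b"]) ** k * np.exp(-p["b"] * r) + disp


def _d_mbh(p, r, k):
    g, s, e = p["gamma"], p["sigma"], p["epsilon"]
    pref = e / (1.0 - 6.0 / g)
    a = -g / s
    rep = (6.0 / g) * a**k * np.exp(g * (1.0 - r / s))
    disp = -(s**6) * math.prod(range(6, 6 + k)) * (-1) ** k / r ** (6 + k)
    return pref * (rep + disp)


_DERIV: dict[str, Callable] = {
    "LJ12-6": _d_lj12_6,
    "LJ8-6": _d_lj8_6,
    "MRS": _d_mrs,
    "BHA": _d_bha,
    "MBH": _d_mbh,
}

# 4th-order central stencils, offsets -3..3 in units of h
_STENCILS = {
    1: ({-2: 1 / 12, -1: -2 / 3, 1: 2 / 3, 2: -1 / 12}, 1),
    2: ({-2: -1 / 12, -1: 4 / 3, 0: -5 / 2, 1: 4 / 3, 2: -1 / 12}, 2),
    3: ({-3: 1 / 8, -2: -1, -1: 13 / 8, 1: -13 / 8, 2: 1, 3: -1 / 8}, 3),
}


def evaluate_derivative(model: PotentialModel, r, order: int = 1):
    """d^order E/dr^order in kJ/mol/Å^order, order in {1, 2, 3}.

    Closed forms are used for the families in
    :data:`ANALYTIC_DERIVATIVE_FAMILIES`; the remaining families use a
    fourth-order central finite difference with step scaled to r.
    """
    if order not in (1, 2, 3):
        raise PotentialError("derivative order must be 1, 2 or 3")
    arr = np.atleast_1d(np.asarray(r, dtype=float))
    scalar = np.asarray(r).ndim == 0
    if model.family in _DERIV:
        out = _DERIV[model.family](model.params, arr, order)
    else:
        h = 1e-3 * np.maximum(arr, 0.5)
        stencil, pw = _STENCILS[order]
        out = np.zeros_like(arr)
        for off, w in stencil.items():
            out += w * evaluate_energy(model, arr + off * h)
        out /= h**pw
    out = np.asarray(out, dtype=float)
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# well location


def _length_scale(model: PotentialModel) -> float:
    p = model.params
    if model.family == "BHA":
        # dispersion/repulsion crossover sets the scale
        return max(1.0 / p["b"], (p["C6"] / p["A"]) ** (1 / 6) if p["C6"] else 1.0)
    if model.family == "TT":
        return model.constants["Re"]
    return p["sigma"]


def locate_well(model: PotentialModel, refine_tol: float = 1e-10):
    """Global minimum position (Å) and positive depth (kJ/mol).

    Closed forms where the family convention fixes them, otherwise a
    dense bracketing scan refined by bounded scalar minimization.

    Raises :class:`NoMinimumError` for purely repulsive parameter sets.
    """
    p = model.params
    if model.family == "LJ12-6":
        return 2 ** (1 / 6) * p["sigma"], p["epsilon"]
    if model.family in ("LJ8-6", "MRS", "MBH", "WBH", "GBH"):
        return p["sigma"], p["epsilon"]
    scale = _length_scale(model)
    grid = np.linspace(0.05 * scale, 10.0 * scale, 4000)
    e = evaluate_energy(model, grid)
    # the physical well is the outermost interior local minimum; this
    # skips the spurious -inf core branch of BHA-type forms
    interior = (e[1:-1] < e[:-2]) & (e[1:-1] <= e[2:]) & (e[1:-1] < 0)
    candidates = np.where(interior)[0] + 1
    if candidates.size == 0:
        raise NoMinimumError(f"{model.family}: no bound minimum found")
    i = int(candidates[-1])
    res = minimize_scalar(
        lambda x: evaluate_energy(model, float(x)),
        bounds=(grid[i - 1], grid[i + 1]),
        method="bounded",
        options={"xatol": refine_tol},
    )
    return float(res.x), float(-res.fun)


# --------------------------------------------------------------------------
# BHA <-> MBH interconversion (the two forms are algebraically identical)


def mbh_to_bha(model: PotentialModel) -> PotentialModel:
    """Convert an MBH (ε, σ, γ) model to the equivalent BHA (A, C6, b)."""
    if model.family != "MBH":
        raise PotentialError("mbh_to_bha expects an MBH model")
    e, s, g = (model.params[k] for k in ("epsilon", "sigma", "gamma"))
    pref = e / (1.0 - 6.0 / g)
    return PotentialModel(
        "BHA",
        {"A": pref * (6.0 / g) * math.exp(g), "b": g / s, "C6": pref * s**6},
    )


def bha_to_mbh(model: PotentialModel) -> PotentialModel:
    """Convert a BHA model back to MBH well form (requires a bound well)."""
    if model.family != "BHA":
        raise PotentialError("bha_to_mbh expects a BHA model")
    A, b, C6 = (model.params[k] for k in ("A", "b", "C6"))
    if C6 <= 0:
        raise NoMinimumError("BHA with C6 = 0 is purely repulsive")
    # sigma solves A e^{-b s} = 6 C6 / (b s^7), the stationarity condition
    # at the minimum; bracket around the numerically located well (the
    # equation has a second root at the short-range maximum)
    r0, _ = locate_well(model)
    f = lambda s: A * math.exp(-b * s) - 6.0 * C6 / (b * s**7)
    lo, hi = 0.9 * r0, 1.1 * r0
    while f(lo) <= 0 and lo > 0.2 * r0:
        lo *= 0.95
    while f(hi) >= 0 and hi < 5.0 * r0:
        hi *= 1.05
    s = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
    g = b * s
    if g <= 6:
        raise PotentialError("BHA well too shallow for exp-6 form (b sigma <= 6)")
    eps = C6 * (1.0 - 6.0 / g) / s**6
    return PotentialModel("MBH", {"epsilon": eps, "sigma": s, "gamma": g})


# --------------------------------------------------------------------------
# TT helper


def tt_well_consistent(
    c6: float, c8: float, c10: float, Re: float, De: float,
    b_guess: float = 7.0,
) -> PotentialModel:
    """Build a TT model whose dimensionless well is exactly (x=1, −1).

    Solves the two conditions U*(1) = −1 and dU*/dx(1) = 0 for (A*, b)
    at given dimensionless dispersion coefficients, so the dimensional
    well sits at (R_e, −D_e).  U*(1) = −1 gives A* = (D(1) − 1) e^{b} in
    closed form, with D(x) = Σ f_{2n}(bx) C*_{2n} x^{−2n}; stationarity
    then reduces to a scalar equation in b solved by bracketing.
    """
    coeffs = ((6, c6), (8, c8), (10, c10))
    if c6 + c8 + c10 <= 1.0:
        raise PotentialError(
            "TT well calibration needs sum of dimensionless dispersion "
            "coefficients > 1 (otherwise no attractive well at x = 1)"
        )

    def d_and_slope(b):
        d1 = sum(c * tt_damping(n2, b) for n2, c in coeffs if c)
        # dD/dx at x=1: b f'_{2n}(b) - 2n f_{2n}(b) per term,
        # with f'_{2n}(y) = e^{-y} y^{2n} / (2n)!
        dp = sum(
            c * (b * math.exp(-b) * b**n2 / math.factorial(n2) - n2 * tt_damping(n2, b))
            for n2, c in coeffs
            if c
        )
        return d1, dp

    def g(b):
        d1, dp = d_and_slope(b)
        return -b * (d1 - 1.0) - dp

    lo, hi = 1.0, 60.0
    if g(lo) * g(hi) > 0:
        raise PotentialError("TT well calibration failed: no bracketing b in [1, 60]")
    b = brentq(g, lo, hi, xtol=1e-13)
    d1, _ = d_and_slope(b)
    a = (d1 - 1.0) * math.exp(b)
    return PotentialModel(
        "TT", {"A": a, "b": b, "C6": c6, "C8": c8, "C10": c10}, {"Re": Re, "De": De}
    )


# --------------------------------------------------------------------------
# YAML I/O


def model_to_yaml(model: PotentialModel) -> str:
    doc = {"family": model.family, "params": {k: float(v) for k, v in model.params.items()}}
    if model.constants:
        doc["constants"] = {k: float(v) for k, v in model.constants.items()}
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> PotentialModel:
    doc = yaml.safe_load(text)
    return PotentialModel(
        doc["family"], doc["params"], doc.get("constants", {}) or {}
    )


def read_model(path) -> PotentialModel:
    with open(path) as fh:
        return model_from_yaml(fh.read())


def write_model(model: PotentialModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(model_to_yaml(model))
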