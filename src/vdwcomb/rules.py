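"""Combination rules mapping homodimer parameters to heterodimer ones.

Twelve relations are implemented, referred to throughout by their
conventional equation identifiers 10–21:

==  =====================================================================
10  geometric mean  √(x₁x₂)
11  arithmetic mean  (x₁+x₂)/2
12  harmonic mean  2x₁x₂/(x₁+x₂)  (Hogervorst's ε rule)
13  Hogervorst σ rule for exp-6 potentials: geometric combination of the
    dispersion coefficients C₆ᵢ = εᵢγᵢσᵢ⁶/(γᵢ−6), solved for σ₁₂ using
    the already-combined ε₁₂ and γ₁₂:
    σ₁₂⁶ = √(C₆₁C₆₂)·(γ₁₂−6)/(ε₁₂γ₁₂)
14  σ/γ rule for the Morse potential: x₁x₂(x₁+x₂)/(x₁²+x₂²)
15  Mason's exp-6 steepness rule: combines the inverse-length slopes
    γᵢ/σᵢ arithmetically on the arithmetic-mean radius:
    γ₁₂ = (σ₁+σ₂)/2 · (γ₁/σ₁+γ₂/σ₂)/2
16  Waldman–Hagler ε rule: ε₁₂ = √(ε₁ε₂)·2σ₁³σ₂³/(σ₁⁶+σ₂⁶)
17  Waldman–Hagler σ rule (sixth-power mean): ((x₁⁶+x₂⁶)/2)^{1/6}
18  cubic-mean rule (Halgren/Qi): (x₁³+x₂³)/(x₁²+x₂²)
19  harmonic mean of square roots, squared (Halgren's HHG rule):
    4x₁x₂/(√x₁+√x₂)²
20  volume (third-power) mean: ((x₁³+x₂³)/2)^{1/3}
21  inverse-volume mean, the sub-geometric counterpart of 20:
    ((x₁⁻³+x₂⁻³)/2)^{−1/3}
==  =====================================================================

Rules 10–12, 14 and 17–21 take a single parameter type and may be
applied to any parameter; 13 is admissible only for σ (and needs the
combined ε and γ), 15 only for γ (needs the homodimer σ), 16 only for ε
(needs the homodimer σ).  All rules are symmetric and idempotent, which
is exactly the homodimer self-consistency requirement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curves import DissociationCurve
from .potentials import FAMILY_PARAMS, PotentialError, PotentialModel, evaluate_energy

SINGLE_INPUT_RULES = (10, 11, 12, 14, 17, 18, 19, 20, 21)
MULTI_INPUT_RULES = (13, 15, 16)
ALL_RULES = tuple(sorted(SINGLE_INPUT_RULES + MULTI_INPUT_RULES))


class CombinationError(ValueError):
    """A rule hit a singular or inadmissible input."""


def _check_positive(eq_id, x1, x2):
    if x1 < 0 or x2 < 0 or not (math.isfinite(x1) and math.isfinite(x2)):
        raise CombinationError(f"rule {eq_id}: inputs must be finite and >= 0")


def apply_rule(eq_id: int, x1: float, x2: float, context: Mapping | None = None) -> float:
    """Combine two homodimer parameter values per the identified relation.

    ``context`` supplies the extra values the multi-input rules need:
    rule 13 needs ``epsilon1/2``, ``gamma1/2``, ``epsilon12``,
    ``gamma12`` (x1, x2 are the homodimer σ); rules 15 and 16 need
    ``sigma1`` and ``sigma2``.
    """
    _check_positive(eq_id, x1, x2)
    c = context or {}
    if eq_id == 10:
        return math.sqrt(x1 * x2)
    if eq_id == 11:
        return 0.5 * (x1 + x2)
    if eq_id == 12:
        if x1 == 0 and x2 == 0:
            raise CombinationError("rule 12 is singular when both inputs are zero")
        return 2.0 * x1 * x2 / (x1 + x2)
    if eq_id == 13:
        return _rule_13(x1, x2, c)
    if eq_id == 14:
        if x1 == 0 and x2 == 0:
            raise CombinationError("rule 14 is singular when both inputs are zero")
        return x1 * x2 * (x1 + x2) / (x1 * x1 + x2 * x2)
    if eq_id == 15:
        return _rule_15(x1, x2, c)
    if eq_id == 16:
        return _rule_16(x1, x2, c)
    if eq_id == 17:
        return (0.5 * (x1**6 + x2**6)) ** (1.0 / 6.0)
    if eq_id == 18:
        if x1 == 0 and x2 == 0:
            raise CombinationError("rule 18 is singular when both inputs are zero")
        return (x1**3 + x2**3) / (x1 * x1 + x2 * x2)
    if eq_id == 19:
        if x1 == 0 and x2 == 0:
            raise CombinationError("rule 19 is singular when both inputs are zero")
        return 4.0 * x1 * x2 / (math.sqrt(x1) + math.sqrt(x2)) ** 2
    if eq_id == 20:
        return (0.5 * (x1**3 + x2**3)) ** (1.0 / 3.0)
    if eq_id == 21:
        if x1 == 0 or x2 == 0:
            raise CombinationError("rule 21 is singular when an input is zero")
        return (0.5 * (x1**-3 + x2**-3)) ** (-1.0 / 3.0)
    raise CombinationError(f"unknown combination rule {eq_id}")


def _require(context, keys, eq_id):
    missing = [k for k in keys if k not in context]
    if missing:
        raise CombinationError(f"rule {eq_id} requires context {missing}")
    return [float(context[k]) for k in keys]


def _rule_13(s1, s2, c):
    e1, e2, g1, g2, e12, g12 = _require(
        c, ("epsilon1", "epsilon2", "gamma1", "gamma2", "epsilon12", "gamma12"), 13
    )
    if e12 == 0 or g12 == 0:
        raise CombinationError("rule 13 is singular when combined epsilon or gamma is zero")
    if g1 <= 6 or g2 <= 6 or g12 <= 6:
        raise CombinationError("rule 13 needs gamma > 6 (exp-6 dispersion coefficient)")
    c6_1 = e1 * g1 * s1**6 / (g1 - 6.0)
    c6_2 = e2 * g2 * s2**6 / (g2 - 6.0)
    s6 = math.sqrt(c6_1 * c6_2) * (g12 - 6.0) / (e12 * g12)
    if s6 <= 0:
        raise CombinationError("rule 13 produced a non-positive sigma^6")
    return s6 ** (1.0 / 6.0)


def _rule_15(g1, g2, c):
    s1, s2 = _require(c, ("sigma1", "sigma2"), 15)
    if s1 <= 0 or s2 <= 0:
        raise CombinationError("rule 15 needs positive homodimer sigmas")
    return 0.5 * (s1 + s2) * 0.5 * (g1 / s1 + g2 / s2)


def _rule_16(e1, e2, c):
    s1, s2 = _require(c, ("sigma1", "sigma2"), 16)
    if s1 == 0 and s2 == 0:
        raise CombinationError("rule 16 is singular when both sigmas are zero")
    return math.sqrt(e1 * e2) * 2.0 * s1**3 * s2**3 / (s1**6 + s2**6)


# --------------------------------------------------------------------------
# rule sets


@dataclass(frozen=True)
class RuleSet:
    """Per-parameter assignment of combination-equation identifiers."""

    family: str
    assignment: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "assignment", dict(self.assignment))
        names = FAMILY_PARAMS[self.family]
        if set(self.assignment) != set(names):
            raise CombinationError(
                f"ruleset must assign exactly the parameters {names}"
            )
        for p, eq in self.assignment.items():
            if eq not in ALL_RULES:
                raise CombinationError(f"unknown rule {eq} for parameter {p}")
            if eq == 13 and p != "sigma":
                raise CombinationError("rule 13 is admissible only for sigma")
            if eq == 15 and p != "gamma":
                raise CombinationError("rule 15 is admissible only for gamma")
            if eq == 16 and p != "epsilon":
                raise CombinationError("rule 16 is admissible only for epsilon")

    @property
    def eq_tuple(self) -> tuple[int, ...]:
        return tuple(self.assignment[p] for p in FAMILY_PARAMS[self.family])

    def notation(self) -> str:
        """Space-separated equation ids in canonical parameter order."""
        return " ".join(str(e) for e in self.eq_tuple)

    @classmethod
    def from_notation(cls, family: str, text: str) -> "RuleSet":
        ids = [int(t) for t in text.split()]
        names = FAMILY_PARAMS[family]
        if len(ids) != len(names):
            raise CombinationError(
                f"{family} needs {len(names)} rule ids, got {len(ids)}"
            )
        return cls(family, dict(zip(names, ids)))


def combine_params(
    ruleset: RuleSet, m1: PotentialModel, m2: PotentialModel,
    constants: Mapping[str, float] | None = None,
) -> PotentialModel:
    """Heterodimer model from two homodimer models under a rule set.

    Dependency order is resolved automatically: all parameters except a
    rule-13 σ are combined first (rules 15/16 need only homodimer
    values), then σ via rule 13 from the combined ε and γ.  For the TT
    family the heterodimer constants (Re, De) must be supplied.
    """
    if m1.family != m2.family or m1.family != ruleset.family:
        raise CombinationError("family mismatch between rule set and models")
    names = FAMILY_PARAMS[ruleset.family]
    p1, p2 = m1.params, m2.params
    base_ctx = {}
    if "sigma" in names:
        base_ctx["sigma1"], base_ctx["sigma2"] = p1["sigma"], p2["sigma"]
    if "gamma" in names:
        base_ctx["gamma1"], base_ctx["gamma2"] = p1["gamma"], p2["gamma"]
    if "epsilon" in names:
        base_ctx["epsilon1"], base_ctx["epsilon2"] = p1["epsilon"], p2["epsilon"]

    combined: dict[str, float] = {}
    deferred = [n for n in names if ruleset.assignment[n] == 13]
    for name in names:
        if name in deferred:
            continue
        combined[name] = apply_rule(
            ruleset.assignment[name], p1[name], p2[name], base_ctx
        )
    for name in deferred:
        ctx = dict(base_ctx)
        if "epsilon" not in combined or "gamma" not in combined:
            raise CombinationError("rule 13 needs combined epsilon and gamma")
        ctx["epsilon12"] = combined["epsilon"]
        ctx["gamma12"] = combined["gamma"]
        combined[name] = apply_rule(13, p1[name], p2[name], ctx)

    consts = dict(constants) if constants else {}
    if ruleset.family == "TT" and not consts:
        raise CombinationError(
            "TT combination needs the heterodimer constants Re and De"
        )
    try:
        return PotentialModel(ruleset.family, combined, consts)
    except PotentialError as exc:
        raise CombinationError(f"combined parameters invalid: {exc}") from exc


# --------------------------------------------------------------------------
# enumeration and ranking


def default_admissibility(family: str) -> dict[str, list[int]]:
    """Admissible equation ids per parameter.

    Every single-input rule is admissible for every parameter; rule 13
    is added for σ when the family carries ε and γ, 15 for γ when it
    carries σ, 16 for ε when it carries σ.
    """
    names = FAMILY_PARAMS[family]
    adm = {n: list(SINGLE_INPUT_RULES) for n in names}
    if "sigma" in names:
        if "epsilon" in names and "gamma" in names:
            adm["sigma"] = sorted(adm["sigma"] + [13])
        if "epsilon" in names:
            adm["epsilon"] = sorted(adm["epsilon"] + [16])
        if "gamma" in names:
            adm["gamma"] = sorted(adm["gamma"] + [15])
    return adm


def enumerate_rulesets(
    family: str, admissibility: Mapping[str, Sequence[int]] | None = None
) -> list[RuleSet]:
    """All rule sets from the Cartesian product of admissible rules,
    in deterministic order sorted by equation-id tuple."""
    adm = dict(admissibility) if admissibility is not None else default_admissibility(family)
    names = FAMILY_PARAMS[family]
    for n in names:
        if n not in adm or not adm[n]:
            raise CombinationError(f"no admissible rules for parameter {n}")
    pools = [sorted(set(int(e) for e in adm[n])) for n in names]
    return [
        RuleSet(family, dict(zip(names, combo)))
        for combo in itertools.product(*pools)
    ]


@dataclass
class RuleScore:
    """Windowed RMSE of one rule set against heterodimer reference curves."""

    ruleset: RuleSet
    per_pair_rmse: dict[tuple[str, str], float]
    mean_rmse: float


def rank_rulesets(
    homodimer_fits: Mapping[str, PotentialModel],
    hetero_curves: Sequence[DissociationCurve],
    window=None,
    admissibility: Mapping[str, Sequence[int]] | None = None,
    constants_table: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
) -> list[RuleScore]:
    """Exhaustively score rule sets against heterodimer reference curves.

    Each rule set combines the homodimer fits per pair; the RMSE is
    computed over the points of the reference curve retained by the
    energy ``window`` (default 20 kJ/mol repulsive cut, 10 % of the
    pair's well depth tail cut), then averaged (unweighted) over pairs.
    Rule sets whose combination is singular on any pair score +inf and
    sort last.  Ties are broken by the equation-id tuple.
    """
    from .fitting import EnergyWindow, select_window

    if not hetero_curves:
        raise CombinationError("no heterodimer curves supplied")
    if window is None:
        window = EnergyWindow()
    families = {m.family for m in homodimer_fits.values()}
    if len(families) != 1:
        raise CombinationError("homodimer fits must share one family")
    family = families.pop()

    windowed = []
    for curve in hetero_curves:
        a, b = curve.pair
        for el in (a, b):
            if el not in homodimer_fits:
                raise CombinationError(f"no homodimer fit for element {el!r}")
        sub = select_window(curve, window)
        consts = None
        if family == "TT":
            if constants_table is None or tuple(sorted((a, b))) not in {
                tuple(sorted(k)) for k in constants_table
            }:
                raise CombinationError(
                    f"TT ranking needs per-pair constants for {a}-{b}"
                )
            key = next(
                k for k in constants_table if tuple(sorted(k)) == tuple(sorted((a, b)))
            )
            consts = constants_table[key]
        windowed.append((curve.pair, homodimer_fits[a], homodimer_fits[b], sub, consts))

    scores = []
    for ruleset in enumerate_rulesets(family, admissibility):
        per_pair = {}
        for pair, ma, mb, sub, consts in windowed:
            try:
                model = combine_params(ruleset, ma, mb, consts)
                pred = evaluate_energy(model, sub.r)
                rmse = float(np.sqrt(np.mean((pred - sub.energy) ** 2)))
                if not math.isfinite(rmse):
                    rmse = math.inf
            except (CombinationError, PotentialError):
                rmse = math.inf
            per_pair[pair] = rmse
        mean = float(np.mean(list(per_pair.values())))
        if not math.isfinite(mean):
            mean = math.inf
        scores.append(RuleScore(ruleset, per_pair, mean))
    scores.sort(key=lambda s: (s.mean_rmse, s.ruleset.eq_tuple))
    return scores
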