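"""End-to-end study drivers and the synthetic validation world.

Two experiment shapes are orchestrated here:

* the *fit study*: fit every requested potential family to every curve
  of a set and report the mean windowed RMSE per (family, source tag) —
  the shape of a direct-analytical-fit comparison table;
* the *rule study*: fit homodimer curves, exhaustively rank combination
  rule sets against the heterodimer curves, and report the best rule
  set per family in the ``10 20 14 10`` space-separated notation.

The synthetic world emulates a five-element noble-gas-like series with
well depths from ~0.09 to ~2.4 kJ/mol and well positions from ~3.0 to
~4.4 Å, scanned in 0.1 Å steps up to 30 Å; heterodimer ground truths
are constructed from the homodimer truths by a planted combination rule
set, so rule-recovery experiments have a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import DissociationCurve, generate_synthetic_curve, read_curve
from .fitting import EnergyWindow, FitResult, fit_potential
from .potentials import FAMILIES, PotentialModel
from .rules import RuleScore, RuleSet, combine_params, rank_rulesets


class StudyError(ValueError):
    """Study configuration problems."""


@dataclass
class StudyConfig:
    curve_directory: str | Path
    families: Sequence[str] = FAMILIES
    window: EnergyWindow = field(default_factory=EnergyWindow)
    admissibility: Mapping[str, Sequence[int]] | None = None
    seed: int = 0
    output_directory: str | Path | None = None

    def load_curves(self) -> list[DissociationCurve]:
        directory = Path(self.curve_directory)
        paths = sorted(directory.glob("*.tsv")) + sorted(directory.glob("*.csv"))
        if not paths:
            raise StudyError(f"no curve files in {directory}")
        errors, curves = [], []
        for p in paths:
            try:
                curves.append(read_curve(p))
            except Exception as exc:  # collect a per-file report
                errors.append(f"{p}: {exc}")
        if errors:
            raise StudyError("curve validation failed:\n" + "\n".join(errors))
        return curves


# --------------------------------------------------------------------------
# fit study


def fit_study(
    curves: Sequence[DissociationCurve],
    families: Sequence[str] = FAMILIES,
    window: EnergyWindow | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit each family to each curve.

    Returns ``(summary, detail)``: the summary has one row per source
    tag and one column per family holding the mean windowed RMSE
    (kJ/mol); the detail table has one row per (curve, family) with the
    fitted RMSE, point count and parameters.
    """
    if not curves:
        raise StudyError("no curves supplied")
    if window is None:
        window = EnergyWindow()
    records = []
    for curve in curves:
        for family in families:
            fr: FitResult = fit_potential(family, curve, window=window, seed=seed)
            rec = {
                "pair": f"{curve.element_a}-{curve.element_b}",
                "source": curve.source_tag,
                "family": family,
                "rmse": fr.rmse,
                "n_points": fr.n_points,
                "converged": fr.converged,
            }
            rec.update({f"p_{k}": v for k, v in fr.model.params.items()})
            records.append(rec)
    detail = pd.DataFrame.from_records(records)
    summary = (
        detail.pivot_table(index="source", columns="family", values="rmse", aggfunc="mean")
        .reindex(columns=[f for f in families])
    )
    summary.columns.name = None
    return summary, detail


# --------------------------------------------------------------------------
# rule study


def split_curves(curves: Sequence[DissociationCurve]):
    homo = [c for c in curves if c.element_a == c.element_b]
    hetero = [c for c in curves if c.element_a != c.element_b]
    return homo, hetero


def rule_study(
    curves: Sequence[DissociationCurve],
    families: Sequence[str] = ("LJ12-6",),
    window: EnergyWindow | None = None,
    admissibility=None,
    seed: int = 0,
    constants_table=None,
) -> tuple[pd.DataFrame, dict[str, list[RuleScore]]]:
    """Fit homodimers, scan combination rules on heterodimers.

    Returns a per-family summary (best ruleset notation + mean RMSE and
    the homodimer fit RMSE) and the full rankings.
    """
    if window is None:
        window = EnergyWindow()
    homo, hetero = split_curves(curves)
    if not homo or not hetero:
        raise StudyError("need both homodimer and heterodimer curves")
    hetero_elements = {e for c in hetero for e in c.pair}
    homo_elements = {c.element_a for c in homo}
    missing = hetero_elements - homo_elements
    if missing:
        raise StudyError(f"heterodimer elements without homodimer curves: {sorted(missing)}")

    rows, rankings = [], {}
    for family in families:
        fits, fit_rmses = {}, []
        for c in homo:
            fr = fit_potential(family, c, window=window, seed=seed)
            fits[c.element_a] = fr.model
            fit_rmses.append(fr.rmse)
        scores = rank_rulesets(
            fits, hetero, window=window, admissibility=admissibility,
            constants_table=constants_table,
        )
        rankings[family] = scores
        best = scores[0]
        rows.append(
            {
                "family": family,
                "best_rule": best.ruleset.notation(),
                "mean_rmse_comb": best.mean_rmse,
                "mean_rmse_fit_homo": float(np.mean(fit_rmses)),
                "n_rulesets": len(scores),
            }
        )
    return pd.DataFrame(rows).set_index("family"), rankings


def ranking_table(scores: Sequence[RuleScore]) -> pd.DataFrame:
    """Full ranking as a table: rank, notation, per-pair RMSE, mean."""
    rows = []
    for rank, s in enumerate(scores, start=1):
        row = {"rank": rank, "rule": s.ruleset.notation()}
        row.update({f"{a}-{b}": v for (a, b), v in s.per_pair_rmse.items()})
        row["mean_rmse"] = s.mean_rmse
        rows.append(row)
    return pd.DataFrame(rows)


def run_fit_study(config: StudyConfig):
    """Directory-driven fit study; writes TSV reports when configured."""
    curves = config.load_curves()
    summary, detail = fit_study(
        curves, families=config.families, window=config.window, seed=config.seed
    )
    if config.output_directory:
        out = Path(config.output_directory)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "fit_summary.tsv", sep="\t", float_format="%.6f")
        detail.to_csv(out / "fit_detail.tsv", sep="\t", index=False, float_format="%.6g")
    return summary, detail


def run_rule_study(config: StudyConfig, families=None, constants_table=None):
    """Directory-driven rule study; writes TSV reports when configured."""
    curves = config.load_curves()
    summary, rankings = rule_study(
        curves,
        families=families or config.families,
        window=config.window,
        admissibility=config.admissibility,
        seed=config.seed,
        constants_table=constants_table,
    )
    if config.output_directory:
        out = Path(config.output_directory)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "rule_summary.tsv", sep="\t", float_format="%.6f")
        for family, scores in rankings.items():
            ranking_table(scores).to_csv(
                out / f"ranking_{family}.tsv", sep="\t", index=False, float_format="%.6g"
            )
    return summary, rankings


# --------------------------------------------------------------------------
# synthetic world

#: noble-gas-like homodimer ground truths: well position (Å), depth (kJ/mol)
DEFAULT_WELLS = {
    "A": (2.97, 0.091),
    "B": (3.09, 0.36),
    "C": (3.76, 1.19),
    "D": (4.01, 1.66),
    "E": (4.36, 2.35),
}


def default_truth(
    family: str, r_well: float, depth: float, g_fac: float = 1.0, d_fac: float = 1.0
) -> PotentialModel:
    """A plausible ground-truth model of the family with the given well.

    ``g_fac``/``d_fac`` scale the shape parameters (steepness and
    dispersion shape) around their defaults, so a multi-element world
    carries element-distinct shapes — without that, combination rules
    for the shape parameters would be unidentifiable (every mean is
    idempotent).
    """
    if family == "LJ12-6":
        return PotentialModel(family, {"sigma": r_well / 2 ** (1 / 6), "epsilon": depth})
    if family == "LJ8-6":
        return PotentialModel(family, {"sigma": r_well, "epsilon": depth})
    if family == "MRS":
        return PotentialModel(
            family, {"sigma": r_well, "epsilon": depth, "gamma": 6.5 * g_fac}
        )
    if family == "WBH":
        return PotentialModel(
            family, {"sigma": r_well, "epsilon": depth, "gamma": 12.0 * g_fac}
        )
    if family == "MBH":
        return PotentialModel(
            family, {"sigma": r_well, "epsilon": depth, "gamma": 13.0 * g_fac}
        )
    if family == "GBH":
        return PotentialModel(
            family,
            {"sigma": r_well, "epsilon": depth, "gamma": 12.5 * g_fac,
             "delta": 6.0 * d_fac},
        )
    if family == "LJ14-7":
        return PotentialModel(
            family,
            {"sigma": r_well, "epsilon": depth, "gamma": 0.12 * g_fac,
             "delta": 0.07 * d_fac},
        )
    if family == "BHA":
        from .potentials import mbh_to_bha

        return mbh_to_bha(
            PotentialModel(
                "MBH", {"sigma": r_well, "epsilon": depth, "gamma": 13.0 * g_fac}
            )
        )
    if family == "TT":
        from .potentials import tt_well_consistent

        return tt_well_consistent(
            1.2 * g_fac, 0.4 * d_fac, 0.2, Re=r_well, De=depth
        )
    raise StudyError(f"unknown family {family!r}")


def tt_constants_table(
    wells: Mapping[str, tuple[float, float]] | None = None,
) -> dict[tuple[str, str], dict[str, float]]:
    """Per-pair fixed TT constants: arithmetic-mean R_e, geometric-mean
    D_e of the homodimer wells (the mixed well must be known beforehand
    for the TT family)."""
    import math

    wells = dict(wells or DEFAULT_WELLS)
    els = sorted(wells)
    table = {}
    for i, a in enumerate(els):
        for b in els[i:]:
            ra, da = wells[a]
            rb, db = wells[b]
            table[(a, b)] = {"Re": 0.5 * (ra + rb), "De": math.sqrt(da * db)}
    return table


def synthetic_world(
    family: str = "GBH",
    wells: Mapping[str, tuple[float, float]] | None = None,
    heterodimer_rule: RuleSet | str | None = None,
    noise_sd: float = 0.0,
    seed: int = 1,
    r_start: float = 1.8,
    r_stop: float = 30.0,
    step: float = 0.1,
    source_tag: str = "synthetic-world",
) -> tuple[list[DissociationCurve], dict[str, PotentialModel], RuleSet]:
    """Build a full synthetic curve set for a five-element world.

    Homodimer curves are generated from per-element ground truths;
    heterodimer curves from the models obtained by combining the truths
    with ``heterodimer_rule`` (default: geometric ε, volume-mean σ,
    arithmetic shape parameters).  Returns (curves, truths, rule).
    """
    wells = dict(wells or DEFAULT_WELLS)
    if isinstance(heterodimer_rule, str):
        rule = RuleSet.from_notation(family, heterodimer_rule)
    elif heterodimer_rule is None:
        from .potentials import FAMILY_PARAMS

        default = {"epsilon": 10, "sigma": 20}
        rule = RuleSet(
            family,
            {p: default.get(p, 11) for p in FAMILY_PARAMS[family]},
        )
    else:
        rule = heterodimer_rule

    ordered = sorted(wells)
    mid = (len(ordered) - 1) / 2.0
    truths = {}
    for i, el in enumerate(ordered):
        r_well, depth = wells[el]
        truths[el] = default_truth(
            family, r_well, depth,
            g_fac=1.0 + 0.06 * (i - mid),
            d_fac=1.0 + 0.02 * (i - mid),
        )
    consts_tab = tt_constants_table(wells) if family == "TT" else {}
    curves = []
    elements = sorted(wells)
    rng_seed = seed
    for i, a in enumerate(elements):
        for b_el in elements[i:]:
            if a == b_el:
                model = truths[a]
            else:
                model = combine_params(
                    rule, truths[a], truths[b_el],
                    constants=consts_tab.get((a, b_el)),
                )
            curve = generate_synthetic_curve(
                model, r_start, r_stop, step, noise_sd=noise_sd, seed=rng_seed,
                element_a=a, element_b=b_el,
            )
            curve.source_tag = source_tag
            curves.append(curve)
            rng_seed += 1
    return curves, truths, rule
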