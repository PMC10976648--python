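"""Combination-rule algebra, enumeration and ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdwcomb import (
    CombinationError,
    PotentialModel,
    RuleSet,
    apply_rule,
    combine_params,
    default_admissibility,
    enumerate_rulesets,
    rank_rulesets,
)
from vdwcomb.rules import ALL_RULES, SINGLE_INPUT_RULES
from vdwcomb.workbench import synthetic_world

positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)


def _context(x1=None, x2=None):
    """A generically valid context for the multi-input rules."""
    return {
        "sigma1": 3.2, "sigma2": 4.1,
        "gamma1": 11.0, "gamma2": 14.0,
        "epsilon1": 0.4, "epsilon2": 1.9,
        "epsilon12": 0.8, "gamma12": 12.5,
    }


# --------------------------------------------------------------------------
# hand values


def test_hand_values():
    assert apply_rule(10, 4.0, 9.0) == pytest.approx(6.0, rel=1e-14)
    assert apply_rule(11, 1.0, 3.0) == pytest.approx(2.0, rel=1e-14)
    assert apply_rule(12, 1.0, 3.0) == pytest.approx(1.5, rel=1e-14)
    assert apply_rule(20, 1.0, 1.0) == pytest.approx(1.0, rel=1e-14)
    assert apply_rule(20, 1.0, 2.0) == pytest.approx(1.6509636244473134, rel=1e-12)
    assert apply_rule(18, 1.0, 2.0) == pytest.approx(9.0 / 5.0, rel=1e-14)
    assert apply_rule(19, 1.0, 4.0) == pytest.approx(16.0 / 9.0, rel=1e-14)
    assert apply_rule(14, 1.0, 2.0) == pytest.approx(6.0 / 5.0, rel=1e-14)


# --------------------------------------------------------------------------
# algebraic properties


@settings(deadline=None, max_examples=300)
@given(x1=positive, x2=positive, eq=st.sampled_from(ALL_RULES))
def test_symmetry(x1, x2, eq):
    ctx = _context()
    assert apply_rule(eq, x1, x2, ctx) == pytest.approx(
        apply_rule(eq, x2, x1, {**ctx,
                                "sigma1": ctx["sigma2"], "sigma2": ctx["sigma1"],
                                "gamma1": ctx["gamma2"], "gamma2": ctx["gamma1"],
                                "epsilon1": ctx["epsilon2"], "epsilon2": ctx["epsilon1"]}),
        rel=1e-10,
    )


@settings(deadline=None, max_examples=300)
@given(x=positive, eq=st.sampled_from(SINGLE_INPUT_RULES))
def test_idempotence_single_input(x, eq):
    """Homodimer self-consistency: every mean returns x on (x, x)."""
    assert apply_rule(eq, x, x) == pytest.approx(x, rel=1e-12)


@settings(deadline=None, max_examples=200)
@given(s=positive, g=st.floats(6.1, 40.0), e=positive)
def test_idempotence_multi_input(s, g, e):
    ctx = {
        "sigma1": s, "sigma2": s, "gamma1": g, "gamma2": g,
        "epsilon1": e, "epsilon2": e, "epsilon12": e, "gamma12": g,
    }
    assert apply_rule(13, s, s, ctx) == pytest.approx(s, rel=1e-10)
    assert apply_rule(15, g, g, ctx) == pytest.approx(g, rel=1e-12)
    assert apply_rule(16, e, e, ctx) == pytest.approx(e, rel=1e-12)


def test_mean_ordering_bulk(rng):
    """21 ≤ 12 ≤ 10 ≤ 11 ≤ 20 ≤ 17 over 10^4 random positive pairs,
    and 21 strictly below the geometric mean for unequal inputs."""
    x = rng.uniform(1e-3, 1e3, size=(10_000, 2))
    chain = [21, 12, 10, 11, 20, 17]
    vals = {eq: np.array([apply_rule(eq, a, b) for a, b in x]) for eq in chain}
    for lo, hi in zip(chain, chain[1:]):
        assert np.all(vals[lo] <= vals[hi] * (1 + 1e-12))
    unequal = np.abs(x[:, 0] - x[:, 1]) > 1e-9
    assert np.all(vals[21][unequal] < vals[10][unequal])


def test_singularities():
    with pytest.raises(CombinationError):
        apply_rule(12, 0.0, 0.0)
    with pytest.raises(CombinationError):
        apply_rule(13, 3.0, 4.0, {**_context(), "epsilon12": 0.0})
    with pytest.raises(CombinationError):
        apply_rule(13, 3.0, 4.0)  # missing context
    with pytest.raises(CombinationError):
        apply_rule(16, 1.0, 2.0)  # missing context
    with pytest.raises(CombinationError):
        apply_rule(99, 1.0, 2.0)


# --------------------------------------------------------------------------
# combining whole parameter sets


def test_combine_homodimer_identity(reference_models):
    """Any admissible ruleset maps (m, m) to m."""
    for family, model in reference_models.items():
        adm = default_admissibility(family)
        ruleset = RuleSet(family, {p: rules[0] for p, rules in adm.items()})
        consts = model.constants if family == "TT" else None
        out = combine_params(ruleset, model, model, consts)
        for k, v in model.params.items():
            assert out.params[k] == pytest.approx(v, rel=1e-12)


def test_combine_lj_geometric_example():
    rs = RuleSet("LJ12-6", {"epsilon": 10, "sigma": 10})
    m1 = PotentialModel("LJ12-6", {"sigma": 3.0, "epsilon": 1.0})
    m2 = PotentialModel("LJ12-6", {"sigma": 4.0, "epsilon": 4.0})
    out = combine_params(rs, m1, m2)
    assert out.params["sigma"] == pytest.approx(math.sqrt(12.0), rel=1e-14)
    assert out.params["epsilon"] == pytest.approx(2.0, rel=1e-14)


def test_waldman_hagler_identity_on_equal_atoms():
    rs = RuleSet("LJ12-6", {"epsilon": 16, "sigma": 17})
    m = PotentialModel("LJ12-6", {"sigma": 3.4, "epsilon": 1.2})
    out = combine_params(rs, m, m)
    assert out.params == pytest.approx(m.params, rel=1e-14)


def test_rule13_dependency_order():
    """Rule 13 consumes the already-combined epsilon and gamma."""
    rs = RuleSet("MBH", {"epsilon": 12, "sigma": 13, "gamma": 11})
    m1 = PotentialModel("MBH", {"epsilon": 0.4, "sigma": 3.1, "gamma": 12.0})
    m2 = PotentialModel("MBH", {"epsilon": 1.9, "sigma": 4.0, "gamma": 14.0})
    out = combine_params(rs, m1, m2)
    e12 = apply_rule(12, 0.4, 1.9)
    g12 = apply_rule(11, 12.0, 14.0)
    c6 = lambda e, g, s: e * g * s**6 / (g - 6)
    s6 = math.sqrt(c6(0.4, 12.0, 3.1) * c6(1.9, 14.0, 4.0)) * (g12 - 6) / (e12 * g12)
    assert out.params["sigma"] == pytest.approx(s6 ** (1 / 6), rel=1e-12)


def test_rule_restrictions():
    with pytest.raises(CombinationError):
        RuleSet("MBH", {"epsilon": 13, "sigma": 10, "gamma": 11})
    with pytest.raises(CombinationError):
        RuleSet("MBH", {"epsilon": 10, "sigma": 15, "gamma": 11})
    with pytest.raises(CombinationError):
        RuleSet("LJ12-6", {"epsilon": 10})


def test_notation_round_trip():
    rs = RuleSet.from_notation("GBH", "10 20 14 10")
    assert rs.notation() == "10 20 14 10"
    assert rs.assignment == {"epsilon": 10, "sigma": 20, "gamma": 14, "delta": 10}


# --------------------------------------------------------------------------
# enumeration


def test_enumeration_counts():
    adm = {"epsilon": list(range(10, 18)), "sigma": [10, 11, 12, 14, 17, 18, 19, 20]}
    adm["epsilon"] = [10, 11, 12, 14, 17, 18, 19, 20]
    sets = enumerate_rulesets("LJ12-6", adm)
    assert len(sets) == 64
    # deterministic sorted order by equation-id tuple
    tuples = [s.eq_tuple for s in sets]
    assert tuples == sorted(tuples)


def test_default_enumeration_products():
    for family, expected in [("LJ12-6", 10 * 9), ("MBH", 10 * 10 * 10),
                             ("LJ14-7", 10 * 10 * 10 * 9), ("BHA", 9**3)]:
        adm = default_admissibility(family)
        n = 1
        for rules in adm.values():
            n *= len(rules)
        assert len(enumerate_rulesets(family)) == n == expected


def test_enumeration_empty_pool_errors():
    with pytest.raises(CombinationError):
        enumerate_rulesets("LJ12-6", {"epsilon": [], "sigma": [10]})


# --------------------------------------------------------------------------
# ranking


def _small_world(rule_notation="10 20"):
    curves, truths, rule = synthetic_world(
        family="LJ12-6",
        wells={"A": (3.0, 0.3), "B": (3.7, 1.1), "C": (4.3, 2.2)},
        heterodimer_rule=rule_notation,
        r_start=2.0,
    )
    hetero = [c for c in curves if c.element_a != c.element_b]
    return truths, hetero, rule


def test_planted_ruleset_ranks_first():
    truths, hetero, rule = _small_world("10 20")
    scores = rank_rulesets(truths, hetero)
    assert scores[0].ruleset.eq_tuple == rule.eq_tuple
    assert scores[0].mean_rmse < 1e-10
    assert scores[-1].mean_rmse >= scores[0].mean_rmse


def test_ranking_is_order_invariant_and_deterministic():
    truths, hetero, _ = _small_world()
    s1 = rank_rulesets(truths, hetero)
    s2 = rank_rulesets(truths, list(reversed(hetero)))
    assert [s.ruleset.eq_tuple for s in s1] == [s.ruleset.eq_tuple for s in s2]
    np.testing.assert_allclose(
        [s.mean_rmse for s in s1], [s.mean_rmse for s in s2], rtol=1e-12
    )


def test_ties_break_by_equation_tuple():
    truths, hetero, _ = _small_world()
    scores = rank_rulesets(truths, hetero)
    for a, b in zip(scores, scores[1:]):
        if a.mean_rmse == b.mean_rmse:
            assert a.ruleset.eq_tuple < b.ruleset.eq_tuple


def test_singular_rulesets_score_infinity():
    """A world containing a gamma <= 6 element makes rule 13 singular;
    those rule sets must sort last with +inf, not abort the scan."""
    m1 = PotentialModel("MRS", {"epsilon": 0.3, "sigma": 3.0, "gamma": 5.0})
    m2 = PotentialModel("MRS", {"epsilon": 1.1, "sigma": 3.7, "gamma": 6.6})
    from vdwcomb import generate_synthetic_curve

    hetero = [
        generate_synthetic_curve(
            combine_params(RuleSet.from_notation("MRS", "10 11 11"), m1, m2),
            2.0, element_a="A", element_b="B",
        )
    ]
    scores = rank_rulesets({"A": m1, "B": m2}, hetero)
    sigma13 = [s for s in scores if s.ruleset.assignment["sigma"] == 13]
    assert sigma13 and all(math.isinf(s.mean_rmse) for s in sigma13)
    assert all(math.isinf(s.mean_rmse) for s in scores[-len(sigma13):])


def test_rank_requires_curves_and_fits():
    truths, hetero, _ = _small_world()
    with pytest.raises(CombinationError):
        rank_rulesets(truths, [])
    with pytest.raises(CombinationError):
        rank_rulesets({"A": truths["A"]}, hetero)
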