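"""Transcription and convention tests for the nine potential families."""

import math

import numpy as np
import pytest

from vdwcomb import (
    NoMinimumError,
    PotentialError,
    PotentialModel,
    bha_to_mbh,
    evaluate_derivative,
    evaluate_energy,
    locate_well,
    mbh_to_bha,
)
from vdwcomb.potentials import (
    FAMILIES,
    model_from_yaml,
    model_to_yaml,
    tt_damping,
)

from conftest import REFERENCE_MODELS

GRID = np.array([2.8, 3.3, 3.76, 4.5, 6.0])


# --------------------------------------------------------------------------
# double-entry transcriptions: each formula typed a second time,
# independently and in a different algebraic arrangement


def _alt_lj12_6(p, r):
    return 4 * p["epsilon"] * ((p["sigma"] / r) ** 12 - (p["sigma"] / r) ** 6)


def _alt_lj8_6(p, r):
    u = p["sigma"] / r
    return p["epsilon"] * u**6 * (3 * u**2 - 4)


def _alt_lj14_7(p, r):
    x, g, d = r / p["sigma"], p["gamma"], p["delta"]
    return (
        p["epsilon"]
        * (1 + d) ** 7
        / (x + d) ** 7
        * ((1 + g) - 2 * (x**7 + g))
        / (x**7 + g)
    )


def _alt_mrs(p, r):
    q = p["gamma"] * (1 - r / p["sigma"])
    return p["epsilon"] * math.exp(q) * (math.exp(q) - 2)


def _alt_bha(p, r):
    return p["A"] / math.exp(p["b"] * r) - p["C6"] * r**-6


def _alt_mbh(p, r):
    g = p["gamma"]
    return (
        p["epsilon"]
        * g
        / (g - 6)
        * ((6 / g) * math.exp(g) * math.exp(-g * r / p["sigma"]) - (p["sigma"] / r) ** 6)
    )


def _alt_wbh(p, r):
    g, s = p["gamma"], p["sigma"]
    k = 3 / (g + 3)
    return 2 * p["epsilon"] / (1 - k) / (1 + (r / s) ** 6) * (
        k * math.exp(g * (1 - r / s)) - 1
    )


def _alt_gbh(p, r):
    g, d, s = p["gamma"], p["delta"], p["sigma"]
    return p["epsilon"] * g / (g - d) * (
        (d / g) * math.exp(g) * math.exp(-g * r / s) - (s / r) ** d
    )


def _alt_tt(p, r, c):
    x = r / c["Re"]
    y = p["b"] * x
    total = p["A"] * math.exp(-y)
    for n2, key in ((6, "C6"), (8, "C8"), (10, "C10")):
        # damping typed as the explicit subtracted exponential sum
        s = sum(y**k / math.factorial(k) for k in range(n2 + 1))
        f = 1.0 - math.exp(-y) * s
        total -= f * p[key] / x**n2
    return c["De"] * total


_ALT = {
    "LJ12-6": _alt_lj12_6,
    "LJ8-6": _alt_lj8_6,
    "LJ14-7": _alt_lj14_7,
    "MRS": _alt_mrs,
    "BHA": _alt_bha,
    "MBH": _alt_mbh,
    "WBH": _alt_wbh,
    "GBH": _alt_gbh,
}


@pytest.mark.parametrize("family", FAMILIES)
def test_double_entry_transcription(family):
    """Energies agree with an independently typed form on 5 grid points."""
    model = REFERENCE_MODELS[family]
    for r in GRID:
        got = evaluate_energy(model, float(r))
        if family == "TT":
            want = _alt_tt(model.params, float(r), model.constants)
        else:
            want = _ALT[family](model.params, float(r))
        assert got == pytest.approx(want, rel=1e-12, abs=1e-15)


# --------------------------------------------------------------------------
# well conventions


@pytest.mark.parametrize(
    "family,expected_rmin",
    [
        ("LJ12-6", 2 ** (1 / 6) * 3.35),
        ("LJ8-6", 3.76),
        ("MRS", 3.76),
        ("MBH", 3.76),
        ("WBH", 3.76),
        ("GBH", 3.76),
    ],
)
def test_minimum_conventions(family, expected_rmin):
    model = REFERENCE_MODELS[family]
    r_min, depth = locate_well(model)
    assert r_min == pytest.approx(expected_rmin, abs=1e-8)
    assert depth == pytest.approx(1.19, abs=1e-8)
    assert evaluate_energy(model, r_min) == pytest.approx(-depth, rel=1e-10)


def test_tt_well_depth_is_de():
    r_min, depth = locate_well(REFERENCE_MODELS["TT"])
    assert r_min == pytest.approx(3.76, abs=1e-6)
    assert depth == pytest.approx(1.19, abs=1e-8)


def test_locate_well_matches_grid_scan(gbh_truth):
    """Numeric refinement agrees with a dense independent grid scan."""
    model = PotentialModel(
        "LJ14-7", {"sigma": 3.5, "epsilon": 0.8, "gamma": 0.2, "delta": 0.1}
    )
    grid = np.arange(2.0, 8.0, 1e-4)
    e = evaluate_energy(model, grid)
    i = int(np.argmin(e))
    r_min, depth = locate_well(model)
    assert abs(r_min - grid[i]) < 1e-3
    assert depth == pytest.approx(-e[i], abs=1e-6)


def test_purely_repulsive_has_no_minimum():
    model = PotentialModel("BHA", {"A": 1e5, "b": 3.0, "C6": 0.0})
    with pytest.raises(NoMinimumError):
        locate_well(model)


# --------------------------------------------------------------------------
# structural identities


def test_bha_mbh_interconversion_identity():
    """exp-6 in well form and A e^{-br} - C6/r^6 are the same function."""
    mbh = REFERENCE_MODELS["MBH"]
    bha = mbh_to_bha(mbh)
    r = np.linspace(0.3, 25.0, 1500)
    diff = evaluate_energy(mbh, r) - evaluate_energy(bha, r)
    assert np.max(np.abs(diff)) < 1e-10 * max(1.0, np.max(np.abs(evaluate_energy(mbh, r))))
    back = bha_to_mbh(bha)
    for k, v in mbh.params.items():
        assert back.params[k] == pytest.approx(v, rel=1e-9)


def test_wbh_finite_at_origin_bha_diverges():
    wbh = REFERENCE_MODELS["WBH"]
    assert math.isfinite(evaluate_energy(wbh, 0.0))
    bha = REFERENCE_MODELS["BHA"]
    assert evaluate_energy(bha, 1e-3) < -1e15


def test_tt_reduces_to_pure_exponential_without_dispersion():
    model = PotentialModel(
        "TT", {"A": 50.0, "b": 8.0, "C6": 0.0, "C8": 0.0, "C10": 0.0},
        {"Re": 3.7, "De": 1.3},
    )
    for x in (0.5, 1.0, 2.1):
        assert evaluate_energy(model, x * 3.7) == pytest.approx(
            50.0 * 1.3 * math.exp(-8.0 * x), rel=1e-12
        )


def test_tt_damping_small_argument_accuracy():
    """The incomplete-gamma evaluation must not cancel at tiny y:
    f_{2n}(y) ~ y^{2n+1}/(2n+1)! to leading order."""
    for n2 in (6, 8, 10):
        for y in (1e-4, 1e-3, 1e-2):
            lead = y ** (n2 + 1) / math.factorial(n2 + 1)
            assert tt_damping(n2, y) == pytest.approx(lead, rel=1e-3)


def test_asymptotic_decay_all_families():
    for family in FAMILIES:
        model = REFERENCE_MODELS[family]
        r_min, depth = locate_well(model)
        assert abs(evaluate_energy(model, 30.0 * r_min)) < 1e-3 * depth


# --------------------------------------------------------------------------
# derivatives


@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("order", [1, 2, 3])
def test_derivatives_match_finite_differences(family, order):
    """Analytic (or scaled-step FD) derivatives agree with a plain
    central difference of the energy with step 1e-4 Å."""
    model = REFERENCE_MODELS[family]
    # the order-3 stencil divides by 2h^3; a 1e-4 step would be all
    # round-off there, so it uses a coarser step
    h = 1e-4 if order < 3 else 2e-3
    for r in (3.2, 3.76, 4.5, 6.0):
        got = evaluate_derivative(model, r, order)
        if order == 1:
            ref = (evaluate_energy(model, r + h) - evaluate_energy(model, r - h)) / (2 * h)
        elif order == 2:
            ref = (
                evaluate_energy(model, r + h)
                - 2 * evaluate_energy(model, r)
                + evaluate_energy(model, r - h)
            ) / h**2
        else:
            ref = (
                evaluate_energy(model, r + 2 * h)
                - 2 * evaluate_energy(model, r + h)
                + 2 * evaluate_energy(model, r - h)
                - evaluate_energy(model, r - 2 * h)
            ) / (2 * h**3)
        tol = 1e-6 if order == 1 else 1e-4
        assert got == pytest.approx(ref, rel=tol, abs=tol)


def test_first_derivative_vanishes_at_minimum():
    for family in FAMILIES:
        model = REFERENCE_MODELS[family]
        r_min, depth = locate_well(model)
        scale = depth / r_min
        assert abs(evaluate_derivative(model, r_min, 1)) < 1e-6 * scale + 1e-9


# --------------------------------------------------------------------------
# validation and I/O


def test_domain_and_parameter_errors():
    with pytest.raises(PotentialError):
        evaluate_energy(REFERENCE_MODELS["LJ12-6"], -1.0)
    with pytest.raises(PotentialError):
        evaluate_energy(REFERENCE_MODELS["MRS"], 0.0)
    with pytest.raises(PotentialError):
        PotentialModel("MBH", {"epsilon": 1.0, "sigma": 3.0, "gamma": 5.0})
    with pytest.raises(PotentialError):
        PotentialModel("GBH", {"epsilon": 1.0, "sigma": 3.0, "gamma": 5.0, "delta": 6.0})
    with pytest.raises(PotentialError):
        PotentialModel("nope", {})
    with pytest.raises(PotentialError):
        PotentialModel("TT", {"A": 1.0, "b": 5.0, "C6": 1.0, "C8": 0.0, "C10": 0.0})


@pytest.mark.parametrize("family", FAMILIES)
def test_yaml_round_trip(family):
    model = REFERENCE_MODELS[family]
    again = model_from_yaml(model_to_yaml(model))
    assert again.family == model.family
    assert again.params == pytest.approx(model.params)
    assert again.constants == pytest.approx(model.constants)
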