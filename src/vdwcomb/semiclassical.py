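"""Symbolic derivation of the Wigner-Kirkwood virial correction terms.

The coded correction integrands in :mod:`vdwcomb.virial` were frozen
from this derivation.  The machinery is kept in the package so the
frozen forms can be re-derived and cross-checked in the test suite:

1.  Solve the Bloch equation for the Kirkwood factor w(r, p, β) of the
    two-particle Slater sum, order by order in ħ:

        ∂w_k/∂β = (i/μ) p·(∇w_{k−1} − β ∇V w_{k−1})
                + (1/2μ)[∇²w_{k−2} − 2β∇V·∇w_{k−2}
                          + (β²(∇V)² − β∇²V) w_{k−2}]

    with w₀ = 1 and w_k(β=0) = 0.
2.  Average over momenta with the Maxwell weight (odd orders vanish).
3.  Specialize to a spherically symmetric V and evaluate on-axis.
4.  Integrate by parts until no derivative of V above the third
    remains (boundary terms vanish for potentials with a repulsive
    core and a decaying tail).

The quantum corrections are then

    B_qn = −2π N_A ħ^{2n} ∫ e^{−βV} A_n(R) dR,

with A_n the order-2n reduced integrand (the R² volume weight is part
of A_n).  An independent exact check: for the isotropic harmonic
oscillator the same machinery must reproduce the series of the exact
trace (2 sinh(βħω/2))⁻³, giving the coefficients −1/8, 17/1920,
−457/967680 at orders ħ², ħ⁴, ħ⁶.
"""

from __future__ import annotations

from functools import lru_cache

import sympy as sp
from sympy import Rational as Q

R, BETA, MU = sp.symbols("R beta mu", positive=True)
_x, _y, _z = sp.symbols("_wk_x _wk_y _wk_z", positive=True)
_p = sp.symbols("_wk_p1 _wk_p2 _wk_p3", real=True)
V = sp.Function("V")

#: exact harmonic-oscillator trace series coefficients at ħ^{2n}
HO_SERIES = {1: Q(-1, 8), 2: Q(17, 1920), 3: Q(-457, 967680)}


def _integrate_beta(expr):
    expr = sp.expand(expr)
    out = []
    for term in sp.Add.make_args(expr):
        pw = sp.degree(term.as_poly(BETA)) if term.has(BETA) else 0
        out.append((term / BETA**pw) * BETA ** (pw + 1) / (pw + 1))
    return sp.Add(*out)


def _gauss_average(expr):
    """Maxwell average over p: per component variance μ/β."""
    var = MU / BETA
    pol = sp.Poly(sp.expand(expr), *_p)
    out = sp.Integer(0)
    for monom, coeff in pol.terms():
        if any(m % 2 for m in monom):
            continue
        fac = sp.Integer(1)
        for m in monom:
            if m:
                fac *= var ** (m // 2) * sp.factorial2(m - 1)
        out += coeff * fac
    return sp.expand(out)


@lru_cache(maxsize=None)
def _kirkwood_terms(max_order: int):
    X = (_x, _y, _z)
    Vxyz = V(*X)
    gV = [sp.Derivative(Vxyz, c) for c in X]
    lV = sum(sp.Derivative(Vxyz, c, 2) for c in X)
    gV2 = sum(g * g for g in gV)
    w = {0: sp.Integer(1)}
    for k in range(1, max_order + 1):
        rhs = sp.Integer(0)
        wk1, wk2 = w.get(k - 1, 0), w.get(k - 2, 0)
        if wk1 != 0:
            rhs += sp.I / MU * sum(
                _p[i] * (sp.diff(wk1, X[i]) - BETA * gV[i] * wk1) for i in range(3)
            )
        if wk2 != 0:
            rhs += Q(1, 2) / MU * (
                sum(sp.diff(wk2, c, 2) for c in X)
                - 2 * BETA * sum(gV[i] * sp.diff(wk2, X[i]) for i in range(3))
                + (BETA**2 * gV2 - BETA * lV) * wk2
            )
        w[k] = _integrate_beta(rhs)
    return w


def raw_integrand(order: int):
    """On-axis momentum-averaged ħ^{2·order} term of the Slater sum,
    before integration by parts (derivatives of V up to order 2n appear).

    Returned as a sympy expression in R, beta, mu and Derivative(V(R), ...),
    WITHOUT the R² weight.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    w = _kirkwood_terms(2 * order)
    avg = _gauss_average(w[2 * order])
    assert sp.simplify(_gauss_average(w[2 * order - 1])) == 0
    sph = V(sp.sqrt(_x**2 + _y**2 + _z**2))
    e = avg.subs(V(_x, _y, _z), sph).doit()
    e = e.subs([(_y, 0), (_z, 0)]).doit()
    return sp.expand(e.subs(_x, R))


def reduced_integrand(order: int):
    """IBP-reduced integrand A_n (includes the R² weight): derivatives of
    V of order ≤ 3 only."""
    expr = sp.expand(raw_integrand(order) * R**2)
    while True:
        worst = None
        for d in expr.atoms(sp.Derivative):
            n = d.derivative_count
            if n > 3 and (worst is None or n > worst.derivative_count):
                worst = d
        if worst is None:
            return expr
        n = worst.derivative_count
        coeff = expr.coeff(worst, 1)
        rest = sp.expand(expr - coeff * worst)
        if rest.has(worst):  # pragma: no cover - structurally impossible
            raise RuntimeError("nonlinear high-order derivative term")
        lower = sp.Derivative(V(R), (R, n - 1))
        expr = sp.expand(
            rest + lower * (BETA * sp.Derivative(V(R), R) * coeff - sp.diff(coeff, R))
        )


def lambdified_integrand(order: int, reduced: bool = True):
    """Numeric (R, beta, v1, v2, v3, mu) -> A_n from the symbolic result.

    Only valid for ``reduced=True``; the raw integrand needs higher
    derivatives and is exposed for symbolic work only.
    """
    expr = reduced_integrand(order)
    v1, v2, v3 = sp.symbols("v1 v2 v3")
    expr = expr.subs(
        [
            (sp.Derivative(V(R), (R, 3)), v3),
            (sp.Derivative(V(R), (R, 2)), v2),
            (sp.Derivative(V(R), R), v1),
        ]
    )
    if expr.has(V(R)):
        raise RuntimeError("undifferentiated V should not appear")
    return sp.lambdify((R, BETA, v1, v2, v3, MU), expr, "numpy")
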