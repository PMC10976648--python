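"""Semiclassical second virial coefficients with quantum corrections.

The classical pairwise contribution is

    B_cl(T) = −2π N_A ∫₀^{r_max} (e^{−V/k_BT} − 1) R² dR,

and nuclear quantum effects are included through the Wigner–Kirkwood
expansion in powers of ħ², evaluated to third order.  The correction
integrands used here were obtained by solving the Bloch equation for
the pair Slater sum order by order, Gaussian-averaging over momenta,
and integrating by parts until no derivative of V above the third
remains; the result was validated against the exact harmonic-oscillator
trace and is re-derivable with :mod:`vdwcomb.semiclassical`.  With
β = 1/k_BT, μ the reduced mass and primes denoting d/dR,

    B_qn = −2π N_A ħ^{2n} ∫ e^{−βV} A_n(R) dR,   n = 1, 2, 3,

where A_n are the polynomials in (V′, V″, V‴, R, β) coded in
:func:`_A1`, :func:`_A2`, :func:`_A3` (each already contains the R²
volume weight).  The first correction is positive (repulsive) at low
temperature and each order scales with a further inverse power of the
mass, so all corrections vanish in the classical (heavy-mass) limit.

The expansion is valid for all noble-gas pairs except He–He, whose
deeply quantum behaviour requires a fully quantum treatment; He–He
comparisons are rejected explicitly.

Tabulated curves are resampled by a natural cubic spline to a 0.025 Å
effective spacing and V′, V″, V‴ are taken from the spline; below the
first tabulated point the Boltzmann factor is taken as zero (the QM
wall there exceeds hundreds of k_BT), contributing −(2π/3)N_A r_first³
analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .constants import (
    ANGSTROM,
    ATOMIC_MASS,
    HBAR,
    K_B,
    KJ_PER_MOL_TO_J,
    M3_TO_CM3,
    N_A,
    R_GAS,
)
from .curves import B2Table, DissociationCurve, resample_spline
from .potentials import (
    PotentialModel,
    _length_scale,
    evaluate_derivative,
    evaluate_energy,
)


class VirialError(ValueError):
    """Invalid virial computation request."""


class UnsupportedPairError(VirialError):
    """Pair outside the validity of the semiclassical expansion."""


@dataclass
class VirialResult:
    """Per-temperature decomposition of B₂ in cm³/mol."""

    T: float
    B_classical: float
    B_qc1: float
    B_qc2: float
    B_qc3: float
    r_max: float
    mass_a: float
    mass_b: float
    #: estimated classical contribution beyond r_max, from a -C6/R^6
    #: asymptote pinned at V(r_max)
    tail_estimate: float = 0.0

    @property
    def B_total(self) -> float:
        return self.B_classical + self.B_qc1 + self.B_qc2 + self.B_qc3


@dataclass
class B2Deviation:
    """Model-vs-experiment comparison at the experimental temperatures."""

    pair: tuple[str, str]
    per_T: list  # (T, B2_model, B2_exp, delta)
    rmse: float


# --------------------------------------------------------------------------
# Wigner-Kirkwood correction integrands (SI units; include the R^2 weight)


def _A1(R, b, v1, v2, v3, mu):
    return (
        R * R * b**3 * v1 * v1 / 24
        - R * R * b * b * v2 / 12
        - R * b * b * v1 / 6
    ) / mu


def _A2(R, b, v1, v2, v3, mu):
    R2 = R * R
    return (
        R2 * b**6 * v1**4 / 1152
        - 11 * R2 * b**5 * v1 * v1 * v2 / 1440
        + R2 * b**4 * v1 * v3 / 240
        + R2 * b**4 * v2 * v2 / 160
        - R * b**5 * v1**3 / 144
        + 11 * R * b**4 * v1 * v2 / 360
        - R * b**3 * v3 / 120
        + b**4 * v1 * v1 / 360
    ) / mu**2


def _A3(R, b, v1, v2, v3, mu):
    R2 = R * R
    return (
        R2 * b**9 * v1**6 / 82944
        - 17 * R2 * b**8 * v1**4 * v2 / 69120
        + R2 * b**7 * v1**3 * v3 / 5760
        + 83 * R2 * b**7 * v1 * v1 * v2 * v2 / 80640
        - 17 * R2 * b**6 * v1 * v2 * v3 / 20160
        - 61 * R2 * b**6 * v2**3 / 120960
        - R2 * b**5 * v3 * v3 / 13440
        - R * b**8 * v1**5 / 6912
        + 17 * R * b**7 * v1**3 * v2 / 8640
        - R * b**6 * v1 * v1 * v3 / 960
        - 83 * R * b**6 * v1 * v2 * v2 / 20160
        + 17 * R * b**5 * v2 * v3 / 10080
        + b**7 * v1**4 / 8640
        - 11 * b**6 * v1 * v1 * v2 / 15120
        - b**5 * v1 * v3 / 5040
        + b**5 * v2 * v2 / 5040
        + b**6 * v1**3 / (7560 * R)
        - b**5 * v1 * v2 / (2520 * R)
        + b**5 * v1 * v1 / (5040 * R2)
    ) / mu**3


_A = {1: _A1, 2: _A2, 3: _A3}

# finite-difference stencils for bare-callable potentials
_FD = {
    1: ({-2: 1 / 12, -1: -2 / 3, 1: 2 / 3, 2: -1 / 12}, 1),
    2: ({-2: -1 / 12, -1: 4 / 3, 0: -5 / 2, 1: 4 / 3, 2: -1 / 12}, 2),
    3: ({-3: 1 / 8, -2: -1, -1: 13 / 8, 1: -13 / 8, 2: 1, 3: -1 / 8}, 3),
}


def _reduced_mass_kg(mass_a, mass_b, convention):
    if mass_a <= 0 or mass_b <= 0:
        raise VirialError("masses must be positive")
    if convention == "reduced":
        mu_u = mass_a * mass_b / (mass_a + mass_b)
    elif convention == "arithmetic":
        mu_u = 0.25 * (mass_a + mass_b)
    else:
        raise VirialError(f"unknown mass convention {convention!r}")
    return mu_u * ATOMIC_MASS


class _PotentialAdapter:
    """Uniform (V, V', V'', V''') interface in kJ/mol and Å."""

    def __init__(self, pot, r_max=None, spline_spacing=0.025):
        self.r_first = 0.0
        self.core_below_first = False
        if isinstance(pot, PotentialModel):
            self.V = lambda r: evaluate_energy(pot, r)
            self.deriv = lambda r, k: evaluate_derivative(pot, r, k)
            self.r_max = r_max if r_max is not None else 50.0 * _length_scale(pot)
            self._finite_at_zero = pot.family == "WBH"
        elif isinstance(pot, DissociationCurve):
            fine = resample_spline(pot, spline_spacing)
            cs = fine.spline()
            self.V = cs
            self.deriv = lambda r, k: cs(r, k)
            self.r_first = float(pot.r[0])
            self.core_below_first = True
            extent = float(pot.r[-1])
            self.r_max = min(r_max, extent) if r_max is not None else extent
            self._finite_at_zero = False
        elif callable(pot):
            if r_max is None:
                raise VirialError("r_max is required for a bare callable potential")
            self.V = np.vectorize(pot, otypes=[float])
            self.deriv = self._fd
            self.r_max = r_max
            self._finite_at_zero = True
        else:
            raise VirialError(f"unsupported potential input {type(pot)!r}")

    def _fd(self, r, k):
        stencil, pw = _FD[k]
        h = 1e-3 * max(float(r), 0.1)
        out = 0.0
        for off, w in stencil.items():
            out += w * float(self.V(float(r) + off * h))
        out /= h**pw
        if not math.isfinite(out):
            raise VirialError(
                f"derivative of order {k} is not finite at r = {r:g} Å "
                "(discontinuous potential?)"
            )
        return out


def _find_core(adapter: _PotentialAdapter, beta_mol: float, r_hi: float) -> float:
    """Largest r at which the repulsive wall exceeds 600 k_BT.

    Everything below is treated as an impenetrable core (integrand −1);
    this also regularizes the unphysical short-range dive of
    exponential-repulsion forms, whose dispersion term overtakes the
    bounded exponential below the wall.  Returns 0.0 when the wall never
    reaches that height (V ≡ 0, or a soft finite-at-origin core).
    """
    if adapter.core_below_first:
        return adapter.r_first
    grid = np.geomspace(max(1e-4, 1e-4 * r_hi), r_hi, 600)
    with np.errstate(over="ignore"):
        v = np.asarray(adapter.V(grid), dtype=float)
    hot = np.where(beta_mol * v >= 600.0)[0]
    if hot.size == 0:
        return 0.0
    return float(grid[hot[-1]])


def b2_semiclassical(
    potential,
    T: float,
    mass_a: float,
    mass_b: float,
    r_max: float | None = None,
    order: int = 3,
    mass_convention: str = "reduced",
    split: Sequence[float] | None = None,
) -> VirialResult:
    """Second virial coefficient with quantum corrections at one T.

    ``potential`` may be a :class:`PotentialModel`, a
    :class:`DissociationCurve` (resampled to 0.025 Å with spline
    derivatives) or a bare callable ``V(r_Å) -> kJ/mol`` (classical and
    finite-difference corrections; pass ``split`` for discontinuities
    and set ``order=0`` for hard steps).  Masses are in u; for unlike
    pairs the printed like-pair mass m is replaced by twice the reduced
    mass (``mass_convention='reduced'``), with the arithmetic mean
    available as an alternative.
    """
    if T <= 0:
        raise VirialError("temperature must be positive")
    if order not in (0, 1, 2, 3):
        raise VirialError("order must be 0..3")
    mu = _reduced_mass_kg(mass_a, mass_b, mass_convention)
    adapter = _PotentialAdapter(potential, r_max=r_max)
    rmax = adapter.r_max

    beta_mol = 1.0 / (R_GAS * T)  # mol/kJ, multiplies kJ/mol energies
    beta_si = 1.0 / (K_B * T)

    r_core = _find_core(adapter, beta_mol, rmax)
    pts = sorted(
        p for p in (list(split) if split else []) if r_core < p < rmax
    )

    # classical term, computed in A^3 then converted
    def f_cl(r):
        return (np.exp(-beta_mol * adapter.V(r)) - 1.0) * r * r

    prefac_cl = 2.0 * math.pi * N_A * ANGSTROM**3 * M3_TO_CM3  # cm^3/mol per A^3
    I_cl, _ = quad(
        f_cl, r_core, rmax, points=pts or None, limit=300,
        epsabs=1e-4 / prefac_cl, epsrel=1e-10,
    )
    core = -(r_core**3) / 3.0  # exp(-beta V) treated as 0 below r_core
    B_cl = -prefac_cl * (I_cl + core)

    # quantum corrections, computed in SI
    B_q = [0.0, 0.0, 0.0]
    if order > 0:
        kj_m = KJ_PER_MOL_TO_J / ANGSTROM  # kJ/mol/A -> J/m, per derivative order
        # the Boltzmann factor kills the integrand below the core radius;
        # start just there (never below 1e-3 A, where stencils degenerate)
        lo = max(r_core, 1e-3)
        # probe the derivatives next to any declared split: a genuine
        # discontinuity must fail loudly rather than be silently missed
        for p in pts:
            for rp in (p - 2e-3, p + 2e-3):
                if rp > lo and math.exp(-beta_mol * float(adapter.V(rp))) > 0:
                    for k in (1, 2, 3):
                        val = float(adapter.deriv(rp, k))
                        if not math.isfinite(val):
                            raise VirialError(
                                f"derivative of order {k} not finite near the "
                                f"split at r = {p:g} Å (discontinuous potential)"
                            )
        for n in range(1, order + 1):
            An = _A[n]

            def f_q(r_ang):
                v = float(adapter.V(r_ang))
                ex = math.exp(-beta_mol * v)
                if ex == 0.0:
                    return 0.0
                v1 = float(adapter.deriv(r_ang, 1)) * kj_m
                v2 = float(adapter.deriv(r_ang, 2)) * kj_m / ANGSTROM
                v3 = float(adapter.deriv(r_ang, 3)) * kj_m / ANGSTROM**2
                R = r_ang * ANGSTROM
                return ex * An(R, beta_si, v1, v2, v3, mu)

            prefac = 2.0 * math.pi * N_A * HBAR ** (2 * n) * M3_TO_CM3 * ANGSTROM
            # full_output suppresses the slow-convergence warning the
            # R^-6 tail of the linear-derivative terms provokes
            out = quad(
                f_q, lo, rmax, points=pts or None, limit=300,
                epsabs=1e-4 / prefac, epsrel=1e-10, full_output=1,
            )
            B_q[n - 1] = -prefac * out[0]

    # classical tail beyond r_max from a -C6/R^6 asymptote pinned at r_max
    v_end = float(adapter.V(rmax))
    tail = -prefac_cl * (-beta_mol * v_end * rmax**3 / 3.0)

    return VirialResult(
        T=T,
        B_classical=B_cl,
        B_qc1=B_q[0],
        B_qc2=B_q[1],
        B_qc3=B_q[2],
        r_max=rmax,
        mass_a=mass_a,
        mass_b=mass_b,
        tail_estimate=tail,
    )


def b2_curve(
    potential, temperatures, mass_a, mass_b, **kwargs
) -> list[VirialResult]:
    """B₂(T) over a temperature sequence."""
    return [
        b2_semiclassical(potential, float(T), mass_a, mass_b, **kwargs)
        for T in temperatures
    ]


def b2_vs_experiment(
    potential,
    exp_table: B2Table,
    mass_a: float | None = None,
    mass_b: float | None = None,
    r_max: float | None = None,
    order: int = 3,
    mass_convention: str = "reduced",
) -> B2Deviation:
    """Deviation of the computed B₂ from an experimental table.

    He–He is rejected: the semiclassical expansion is not valid for the
    helium dimer, which requires a fully quantum treatment.
    """
    pair = (exp_table.element_a, exp_table.element_b)
    if pair == ("He", "He"):
        raise UnsupportedPairError(
            "He-He is outside the validity of the semiclassical expansion; "
            "a fully quantum treatment of B2 is required for the helium dimer"
        )
    if exp_table.T.size == 0:
        raise VirialError("experimental table is empty")
    from .constants import atomic_mass_u

    if mass_a is None:
        mass_a = atomic_mass_u(exp_table.element_a)
    if mass_b is None:
        mass_b = atomic_mass_u(exp_table.element_b)
    rows = []
    for T, b_exp in zip(exp_table.T, exp_table.B2):
        res = b2_semiclassical(
            potential, float(T), mass_a, mass_b, r_max=r_max, order=order,
            mass_convention=mass_convention,
        )
        rows.append((float(T), res.B_total, float(b_exp), res.B_total - float(b_exp)))
    delta = np.array([r[3] for r in rows])
    return B2Deviation(pair=pair, per_T=rows, rmse=float(np.sqrt(np.mean(delta**2))))


def hard_sphere_b2(diameter: float) -> float:
    """Closed-form classical hard-sphere B₂ = (2π/3) N_A d³ in cm³/mol."""
    return 2.0 * math.pi / 3.0 * N_A * (diameter * ANGSTROM) ** 3 * M3_TO_CM3
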