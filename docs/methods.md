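# Methods

This note documents the models implemented in `vdwcomb`, the numerical
choices behind them, what the synthetic data emulate, and the limits of
what the tests demonstrate.  Units throughout: Å, kJ/mol, K, cm³/mol;
all physical constants are CODATA 2018 values centralized in
`vdwcomb.constants`.

## Pair potential families

All families return the pair interaction energy E(r) of two atoms at
separation r.  Parameter conventions follow the forms most common in
the force-field literature; where a family admits several conventions,
the choice is pinned by unit tests (double-entry transcription tests
that compare against independently typed forms, and well-convention
tests).

| family | form | parameters | well convention |
|---|---|---|---|
| LJ12-6 | 4ε[(σ/r)¹² − (σ/r)⁶] | ε, σ | σ = zero crossing, min at 2^{1/6}σ |
| LJ8-6 | ε[3(σ/r)⁸ − 4(σ/r)⁶] | ε, σ | min at σ, depth ε |
| LJ14-7 | ε((1+δ)/(x+δ))⁷((1+γ)/(x⁷+γ) − 2), x = r/σ | ε, σ, γ, δ | min near σ (exactly σ only if γ = δ) |
| MRS (Morse) | ε[e^{2γ(1−r/σ)} − 2e^{γ(1−r/σ)}] | ε, σ, γ | min at σ, depth ε |
| BHA (Buckingham) | A e^{−br} − C₆/r⁶ | A, C₆, b | numeric; diverges to −∞ at r → 0 |
| MBH (exp-6) | ε/(1−6/γ)[(6/γ)e^{γ(1−r/σ)} − (σ/r)⁶], γ > 6 | ε, σ, γ | min at σ, depth ε |
| WBH | 2ε/(1−3/(γ+3)) · σ⁶/(σ⁶+r⁶) · [(3/(γ+3))e^{γ(1−r/σ)} − 1] | ε, σ, γ | min at σ, depth ε; finite at r = 0 |
| GBH | ε/(1−δ/γ)[(δ/γ)e^{γ(1−r/σ)} − (σ/r)^δ], γ > δ | ε, σ, γ, δ | min at σ, depth ε |
| TT | D_e[A* e^{−bx} − Σ_{n=3,4,5} f_{2n}(bx) C*_{2n} x^{−2n}], x = r/R_e | A*, b, C*₆, C*₈, C*₁₀ (+ fixed R_e, D_e) | well at (R_e, −D_e) when parameters are calibrated |

The Morse steepness γ is kept dimensionless (rather than a 1/length)
so that all three parameters can be combined by dimension-agnostic
rules.  The Tang–Toennies damping f_{2n}(y) = 1 − e^{−y}Σ_{k≤2n} yᵏ/k!
is evaluated as the regularized lower incomplete gamma function
P(2n+1, y) (`scipy.special.gammainc`), which is cancellation-free at
small y where the subtracted form loses all significance; a unit test
pins the y^{2n+1}/(2n+1)! leading behaviour down to y = 10⁻⁴.

MBH and BHA are the same function in different parameterizations; the
conversions A = ε(6/γ)e^γ/(1−6/γ), b = γ/σ, C₆ = εσ⁶/(1−6/γ) and the
inverse are implemented and tested to 1e-10 over 0.2–28 Å.  This
identity is also used as a cross-family fitting oracle.

Derivatives up to third order are analytic for LJ12-6, LJ8-6, Morse,
BHA and MBH, and fourth-order central finite differences with step
h = 10⁻³·max(r, 0.5 Å) for the remaining families — correctness over
elegance, and the virial module accepts either route.  `locate_well`
returns closed forms where the convention fixes them and otherwise
scans a dense grid for the *outermost* interior local minimum (skipping
the unphysical short-range branch of Buckingham-type forms) refined by
bounded scalar minimization.

## Curves, windows and fitting

Dissociation curves are ordered (r, E) tables with provenance tags;
files are human-diffable TSV with `#` metadata.  Resampling uses a
natural cubic spline (the conventional default boundary condition,
recorded here so tests are deterministic).  The two-point
complete-basis-set extrapolation utility implements the n³ scheme
E_CBS = (n³E_n − (n−1)³E_{n−1})/(n³ − (n−1)³) for correlation energies
only — any SCF component should be passed through unextrapolated by
the caller.

Fitting minimizes the unweighted sum of squared energy residuals over
the points retained by an energy window: E ≤ 20 kJ/mol on the
repulsive wall and |E| ≥ 10 % of the well depth in the tail (defaults;
both configurable).  The depth used by the window is spline-refined
rather than the coarsest grid minimum, because 0.1 Å grids misplace
shallow wells.  No weighting is applied; since RMSE values from curves
with different point densities are not directly comparable, every
result reports the number of fitted points.

The optimizer is bounded trust-region least squares
(`scipy.optimize.least_squares`) started from one curve-derived
heuristic guess plus 15 seeded Latin-hypercube points (log-uniform for
parameters whose admissible range spans more than two decades).  Bounds
default to curve-adaptive boxes — σ within a factor 2 of the well
position, ε within a factor 10 of the depth, fixed physical boxes for
shape parameters — because loosely chosen bounds demonstrably trap the
optimizer; the bounds and seed used are part of every `FitResult`.
For the TT family, R_e and D_e are held fixed and only the five
dimensionless parameters are adjusted, which restricts that family to
mixtures whose combined well is known beforehand.

## Combination rules

Twelve relations (identifiers 10–21) map homodimer parameters to
heterodimer ones; all are symmetric and idempotent, which is the
homodimer self-consistency requirement.  Single-input relations
(10, 11, 12, 14, 17, 18, 19, 20, 21) may be applied to any parameter.
Three are parameter-specific: the Hogervorst σ relation (13) combines
the exp-6 dispersion coefficients C₆ᵢ = εᵢγᵢσᵢ⁶/(γᵢ−6) geometrically
and solves for σ₁₂ using the already-combined ε₁₂ and γ₁₂ (singular if
either vanishes or any γ ≤ 6); the Mason γ relation (15) averages the
inverse-length slopes γᵢ/σᵢ on the arithmetic-mean radius; the
Waldman–Hagler ε relation (16) consumes the homodimer σ of both atoms.
Dependency order is resolved automatically (everything except a
rule-13 σ first); the ordering chain
inverse-volume ≤ harmonic ≤ geometric ≤ arithmetic ≤ volume ≤
sixth-power mean and the strictly-sub-geometric property of the
inverse-volume mean are property-tested over 10⁴ random inputs.

The exhaustive scan enumerates the Cartesian product of admissible
rules per parameter (default admissibility: all single-input rules
everywhere, 13/15/16 where defined — 9 000 rule sets for a
four-parameter family), scores each by the unweighted mean windowed
RMSE over the heterodimer pairs, and sorts ascending with ties broken
by the equation-id tuple.  Rule sets that hit a singularity on any
pair score +∞ and sort last rather than aborting the scan — a
permutation scan must survive individual pathological rules.

## Second virial coefficients

B₂(T) = B_cl + B_q1 + B_q2 + B_q3 with

    B_cl = −2π N_A ∫₀^{r_max} (e^{−βV} − 1) R² dR,   β = 1/k_BT,
    B_qn = −2π N_A ħ^{2n} ∫ e^{−βV} A_n(R; β, μ) dR,

where μ is the reduced mass.  The correction integrands A_n were
derived symbolically (the machinery ships in
`vdwcomb.semiclassical`): the Bloch equation for the pair Slater sum
is solved order by order in ħ (Wigner–Kirkwood expansion), the
momentum dependence is Gaussian-averaged, the result is specialized to
spherical symmetry, and integration by parts removes every derivative
of V above the third.  Three independent validations back the frozen
forms: (i) the expansion reproduces the exact harmonic-oscillator
trace (2 sinh(βħω/2))⁻³ term by term through ħ⁶ — coefficients −1/8,
17/1920, −457/967680 — a check run numerically against the coded
integrands in the test suite; (ii) the ħ² term is the classic Wigner
correction −(β²/12μ)(∇²V − β(∇V)²/2); (iii) the ħ⁴ term agrees under
the integral with the classic literature form
−(πN_Aħ⁴β⁴/6m²)∫e^{−βV}[V″²/10 + V′²/(5R²) + βV′³/(9R) − β²V′⁴/72]R²dR
once the like-pair atom mass m is identified with 2μ.  That
identification is also the package's heterodimer convention: formulas
printed with "the atom mass" for like pairs are evaluated with 2μ,
which reduces to m for identical atoms (an arithmetic-mean-mass
alternative is available behind a flag).

Numerics: adaptive quadrature (`scipy.integrate.quad`, absolute
tolerance 1e-4 cm³/mol) on either the analytic model or a natural
cubic spline of the tabulated curve resampled to 0.025 Å, with V′, V″,
V‴ from the spline.  Below the largest radius where βV ≥ 600 the
Boltzmann factor is taken as exactly zero, contributing −(2π/3)N_A r³
analytically; for tabulated curves the same treatment applies below
the first sample (quantum-chemical walls there exceed hundreds of
k_BT).  This cut also regularizes the unphysical short-range dive of
exponential-repulsion families, whose bounded exponential is overtaken
by the dispersion term deep inside the wall.  r_max defaults to the
data extent for curves and 50 length scales for models; the classical
tail beyond r_max is estimated from a −C₆/R⁶ asymptote pinned at
V(r_max) and reported.  Discontinuous potentials (hard steps) are
supported for the classical term via explicit split points; requesting
quantum corrections across a declared split raises a derivative error.

The expansion is semiclassical: it is not valid for He–He, and the
comparison driver rejects that pair explicitly.

## Three-body dispersion

The Axilrod–Teller triple-dipole energy
V_ABC(1 + 3cosθ_A cosθ_B cosθ_C)/(r_AB r_BC r_CA)³ is evaluated from
Cartesian positions via dot products; a triplet enters the total sum
when **all three** pair distances are within the cutoff (the single
stated cutoff convention; a center-based criterion would change totals
only for triplets straddling the cutoff shell).  Periodic boxes use
the minimum-image convention, and the cutoff may not exceed half the
smallest box length.  Coefficients V_ABC ship as an empty user-filled
YAML schema keyed by sorted element triples — no published values are
bundled.  The module computes energies only (no forces, no dynamics);
it exists to validate force-field files and energy audits for external
simulators.  Δ_vap H = −E_pot(liquid) + RT interprets Boltzmann's
constant per mole, consistent with the molar energy convention.

## Synthetic data and what the tests show

The synthetic world emulates the study conditions of a five-element
noble-gas-like series: homodimer wells from (2.97 Å, 0.091 kJ/mol) to
(4.36 Å, 2.35 kJ/mol) — helium-like through xenon-like — scanned in
0.1 Å steps up to 30 Å, with optional seeded Gaussian noise (0.01
kJ/mol in the noisy experiments).  Shape parameters (γ, δ, TT
dispersion coefficients) vary by ±6 %/±2 % across the series: without
element-distinct shapes, shape-parameter combination rules would be
unidentifiable, since every rule is idempotent.  Heterodimer ground
truths are *constructed* from the homodimer truths by a planted
combination rule, so rule-recovery experiments have a unique known
answer.

That construction is also the main caveat: in the synthetic world a
perfect combination rule exists by design, whereas real heterodimer
physics is not exactly representable by any rule applied to any of
these families.  Passing the planted-rule and recovery tests
demonstrates the machinery (windowing, fitting, enumeration, scoring,
tie-breaking) is correct, not that any particular rule is physically
superior.  Similarly, synthetic noise is i.i.d. Gaussian on a uniform
grid; real quantum-chemistry curves have r-dependent, correlated
errors and occasionally ill-behaved SAPT tails — which is precisely
why the virial comparison accepts raw tabulated curves as well as
fitted models.

Problem sizes used by the default test suite and the acceptance
script: 15-curve worlds, 9 000-rule-set scans for four-parameter
families, 50-seed noise replicates, 20-atom three-body configurations,
and 10⁴-sample property checks.

## Known limitations

* The He–He pair is outside the semiclassical B₂ expansion by
  construction; no phase-shift or path-integral route is provided.
* BHA's r → 0 divergence is regularized in the virial integral by the
  impenetrable-core cut; energies below the repulsive barrier are
  reported as-is and are unphysical.
* The TT family cannot be combined or fitted without externally
  supplied (R_e, D_e) for the pair.
* Rule identifiability degrades to tie-breaking whenever two elements
  share a parameter value exactly.
* No simulation engine: melting points, densities and other condensed
  phase observables require an external MD code consuming the
  parameter files produced here.
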