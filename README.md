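# vdwcomb

A workbench for developing and evaluating **van der Waals pair
potentials** for noble-gas-like systems.  It covers the full pipeline a
force-field developer needs between a set of dimer dissociation curves
and a validated nonbonded model:

* **Nine analytic potential families** — Lennard-Jones 12-6 and 8-6,
  buffered 14-7 (Halgren), Morse, Buckingham (A·e^(−br) − C₆/r⁶),
  modified Buckingham (exp-6), Wang–Buckingham (exp-6 made finite at
  r = 0), a generalized four-parameter Buckingham with adjustable
  long-range exponent, and the five-parameter dimensionless
  Tang–Toennies form with incomplete-gamma dispersion damping.
* **Window-restricted least-squares fitting** of any family to a
  dissociation curve (default window: repulsive cutoff 20 kJ/mol,
  tail cut at 10 % of the well depth), with curve-adaptive bounds and
  seeded Latin-hypercube multi-starts.
* **Combination rules.** Twelve classical and modern combination
  relations (geometric, arithmetic, harmonic, Hogervorst, Yang/Morse,
  Mason, Waldman–Hagler, cubic-mean, Halgren HHG, sixth-power mean,
  volume mean and its sub-geometric inverse-volume counterpart) that map
  homodimer parameters to heterodimer ones, plus an **exhaustive
  permutation scan** that ranks every admissible per-parameter rule
  assignment against heterodimer reference curves.
* **Semiclassical second virial coefficients** B₂(T): the classical
  integral −2πN_A ∫ (e^(−V/k_BT) − 1) R² dR plus Wigner–Kirkwood quantum
  corrections to third order in ħ², for analytic models and for
  spline-interpolated tabulated curves (0.025 Å effective spacing).
  Valid for all noble-gas pairs except He–He, which is rejected.
* **Axilrod–Teller triple-dipole dispersion** for atom triplets and
  periodic configurations, and an enthalpy-of-vaporization helper
  Δ_vap H = −E_pot(l) + RT.
* A **synthetic-data module**: ground-truth curves scanned in 0.1 Å
  steps up to 30 Å with optional seeded Gaussian noise, and a
  five-element noble-gas-like world whose heterodimers are generated by
  a planted combination rule — so every operation is testable with no
  external data.

Everything uses one unit convention: Å, kJ/mol, K, cm³/mol.

## Worked example

Fit a four-parameter generalized Buckingham to a noisy synthetic
argon-like curve and predict its second virial coefficient:

```python
from vdwcomb import (
    PotentialModel, generate_synthetic_curve, fit_potential,
    b2_semiclassical, locate_well,
)

truth = PotentialModel("LJ12-6", {"sigma": 3.4, "epsilon": 0.998})
curve = generate_synthetic_curve(truth, 2.2, 30.0, 0.1, noise_sd=0.01, seed=7)

fit = fit_potential("GBH", curve, seed=0)
print(f"GBH fit: rmse = {fit.rmse:.4f} kJ/mol over {fit.n_points} points")
for name, value in fit.model.params.items():
    print(f"  {name} = {value:.4f}")

r_min, depth = locate_well(fit.model)
print(f"well: r_min = {r_min:.3f} A, depth = {depth:.3f} kJ/mol")

b2 = b2_semiclassical(fit.model, 273.15, 39.948, 39.948, r_max=30.0)
print(f"B2(273.15 K) = {b2.B_total:.2f} cm^3/mol "
      f"(classical {b2.B_classical:.2f}, first quantum correction {b2.B_qc1:+.3f})")
```

prints

```
GBH fit: rmse = 0.0247 kJ/mol over 33 points
  epsilon = 0.9968
  sigma = 3.7959
  gamma = 16.9102
  delta = 4.8503
well: r_min = 3.796 A, depth = 0.997 kJ/mol
B2(273.15 K) = -34.92 cm^3/mol (classical -35.06, first quantum correction +0.139)
```

The fit nails the well (true position 3.816 Å, depth 0.998 kJ/mol)
within the 0.01 kJ/mol noise, but the fitted long-range exponent
δ ≈ 4.9 gives a fatter attractive tail than the true r⁻⁶ — and B₂,
which integrates the whole curve, moves from −21.3 (the ground truth)
to −34.9 cm³/mol.  Points outside the fitting window are irrelevant
for the well region yet decisive for virial coefficients; this is the
kind of trade-off the workbench is built to expose.

Ranking combination rules on a synthetic world with a planted rule:

```python
from vdwcomb.workbench import synthetic_world, rule_study

curves, truths, rule = synthetic_world(family="GBH", heterodimer_rule="10 20 14 10")
summary, rankings = rule_study(curves, families=("GBH",), seed=0)
print(summary.loc["GBH", "best_rule"])   # -> "10 20 14 10"
```

Rule sets are written as space-separated equation identifiers in the
family's canonical parameter order (ε σ γ δ for GBH), e.g. `10 20 14
10` = geometric ε, volume-mean σ, Morse-type γ, geometric δ.

## Command line

```bash
vdwcomb synth --family LJ12-6 --params lj.yaml --step 0.1 --stop 30 -o ar.tsv
vdwcomb fit --family GBH --curve ar.tsv --window 20:0.10 --seed 7 -o fit.yaml
vdwcomb scan-rules --family GBH --curves curves/ -o ranking/
vdwcomb b2 --model fit.yaml --mass-a 39.948 --mass-b 39.948 --temps 100:700:25
vdwcomb b2-compare --curve ar.tsv --exp ar-exp.tsv
vdwcomb at3 --xyz box.xyz --coeffs ddd.yaml --cutoff 10.0
vdwcomb cbs --n 4 --e-small -0.9 --e-large -1.0
vdwcomb dhvap --epot -2.0 --temp 100
```

Curve files are two-column TSV (separation Å, energy kJ/mol) with
`#`-prefixed metadata (`# pair: He Xe`, `# source: ...`); experimental
B₂ tables use (T in K, B₂ in cm³/mol); models are small YAML documents.

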