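"""Physical constants and unit conventions.

Package-wide unit conventions: separations in angstrom (Å), pair energies
in kJ/mol, temperatures in K, second virial coefficients in cm³/mol.
All constants are CODATA 2018 values, centralized here so that no module
carries its own conversion factors.
"""

from __future__ import annotations

#: Avogadro constant, 1/mol (exact).
N_A = 6.02214076e23

#: Boltzmann constant, J/K (exact).
K_B = 1.380649e-23

#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34

#: Molar gas constant, kJ/(mol K).
R_GAS = 8.31446261815324e-3

#: Unified atomic mass unit, kg.
ATOMIC_MASS = 1.66053906660e-27

#: One kJ/mol expressed in J per particle.
KJ_PER_MOL_TO_J = 1e3 / N_A

#: One angstrom in metres.
ANGSTROM = 1e-10

#: One m³/mol in cm³/mol.
M3_TO_CM3 = 1e6

#: Standard atomic weights (u) of the noble gases handled by the workbench.
ATOMIC_MASSES_U = {
    "He": 4.002602,
    "Ne": 20.1797,
    "Ar": 39.948,
    "Kr": 83.798,
    "Xe": 131.293,
    "Rn": 222.0,
}


def atomic_mass_u(element: str) -> float:
    """Atomic mass in u for a supported element symbol."""
    try:
        return ATOMIC_MASSES_U[element]
    except KeyError:
        raise KeyError(
            f"no tabulated atomic mass for element {element!r}; "
            "pass masses explicitly"
        ) from None
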