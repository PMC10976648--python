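"""Axilrod–Teller triple-dipole dispersion and a vaporization helper.

The leading non-additive three-body dispersion term for atoms A, B, C is

    E_ABC = V_ABC (1 + 3 cosθ_A cosθ_B cosθ_C) / (r_AB r_BC r_CA)³,

with θ the internal angles of the triangle and V_ABC a positive
substance-specific coefficient (kJ Å⁹/mol).  The term is repulsive for
near-equilateral geometries and attractive for near-linear ones.

Configurations are plain XYZ files; an orthorhombic periodic box may be
given on the comment line as ``box a b c`` (Å), in which case distances
use the minimum-image convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import yaml

from .constants import R_GAS


class ThreeBodyError(ValueError):
    """Invalid three-body input."""


@dataclass
class Configuration:
    """Atom positions (Å), element symbols, optional periodic box lengths."""

    positions: np.ndarray
    elements: list[str]
    box: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ThreeBodyError("positions must be an (n, 3) array")
        if len(self.elements) != self.positions.shape[0]:
            raise ThreeBodyError("elements and positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ThreeBodyError("positions must be finite")
        if self.box is not None:
            self.box = tuple(float(b) for b in self.box)
            if len(self.box) != 3 or any(b <= 0 for b in self.box):
                raise ThreeBodyError("box lengths must be three positive values")

    def __len__(self):
        return self.positions.shape[0]


def read_xyz(path) -> Configuration:
    """Read an XYZ file; ``box a b c`` on the comment line sets the box."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ThreeBodyError(f"{path}: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ThreeBodyError(f"{path}:1: expected an atom count") from None
    box = None
    comment = lines[1].split()
    if comment[:1] == ["box"] and len(comment) >= 4:
        box = tuple(float(v) for v in comment[1:4])
    elements, pos = [], []
    for lineno, line in enumerate(lines[2 : 2 + n], start=3):
        fields = line.split()
        if len(fields) < 4:
            raise ThreeBodyError(f"{path}:{lineno}: expected 'El x y z'")
        elements.append(fields[0])
        try:
            pos.append([float(v) for v in fields[1:4]])
        except ValueError:
            raise ThreeBodyError(f"{path}:{lineno}: malformed coordinate") from None
    if len(pos) != n:
        raise ThreeBodyError(f"{path}: expected {n} atoms, found {len(pos)}")
    return Configuration(np.array(pos), elements, box)


def read_coefficients(path) -> dict[tuple[str, str, str], float]:
    """YAML table of V_ABC keyed by 'El El El' (sorted element triple)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    table = {}
    for key, val in doc.items():
        triple = tuple(sorted(str(key).split()))
        if len(triple) != 3:
            raise ThreeBodyError(f"coefficient key {key!r} is not an element triple")
        table[triple] = float(val)
    return table


def _mic(d, box):
    if box is None:
        return d
    b = np.asarray(box)
    return d - b * np.round(d / b)


def axilrod_teller_energy(pos_a, pos_b, pos_c, v_abc: float, box=None) -> float:
    """Triple-dipole energy (kJ/mol) of one atom triplet.

    Invariant under any permutation of the three atoms and under rigid
    rotations/translations; raises on coincident points.
    """
    a = np.asarray(pos_a, dtype=float)
    b = np.asarray(pos_b, dtype=float)
    c = np.asarray(pos_c, dtype=float)
    ab = _mic(b - a, box)
    ac = _mic(c - a, box)
    bc = _mic(c - b, box)
    r_ab = np.linalg.norm(ab)
    r_ac = np.linalg.norm(ac)
    r_bc = np.linalg.norm(bc)
    if min(r_ab, r_ac, r_bc) <= 0:
        raise ThreeBodyError("coincident atoms in a three-body triplet")
    cos_a = float(np.dot(ab, ac)) / (r_ab * r_ac)
    cos_b = float(np.dot(-ab, bc)) / (r_ab * r_bc)
    cos_c = float(np.dot(-ac, -bc)) / (r_ac * r_bc)
    return v_abc * (1.0 + 3.0 * cos_a * cos_b * cos_c) / (r_ab * r_bc * r_ac) ** 3


def three_body_total(
    config: Configuration,
    coefficients: dict[tuple[str, str, str], float],
    cutoff: float,
) -> float:
    """Sum of triple-dipole energies over all unordered triplets whose
    three pair distances are all within the cutoff (minimum image when
    periodic)."""
    if cutoff <= 0:
        raise ThreeBodyError("cutoff must be positive")
    n = len(config)
    if n < 3:
        raise ThreeBodyError("three-body evaluation needs at least 3 atoms")
    if config.box is not None and cutoff > 0.5 * min(config.box):
        raise ThreeBodyError("cutoff exceeds half the smallest box length")
    pos = config.positions
    # pair distance matrix (minimum image if periodic)
    diff = pos[:, None, :] - pos[None, :, :]
    diff = _mic(diff, config.box)
    dist = np.sqrt((diff**2).sum(axis=-1))
    within = dist <= cutoff
    total = 0.0
    for i, j, k in itertools.combinations(range(n), 3):
        if not (within[i, j] and within[j, k] and within[i, k]):
            continue
        triple = tuple(sorted((config.elements[i], config.elements[j], config.elements[k])))
        if triple not in coefficients:
            raise ThreeBodyError(f"no coefficient for element triple {triple}")
        total += axilrod_teller_energy(
            pos[i], pos[j], pos[k], coefficients[triple], config.box
        )
    return total


def enthalpy_of_vaporization(e_pot_liquid: float, T: float) -> float:
    """Δ_vap H = E_pot(gas) − E_pot(liquid) + R·T with E_pot(gas) = 0.

    Energies are molar (kJ/mol), so Boltzmann's constant enters as the
    molar gas constant R.
    """
    if T < 0:
        raise ThreeBodyError("temperature must be >= 0")
    if not math.isfinite(e_pot_liquid):
        raise ThreeBodyError("liquid potential energy must be finite")
    return -e_pot_liquid + R_GAS * T
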