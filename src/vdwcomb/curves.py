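"""Dissociation curves, experimental B₂ tables, synthetic data and CBS.

Curve files are plain TSV/CSV with ``#``-prefixed metadata lines::

    # pair: He Xe
    # source: CCSD(T)/CBS
    3.0   1.234
    3.1   0.567

Columns are separation (Å) and interaction energy (kJ/mol); B₂ tables
use temperature (K) and B₂ (cm³/mol) instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .potentials import PotentialModel, evaluate_energy


class CurveError(ValueError):
    """Invalid curve data."""


class ParseError(CurveError):
    """Malformed curve or table file."""


@dataclass
class DissociationCurve:
    """Ordered (r, E) samples for one element pair.

    r in Å (strictly increasing, positive), E in kJ/mol; ``source_tag``
    is free-text provenance (level of theory, or a synthetic recipe).
    """

    element_a: str
    element_b: str
    r: np.ndarray
    energy: np.ndarray
    source_tag: str = ""

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.r.shape != self.energy.shape or self.r.ndim != 1:
            raise CurveError("r and energy must be 1-D arrays of equal length")
        if self.r.size < 2:
            raise CurveError("a curve needs at least 2 points")
        if np.any(self.r <= 0):
            raise CurveError("separations must be positive")
        dr = np.diff(self.r)
        if np.any(dr == 0):
            dup = self.r[:-1][dr == 0]
            raise CurveError(f"duplicate separations: {dup[:5].tolist()}")
        if np.any(dr < 0):
            raise CurveError("separations must be strictly increasing")
        if not np.all(np.isfinite(self.energy)):
            raise CurveError("energies must be finite at every point")

    def __len__(self):
        return self.r.size

    @property
    def pair(self) -> tuple[str, str]:
        return (self.element_a, self.element_b)

    def validate_well(self) -> None:
        """Check the tail invariant: |E| at the largest r must not exceed
        the well depth magnitude (the tail approaches zero)."""
        depth = -float(self.energy.min())
        if depth <= 0:
            raise CurveError("curve has no negative minimum")
        if abs(float(self.energy[-1])) > depth:
            raise CurveError("tail energy exceeds the well depth magnitude")

    def subset(self, mask) -> "DissociationCurve":
        return DissociationCurve(
            self.element_a, self.element_b, self.r[mask], self.energy[mask],
            self.source_tag,
        )

    def spline(self) -> CubicSpline:
        if len(self) < 4:
            raise CurveError("at least 4 points are needed for a cubic spline")
        return CubicSpline(self.r, self.energy, bc_type="natural")


@dataclass
class B2Table:
    """Experimental second virial coefficients for one element pair."""

    element_a: str
    element_b: str
    T: np.ndarray
    B2: np.ndarray
    source_tag: str = ""

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.B2 = np.asarray(self.B2, dtype=float)
        if self.T.shape != self.B2.shape or self.T.ndim != 1:
            raise CurveError("T and B2 must be 1-D arrays of equal length")
        if np.any(self.T <= 0):
            raise CurveError("temperatures must be positive")
        if np.any(np.diff(self.T) <= 0):
            raise CurveError("temperatures must be strictly increasing")


# --------------------------------------------------------------------------
# file I/O

_PAIR_RE = re.compile(r"#\s*pair\s*:\s*(\S+)[\s,]+(\S+)")
_SOURCE_RE = re.compile(r"#\s*source\s*:\s*(.*\S)")


def _read_two_columns(path):
    meta = {"a": "", "b": "", "source": ""}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _PAIR_RE.match(line)
                if m:
                    meta["a"], meta["b"] = m.group(1), m.group(2)
                m = _SOURCE_RE.match(line)
                if m:
                    meta["source"] = m.group(1)
                continue
            fields = re.split(r"[,\s]+", line)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            try:
                rows.append((float(fields[0]), float(fields[1])))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: malformed numeric field in {line!r}"
                ) from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return meta, np.array(rows)


def read_curve(path) -> DissociationCurve:
    """Read a dissociation curve; rows are sorted by r, duplicates rejected."""
    meta, data = _read_two_columns(path)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    return DissociationCurve(meta["a"], meta["b"], data[:, 0], data[:, 1], meta["source"])


def write_curve(curve: DissociationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pair: {curve.element_a} {curve.element_b}\n")
        if curve.source_tag:
            fh.write(f"# source: {curve.source_tag}\n")
        fh.write("# r_A\tE_kJ_per_mol\n")
        for r, e in zip(curve.r, curve.energy):
            fh.write(f"{r:.12g}\t{e:.12g}\n")


def read_b2_table(path) -> B2Table:
    meta, data = _read_two_columns(path)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    return B2Table(meta["a"], meta["b"], data[:, 0], data[:, 1], meta["source"])


def write_b2_table(table: B2Table, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pair: {table.element_a} {table.element_b}\n")
        if table.source_tag:
            fh.write(f"# source: {table.source_tag}\n")
        fh.write("# T_K\tB2_cm3_per_mol\n")
        for t, b in zip(table.T, table.B2):
            fh.write(f"{t:.12g}\t{b:.12g}\n")


# --------------------------------------------------------------------------
# resampling

def resample_spline(curve: DissociationCurve, spacing: float) -> DissociationCurve:
    """Natural cubic-spline resampling on a uniform grid of given spacing.

    The grid spans [r_min, r_max] of the input; knot values are
    reproduced exactly at the knots.
    """
    if spacing <= 0:
        raise CurveError("spacing must be positive")
    span = float(curve.r[-1] - curve.r[0])
    if spacing > span:
        raise CurveError("spacing exceeds the span of the curve")
    cs = curve.spline()
    n = int(np.floor(span / spacing + 1e-9))
    grid = curve.r[0] + spacing * np.arange(n + 1)
    if grid[-1] < curve.r[-1] - 1e-9 * span:
        grid = np.append(grid, curve.r[-1])
    else:
        grid[-1] = curve.r[-1]
    return DissociationCurve(
        curve.element_a, curve.element_b, grid, cs(grid), curve.source_tag
    )


# --------------------------------------------------------------------------
# complete-basis-set extrapolation (two-point Helgaker n^3 scheme)

def cbs_extrapolate(e_small: float, e_large: float, n: int) -> float:
    """Extrapolate correlation energies at cardinals (n−1, n) to the CBS
    limit: E = (n³ E_n − (n−1)³ E_{n−1}) / (n³ − (n−1)³).

    Only the correlation component should be extrapolated; any SCF part
    is passed through from the larger basis unextrapolated by the caller.
    """
    if int(n) != n or n < 3:
        raise ValueError("cardinal number n must be an integer >= 3")
    n = int(n)
    n3, m3 = n**3, (n - 1) ** 3
    return (n3 * e_large - m3 * e_small) / (n3 - m3)


# --------------------------------------------------------------------------
# synthetic curves

def generate_synthetic_curve(
    truth: PotentialModel,
    r_start: float,
    r_stop: float = 30.0,
    step: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
    element_a: str = "X",
    element_b: str = "X",
) -> DissociationCurve:
    """Sample a ground-truth potential on a uniform grid, optionally with
    seeded Gaussian noise, mimicking a scanned dissociation curve.

    The default grid convention is 0.1 Å steps up to 30 Å.
    """
    if not (0 < r_start < r_stop):
        raise CurveError("need 0 < r_start < r_stop")
    if step <= 0:
        raise CurveError("step must be positive")
    if noise_sd < 0:
        raise CurveError("noise_sd must be >= 0")
    n = int(round((r_stop - r_start) / step))
    grid = r_start + step * np.arange(n + 1)
    grid = grid[grid <= r_stop + 1e-12]
    energy = evaluate_energy(truth, grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        energy = energy + rng.normal(0.0, noise_sd, size=grid.size)
    params = ",".join(f"{k}={v:g}" for k, v in truth.params.items())
    tag = f"synthetic {truth.family}({params}) noise={noise_sd:g} seed={seed}"
    return DissociationCurve(element_a, element_b, grid, energy, tag)
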