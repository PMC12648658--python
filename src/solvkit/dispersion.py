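"""Parametric two-body D3(0)-style dispersion energy.

The model is the classic pairwise dispersion correction with zero
(original) damping:

    E_disp = - sum_pairs [ s6 * C6/r^6 * f6(r) + s8 * C8/r^8 * f8(r) ]

with the rational damping function ``f_n(r) = 1/(1 + 6 (r/(sr_n R0))^-alpha_n)``
(``sr8 = 1`` by convention), pair C6 coefficients interpolated over the
coordination numbers of the two atoms (Gaussian weights, k3 = 4) and
``C8 = 3 C6 sqrt(Q_A) sqrt(Q_B)``.  For periodic systems the pair sum
runs over all lattice images within the cutoff.  Per-element-pair s8
overrides allow tuning a single interaction class (e.g. an ion-oxygen
channel) while leaving the rest of the parametrization untouched.

Internal units: kcal/mol, Angstrom; C6 in kcal mol^-1 A^6.  Tables in
atomic units are converted at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .core_io import Structure
from .errors import ParseError, ValidationError
from .units import AU_C6_TO_KCAL_A6, BOHR_TO_ANGSTROM

# counting-function constants of the standard CN definition
K1 = 16.0
K2 = 4.0 / 3.0
K3 = 4.0  # Gaussian-weight exponent of the C6(CN) interpolation


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ElementTable:
    """Element and pair data backing the dispersion energy.

    ``covalent_radii`` (A) enter the coordination-number counting
    function; ``sqrt_q`` (A) builds C8 from C6; ``r0_pairs`` (A) are the
    damping cutoff radii; ``c6_reference`` maps each (alphabetically
    ordered) element pair to a list of ``(CN_A, CN_B, C6)`` reference
    points with C6 in kcal mol^-1 A^6.
    """

    covalent_radii: dict[str, float]
    sqrt_q: dict[str, float]
    r0_pairs: dict[tuple[str, str], float]
    c6_reference: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        self.r0_pairs = {_pair_key(*k): float(v) for k, v in self.r0_pairs.items()}
        self.c6_reference = {
            _pair_key(*k): np.atleast_2d(np.asarray(v, dtype=float))
            for k, v in self.c6_reference.items()
        }
        for k, pts in self.c6_reference.items():
            if pts.size == 0:
                raise ValidationError(f"empty C6 reference list for pair {k}")

    def check_elements(self, symbols) -> None:
        for s in set(symbols):
            if s not in self.covalent_radii:
                raise ValidationError(f"no covalent radius for element {s!r}")
            if s not in self.sqrt_q:
                raise ValidationError(f"no sqrt_q entry for element {s!r}")
        for a in set(symbols):
            for b in set(symbols):
                k = _pair_key(a, b)
                if k not in self.r0_pairs:
                    raise ValidationError(f"no R0 for pair {k}")
                if k not in self.c6_reference:
                    raise ValidationError(f"no C6 reference for pair {k}")

    def c6_points(self, a: str, b: str) -> np.ndarray:
        """(m, 3) reference points oriented as (CN_a, CN_b, C6)."""
        key = _pair_key(a, b)
        pts = self.c6_reference[key]
        if (a, b) != key:
            pts = pts[:, [1, 0, 2]]
        return pts

    def r0(self, a: str, b: str) -> float:
        return self.r0_pairs[_pair_key(a, b)]


@dataclass
class DispersionParams:
    """Tunable scaling factors of the dispersion energy.

    ``pair_s8_overrides`` maps element pairs (any order) to an s8 that
    takes precedence over the global ``s8`` for that interaction class.
    """

    s6: float = 1.0
    s8: float = 1.0
    sr6: float = 1.0
    alpha6: float = 14.0
    alpha8: float = 16.0
    pair_s8_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    cutoff: float = 50.0
    cn_cutoff: float = 20.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        for v in (self.s6, self.s8, self.sr6):
            if not math.isfinite(v):
                raise ValidationError("scaling factors must be finite")
        self.pair_s8_overrides = {
            _pair_key(*k): float(v) for k, v in self.pair_s8_overrides.items()
        }

    def s8_for(self, a: str, b: str) -> float:
        return self.pair_s8_overrides.get(_pair_key(a, b), self.s8)

    def replace(self, **kwargs) -> "DispersionParams":
        d = dict(
            s6=self.s6, s8=self.s8, sr6=self.sr6, alpha6=self.alpha6,
            alpha8=self.alpha8, pair_s8_overrides=dict(self.pair_s8_overrides),
            cutoff=self.cutoff, cn_cutoff=self.cn_cutoff,
        )
        d.update(kwargs)
        return DispersionParams(**d)


# ---------------------------------------------------------------------------
# Lattice images
# ---------------------------------------------------------------------------


def _lattice_shifts(cell: np.ndarray, cutoff: float) -> np.ndarray:
    """All integer lattice translations with any chance of entering *cutoff*."""
    recip = np.linalg.inv(cell).T  # rows: reciprocal vectors (no 2 pi)
    nmax = np.ceil(cutoff * np.linalg.norm(recip, axis=1)).astype(int) + 1
    ranges = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid @ cell


def _shifts_for(structure: Structure, cutoff: float) -> np.ndarray:
    if any(structure.pbc):
        if structure.cell is None or abs(np.linalg.det(structure.cell)) < 1e-10:
            raise ValidationError("singular cell with periodic boundaries")
        return _lattice_shifts(structure.cell, cutoff)
    return np.zeros((1, 3))


# ---------------------------------------------------------------------------
# Coordination numbers and C6 interpolation
# ---------------------------------------------------------------------------


def coordination_numbers(
    structure: Structure, element_table: ElementTable, cn_cutoff: float = 20.0
) -> np.ndarray:
    """Fractional coordination number per atom.

    CN_A = sum_{B != A, r < cutoff} 1/(1 + exp(-k1 (k2 (Rcov_A+Rcov_B)/r - 1)))
    with k1 = 16 and k2 = 4/3; for periodic structures the sum runs over
    lattice images within the cutoff.
    """
    element_table.check_elements(structure.symbols)
    coords = structure.coords
    n = len(coords)
    rcov = np.array([element_table.covalent_radii[s] for s in structure.symbols])
    rsum = rcov[:, None] + rcov[None, :]
    cn = np.zeros(n)
    for shift in _shifts_for(structure, cn_cutoff):
        diff = coords[None, :, :] + shift - coords[:, None, :]
        r = np.linalg.norm(diff, axis=-1)
        mask = (r > 1e-12) & (r < cn_cutoff)
        with np.errstate(over="ignore", divide="ignore"):
            contrib = np.where(
                mask, 1.0 / (1.0 + np.exp(-K1 * (K2 * rsum / np.where(mask, r, 1.0) - 1.0))), 0.0
            )
        cn += contrib.sum(axis=1)
    return cn


def c6_interpolated(cn_a: float, cn_b: float, pair_reference_points) -> float:
    """Gaussian-weighted C6(CN) interpolation over reference points.

    C6 = sum_i C6_i L_i / sum_i L_i with
    L_i = exp(-k3 [(CN_A - CN_A,i)^2 + (CN_B - CN_B,i)^2]), k3 = 4.
    """
    pts = np.atleast_2d(np.asarray(pair_reference_points, dtype=float))
    if pts.size == 0:
        raise ValidationError("empty C6 reference list")
    expo = -K3 * ((cn_a - pts[:, 0]) ** 2 + (cn_b - pts[:, 1]) ** 2)
    expo -= expo.max()  # stabilize
    w = np.exp(expo)
    return float(np.dot(w, pts[:, 2]) / w.sum())


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------


def _c6_matrix(structure: Structure, table: ElementTable, cn: np.ndarray) -> np.ndarray:
    n = structure.n_atoms
    c6 = np.empty((n, n))
    cache: dict[tuple, np.ndarray] = {}
    for i in range(n):
        for j in range(i, n):
            a, b = structure.symbols[i], structure.symbols[j]
            pts = cache.get((a, b))
            if pts is None:
                pts = table.c6_points(a, b)
                cache[(a, b)] = pts
            val = c6_interpolated(cn[i], cn[j], pts)
            c6[i, j] = c6[j, i] = val
    return c6


def pair_component_sums(
    structure: Structure, element_table: ElementTable, params: DispersionParams
) -> dict[tuple[str, str], tuple[float, float]]:
    """Unit C6 and C8 sums per element-pair class.

    Returns ``{(elem_a, elem_b): (E6_unit, E8_unit)}`` where the unit
    sums are evaluated with s6 = s8 = 1 (damping from *params*), so that

        E_disp = sum_pairs s6 * E6_unit + s8(pair) * E8_unit.

    This is the linear decomposition the fitting layer exploits.
    """
    element_table.check_elements(structure.symbols)
    coords = structure.coords
    n = len(coords)
    syms = structure.symbols
    cn = coordination_numbers(structure, element_table, params.cn_cutoff)
    c6 = _c6_matrix(structure, element_table, cn)
    sq = np.array([element_table.sqrt_q[s] for s in syms])
    c8 = 3.0 * c6 * sq[:, None] * sq[None, :]
    r0 = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            r0[i, j] = element_table.r0(syms[i], syms[j])

    pair_class = np.empty((n, n), dtype=object)
    classes = sorted({_pair_key(a, b) for a in set(syms) for b in set(syms)})
    class_index = {c: k for k, c in enumerate(classes)}
    idx = np.empty((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            idx[i, j] = class_index[_pair_key(syms[i], syms[j])]

    e6 = np.zeros(len(classes))
    e8 = np.zeros(len(classes))
    cutoff = params.cutoff
    for shift in _shifts_for(structure, cutoff):
        diff = coords[None, :, :] + shift - coords[:, None, :]
        r = np.linalg.norm(diff, axis=-1)
        zero_shift = bool(np.all(np.abs(shift) < 1e-12))
        if zero_shift:
            off = ~np.eye(n, dtype=bool)
            if np.any((r < 1e-8) & off):
                raise ValidationError("zero distance between distinct atoms")
        mask = (r <= cutoff) & (r > 1e-8)
        if not mask.any():
            continue
        rm = r[mask]
        x6 = rm / (params.sr6 * r0[mask])
        x8 = rm / r0[mask]  # sr8 = 1
        f6 = 1.0 / (1.0 + 6.0 * x6 ** (-params.alpha6))
        f8 = 1.0 / (1.0 + 6.0 * x8 ** (-params.alpha8))
        t6 = -0.5 * c6[mask] / rm**6 * f6
        t8 = -0.5 * c8[mask] / rm**8 * f8
        e6 += np.bincount(idx[mask], weights=t6, minlength=len(classes))
        e8 += np.bincount(idx[mask], weights=t8, minlength=len(classes))
    return {c: (float(e6[k]), float(e8[k])) for c, k in class_index.items()}


def dispersion_energy(
    structure: Structure,
    element_table: ElementTable,
    params: DispersionParams,
    breakdown: bool = False,
):
    """Total dispersion energy in kcal/mol.

    With ``breakdown=True`` returns ``(energy, per_pair)`` where
    ``per_pair`` maps each element-pair class to its energy contribution.
    """
    sums = pair_component_sums(structure, element_table, params)
    per_pair = {
        c: params.s6 * e6 + params.s8_for(*c) * e8 for c, (e6, e8) in sums.items()
    }
    total = float(sum(per_pair.values()))
    if breakdown:
        return total, per_pair
    return total


def dispersion_components(
    structure: Structure, element_table: ElementTable, params: DispersionParams
) -> tuple[float, float]:
    """(E6_unit, E8_unit): the two pair sums at s6 = s8 = 1.

    ``dispersion_energy`` with no pair overrides equals
    ``s6 * E6_unit + s8 * E8_unit`` exactly at fixed damping.
    """
    sums = pair_component_sums(structure, element_table, params)
    e6 = sum(v[0] for v in sums.values())
    e8 = sum(v[1] for v in sums.values())
    return float(e6), float(e8)


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------


def load_element_table(path: str | Path) -> ElementTable:
    """Load an element table from its YAML schema.

    Schema::

        version: 1
        units: {radius: angstrom|bohr, r0: angstrom|bohr,
                c6: kcal_mol_A6|au, sqrt_q: angstrom2|bohr2}
        elements:
          H: {covalent_radius: 0.32, sqrt_q: 2.0073}
        pairs:
          H-O: {r0: 1.80, c6_reference: [[CN_H, CN_O, C6], ...]}

    Pair keys are ``A-B`` with reference CN columns in key order.
    """
    doc = yaml.safe_load(Path(path).read_text())
    return element_table_from_dict(doc, source=str(path))


def element_table_from_dict(doc: dict, source: str = "<dict>") -> ElementTable:
    if not isinstance(doc, dict) or "elements" not in doc or "pairs" not in doc:
        raise ParseError(f"{source}: not an element-table document")
    units = doc.get("units", {})
    rfac = BOHR_TO_ANGSTROM if units.get("radius", "angstrom") == "bohr" else 1.0
    r0fac = BOHR_TO_ANGSTROM if units.get("r0", "angstrom") == "bohr" else 1.0
    c6fac = AU_C6_TO_KCAL_A6 if units.get("c6", "kcal_mol_A6") == "au" else 1.0
    sqfac = BOHR_TO_ANGSTROM**2 if units.get("sqrt_q", "angstrom2") == "bohr2" else 1.0
    cov, sq = {}, {}
    for el, rec in doc["elements"].items():
        cov[el] = float(rec["covalent_radius"]) * rfac
        sq[el] = float(rec["sqrt_q"]) * sqfac
    r0_pairs, c6_reference = {}, {}
    for key, rec in doc["pairs"].items():
        a, b = key.split("-")
        pts = np.atleast_2d(np.asarray(rec["c6_reference"], dtype=float)).copy()
        pts[:, 2] *= c6fac
        if (a, b) != _pair_key(a, b):
            pts = pts[:, [1, 0, 2]]
        r0_pairs[_pair_key(a, b)] = float(rec["r0"]) * r0fac
        c6_reference[_pair_key(a, b)] = pts
    return ElementTable(
        covalent_radii=cov, sqrt_q=sq, r0_pairs=r0_pairs, c6_reference=c6_reference
    )


def save_element_table(path: str | Path, table: ElementTable) -> None:
    """Write a table in the YAML schema (kcal/Angstrom units)."""
    doc: dict = {
        "version": 1,
        "units": {
            "radius": "angstrom", "r0": "angstrom",
            "c6": "kcal_mol_A6", "sqrt_q": "angstrom2",
        },
        "elements": {
            el: {
                "covalent_radius": float(table.covalent_radii[el]),
                "sqrt_q": float(table.sqrt_q[el]),
            }
            for el in sorted(table.covalent_radii)
        },
        "pairs": {},
    }
    for (a, b), pts in sorted(table.c6_reference.items()):
        doc["pairs"][f"{a}-{b}"] = {
            "r0": float(table.r0_pairs[(a, b)]),
            "c6_reference": [[float(x) for x in row] for row in pts],
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_element_table() -> ElementTable:
    """The packaged H/O/Mg/Cl table (approximate public D3-style data).

    Convenience data for exploratory use; fits and tests should supply
    their own tables.
    """
    ref = resources.files("solvkit") / "data" / "d3_minimal.yaml"
    return element_table_from_dict(yaml.safe_load(ref.read_text()), source=str(ref))
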