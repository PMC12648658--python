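"""Structures, trajectories, fit records and their file formats.

This module owns all unit conventions: after loading, energies are
kcal/mol, lengths Angstrom, times fs, temperatures K.  Geometry files are
XYZ / extended-XYZ (the key=value comment-line dialect with
``Lattice="ax ay az bx ..."`` and a ``Properties`` column descriptor);
fit datasets and element tables are YAML documents so that fragment maps
stay adjacent to their energies; scalar time series are delimited text
with ``#``-prefixed header metadata.
"""

from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError
from .units import energy_to_kcal

# fmt: off
ELEMENT_SYMBOLS = frozenset("""
H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni
Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I
Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt
Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu
""".split())
# fmt: on


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Structure:
    """Atoms with Cartesian coordinates and an optional periodic cell.

    Parameters
    ----------
    symbols : element symbols, one per atom.
    coords : (N, 3) Cartesian positions, Angstrom.
    cell : optional (3, 3) lattice vectors as rows, Angstrom.
    pbc : per-axis periodicity flags.
    tags : optional per-atom fragment labels.
    """

    symbols: list[str]
    coords: np.ndarray
    cell: np.ndarray | None = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.symbols = [str(s) for s in self.symbols]
        if len(self.symbols) != len(self.coords):
            raise ValidationError(
                f"{len(self.symbols)} symbols but {len(self.coords)} coordinates"
            )
        for s in self.symbols:
            if s not in ELEMENT_SYMBOLS:
                raise ValidationError(f"unknown element symbol {s!r}")
        self.pbc = tuple(bool(p) for p in self.pbc)  # type: ignore[assignment]
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if any(self.pbc):
            if self.cell is None:
                raise ValidationError("pbc set but no cell given")
            if abs(np.linalg.det(self.cell)) < 1e-10:
                raise ValidationError("singular cell with periodic boundaries")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def select(self, indices: Sequence[int]) -> "Structure":
        """Sub-structure with the given atom indices (cluster, no pbc)."""
        idx = list(indices)
        return Structure(
            symbols=[self.symbols[i] for i in idx],
            coords=self.coords[idx],
            cell=None,
            pbc=(False, False, False),
            tags=[self.tags[i] for i in idx] if self.tags else None,
        )


@dataclass
class TrajectorySeries:
    """Ordered frames with uniform timestamps and optional velocities.

    ``times`` are fs and must be uniformly spaced (relative tolerance
    1e-9); ``velocities`` is None or an (n_frames, N, 3) array in
    Angstrom/fs.
    """

    frames: list[Structure]
    times: np.ndarray
    velocities: np.ndarray | None = None
    temperature: float = 300.0
    pressure: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValidationError("times and frames length mismatch")
        if len(self.frames) > 1:
            n0 = self.frames[0].n_atoms
            for k, f in enumerate(self.frames):
                if f.n_atoms != n0:
                    raise ValidationError(
                        f"atom count changes at frame {k}: {f.n_atoms} != {n0}"
                    )
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValidationError("times must be strictly increasing")
            if np.max(np.abs(dts - dts[0])) > 1e-9 * max(abs(dts[0]), 1e-30):
                raise ValidationError("non-uniform time step")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            expected = (len(self.frames), self.frames[0].n_atoms, 3)
            if self.velocities.shape != expected:
                raise ValidationError(
                    f"velocities shape {self.velocities.shape} != {expected}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        """Time step in fs (0 for a single-frame series)."""
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def positions(self) -> np.ndarray:
        """(n_frames, N, 3) position array."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class FitRecord:
    """One configuration of a dispersion-fitting dataset.

    All energies kcal/mol.  ``fragments`` is a partition of atom indices
    (e.g. the ion and each water molecule); ``one_body_correction`` holds
    externally computed monomer-deformation energy to be subtracted from
    the reference interaction energy (one-body exclusion), defaulting to
    zero.  ``components`` may carry precomputed unit dispersion sums
    ``{"total": (E6, E8), "fragments": [(E6, E8), ...]}`` for linear
    fitting without a geometry engine.
    """

    structure: Structure
    fragments: list[list[int]]
    e_base_total: float
    e_base_fragments: list[float]
    e_ref_interaction: float
    one_body_correction: float = 0.0
    n_molecules: int = 1
    components: dict | None = None

    def __post_init__(self) -> None:
        n = self.structure.n_atoms
        seen = sorted(i for frag in self.fragments for i in frag)
        if seen != list(range(n)):
            raise ValidationError(
                "fragments must partition the atom indices exactly once"
            )
        if len(self.e_base_fragments) != len(self.fragments):
            raise ValidationError("one base energy required per fragment")
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")


# ---------------------------------------------------------------------------
# XYZ / extended-XYZ
# ---------------------------------------------------------------------------

_VEL_KEYS = {"vel", "velo", "velocities"}


def _parse_comment_line(comment: str) -> dict:
    """Parse ``key=value`` pairs of an extended-xyz comment line."""
    try:
        tokens = shlex.split(comment)
    except ValueError:
        return {}
    out: dict[str, str] = {}
    for tok in tokens:
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    parts = spec.split(":")
    if len(parts) % 3:
        raise ParseError(f"malformed Properties string {spec!r}")
    out = []
    for i in range(0, len(parts), 3):
        out.append((parts[i], parts[i + 1], int(parts[i + 2])))
    return out


def read_structures(path: str | Path, format: str = "auto") -> list[Structure]:
    """Read all frames of an XYZ / extended-XYZ file.

    Returns one :class:`Structure` per frame; an empty file yields an
    empty list.  When the comment line carries a ``Lattice`` field the
    cell is populated and all pbc flags set true.  Per-atom velocity
    columns (``vel:R:3`` in the Properties string) are attached to each
    structure as a ``velocities`` attribute (used by
    :func:`read_trajectory`).
    """
    if format not in ("auto", "xyz", "extended-xyz", "extxyz"):
        raise ValidationError(f"unsupported format {format!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    structures: list[Structure] = []
    i = 0
    nlines = len(lines)
    while i < nlines:
        if not lines[i].strip():  # trailing blank lines
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 + natoms >= nlines + 1 or i + 1 >= nlines:
            raise ParseError(f"{path}:{i + 1}: truncated frame header")
        comment = lines[i + 1]
        meta = _parse_comment_line(comment)
        cell = None
        pbc = (False, False, False)
        if "Lattice" in meta:
            vals = [float(x) for x in meta["Lattice"].split()]
            if len(vals) != 9:
                raise ParseError(f"{path}:{i + 2}: Lattice needs 9 numbers")
            cell = np.array(vals, dtype=float).reshape(3, 3)
            pbc = (True, True, True)
        props = None
        if "Properties" in meta:
            props = _parse_properties(meta["Properties"])
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) < natoms:
            raise ParseError(
                f"{path}:{i + 1}: header claims {natoms} atoms, "
                f"only {len(body)} lines follow"
            )
        symbols: list[str] = []
        coords = np.empty((natoms, 3))
        vels = None
        # column layout: default symbol x y z; with Properties, walk fields
        for a, line in enumerate(body):
            cols = line.split()
            lineno = i + 3 + a
            try:
                if props is None:
                    if len(cols) < 4:
                        raise ParseError(
                            f"{path}:{lineno}: expected 'symbol x y z', got {line!r}"
                        )
                    symbols.append(cols[0])
                    coords[a] = [float(c) for c in cols[1:4]]
                else:
                    pos = 0
                    for name, kind, width in props:
                        fields = cols[pos : pos + width]
                        if len(fields) < width:
                            raise ParseError(
                                f"{path}:{lineno}: inconsistent column count"
                            )
                        lname = name.lower()
                        if lname in ("species", "symbols") and kind == "S":
                            symbols.append(fields[0])
                        elif lname == "pos":
                            coords[a] = [float(c) for c in fields]
                        elif lname in _VEL_KEYS:
                            if vels is None:
                                vels = np.empty((natoms, 3))
                            vels[a] = [float(c) for c in fields]
                        pos += width
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
        try:
            s = Structure(symbols=symbols, coords=coords, cell=cell, pbc=pbc)
        except ValidationError as exc:
            raise ParseError(f"{path}: frame starting line {i + 1}: {exc}") from None
        if vels is not None:
            s.velocities = vels  # type: ignore[attr-defined]
        structures.append(s)
        i += 2 + natoms
    return structures


def write_structures(
    path: str | Path,
    structures: Iterable[Structure],
    velocities: np.ndarray | None = None,
    comment_extra: str = "",
) -> None:
    """Write frames as extended-XYZ (plain XYZ when no cell/velocities)."""
    path = Path(path)
    structures = list(structures)
    with path.open("w") as fh:
        for k, s in enumerate(structures):
            fh.write(f"{s.n_atoms}\n")
            fields = []
            if s.cell is not None:
                flat = " ".join(f"{x:.10f}" for x in s.cell.ravel())
                fields.append(f'Lattice="{flat}"')
            props = "species:S:1:pos:R:3"
            vel = velocities[k] if velocities is not None else None
            if vel is not None:
                props += ":vel:R:3"
            fields.append(f"Properties={props}")
            if comment_extra:
                fields.append(comment_extra)
            fh.write(" ".join(fields) + "\n")
            for a in range(s.n_atoms):
                row = f"{s.symbols[a]:2s} " + " ".join(
                    f"{x: .10f}" for x in s.coords[a]
                )
                if vel is not None:
                    row += " " + " ".join(f"{x: .10e}" for x in vel[a])
                fh.write(row + "\n")


def read_trajectory(
    path: str | Path,
    dt_fs: float,
    temperature_K: float = 300.0,
    pressure_atm: float | None = None,
) -> TrajectorySeries:
    """Read an XYZ/extended-XYZ file as a trajectory.

    Times are assigned as ``frame_index * dt_fs``; velocity columns, when
    present in every frame, are attached to the series.
    """
    if dt_fs <= 0:
        raise ValidationError("dt_fs must be positive")
    frames = read_structures(path)
    if not frames:
        raise ParseError(f"{path}: no frames")
    n0 = frames[0].n_atoms
    for k, f in enumerate(frames):
        if f.n_atoms != n0:
            raise ValidationError(f"atom count changes at frame {k}")
    vels = [getattr(f, "velocities", None) for f in frames]
    has_vel = [v is not None for v in vels]
    if any(has_vel) and not all(has_vel):
        raise ValidationError("velocities present in some frames but not all")
    velocities = np.stack(vels) if all(has_vel) and frames else None
    times = dt_fs * np.arange(len(frames), dtype=float)
    return TrajectorySeries(
        frames=frames,
        times=times,
        velocities=velocities,
        temperature=temperature_K,
        pressure=pressure_atm,
    )


# ---------------------------------------------------------------------------
# Fit datasets (YAML)
# ---------------------------------------------------------------------------


def load_fit_dataset(path: str | Path) -> list[FitRecord]:
    """Load a YAML fit dataset; energies converted to kcal/mol on load.

    The document schema::

        version: 1
        energy_unit: kcal/mol | hartree | eV | kJ/mol
        records:
          - symbols: [Mg, O, H, H, ...]
            coords: [[x, y, z], ...]          # Angstrom
            cell: [[...], [...], [...]]       # optional
            fragments: [[0], [1, 2, 3], ...]  # partition of atom indices
            e_base_total: float               # dispersion-free total energy
            e_base_fragments: [float, ...]
            e_ref_interaction: float          # reference interaction energy
            one_body_correction: float        # optional, default 0
            n_molecules: int
            components:                       # optional precomputed unit sums
              total: [E6_unit, E8_unit]
              fragments: [[E6, E8], ...]
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "records" not in doc:
        raise ParseError(f"{path}: not a fit-dataset document")
    unit = str(doc.get("energy_unit", "kcal/mol"))
    records: list[FitRecord] = []
    for k, rec in enumerate(doc["records"]):
        if "e_ref_interaction" not in rec or rec["e_ref_interaction"] is None:
            raise ParseError(f"{path}: record {k}: missing e_ref_interaction")
        cell = rec.get("cell")
        structure = Structure(
            symbols=rec["symbols"],
            coords=np.asarray(rec["coords"], dtype=float),
            cell=np.asarray(cell, dtype=float) if cell is not None else None,
            pbc=(True, True, True) if cell is not None else (False, False, False),
        )
        try:
            record = FitRecord(
                structure=structure,
                fragments=[list(f) for f in rec["fragments"]],
                e_base_total=energy_to_kcal(float(rec["e_base_total"]), unit),
                e_base_fragments=[
                    energy_to_kcal(float(x), unit) for x in rec["e_base_fragments"]
                ],
                e_ref_interaction=energy_to_kcal(
                    float(rec["e_ref_interaction"]), unit
                ),
                one_body_correction=energy_to_kcal(
                    float(rec.get("one_body_correction", 0.0)), unit
                ),
                n_molecules=int(rec.get("n_molecules", 1)),
                components=_load_components(rec.get("components"), unit),
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: record {k}: {exc}") from None
        records.append(record)
    return records


def _load_components(comp: dict | None, unit: str) -> dict | None:
    if comp is None:
        return None
    conv = energy_to_kcal
    return {
        "total": tuple(conv(float(x), unit) for x in comp["total"]),
        "fragments": [
            tuple(conv(float(x), unit) for x in frag) for frag in comp["fragments"]
        ],
    }


def save_fit_dataset(path: str | Path, records: Sequence[FitRecord]) -> None:
    """Write records as a YAML fit dataset (kcal/mol)."""
    doc: dict = {"version": 1, "energy_unit": "kcal/mol", "records": []}
    for r in records:
        rec = {
            "symbols": list(r.structure.symbols),
            "coords": [[float(x) for x in row] for row in r.structure.coords],
            "fragments": [list(map(int, f)) for f in r.fragments],
            "e_base_total": float(r.e_base_total),
            "e_base_fragments": [float(x) for x in r.e_base_fragments],
            "e_ref_interaction": float(r.e_ref_interaction),
            "one_body_correction": float(r.one_body_correction),
            "n_molecules": int(r.n_molecules),
        }
        if r.structure.cell is not None:
            rec["cell"] = [[float(x) for x in row] for row in r.structure.cell]
        if r.components is not None:
            rec["components"] = {
                "total": [float(x) for x in r.components["total"]],
                "fragments": [
                    [float(x) for x in frag] for frag in r.components["fragments"]
                ],
            }
        doc["records"].append(rec)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Scalar time series (delimited text)
# ---------------------------------------------------------------------------


def write_timeseries(
    path: str | Path, df: pd.DataFrame, metadata: dict | None = None
) -> None:
    """Write a DataFrame as CSV with ``# key: value`` metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_timeseries(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a delimited-text time series; returns (frame, metadata).

    Column headers are required; ``#``-prefixed ``key: value`` lines
    before the header become metadata.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                m = re.match(r"#\s*([^:]+):\s*(.*)", line)
                if m:
                    meta[m.group(1).strip()] = m.group(2).strip()
            else:
                break
    df = pd.read_csv(path, skiprows=skip)
    if df.columns.str.match(r"^Unnamed|^\d+\.?\d*$").any():
        raise ParseError(f"{path}: column headers required")
    return df, meta
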