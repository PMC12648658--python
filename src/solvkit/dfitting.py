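"""Fit dispersion scaling factors against reference interaction energies.

The interaction energy of a configuration is the total energy minus the
sum of frozen-geometry fragment energies.  The model value is

    dE_int = (E_base_total + E_disp(total)) - sum_f (E_base_f + E_disp(f))

and its deviation from the reference is taken after one-body exclusion:
an externally supplied monomer-deformation correction is subtracted from
the reference interaction energy, so only intermolecular terms drive the
fit.  The objective is the mean absolute error normalized per molecule
(each record's absolute deviation divided by its own molecule count,
then averaged), minimized by a coarse grid scan followed by
derivative-free local refinement.

Two evaluation modes are supported.  In ``engine`` mode dispersion
energies come from the geometry engine; when all free parameters are
linear (s6, s8, per-pair s8) the engine's unit pair sums are precomputed
once per record, making the two modes numerically identical.  In
``components`` mode each record carries precomputed (E6_unit, E8_unit)
for the total system and every fragment, and no geometry is needed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core_io import FitRecord
from .dispersion import (
    DispersionParams,
    ElementTable,
    _pair_key,
    dispersion_energy,
    pair_component_sums,
)
from .errors import DegenerateFitError, ValidationError

GRID_POINTS_DEFAULT = 41
_FLAT_TOL = 1e-12


@dataclass
class FitReport:
    """Result of a dispersion-parameter fit."""

    optimized_params: DispersionParams
    mae_per_mol: float
    rmse_per_mol: float
    per_record_deviation: list[float]
    objective_trace: list[tuple[dict, float]]
    normalization: str = "per-molecule"
    mode: str = "engine"
    free_params: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        p = self.optimized_params
        return {
            "normalization": self.normalization,
            "mode": self.mode,
            "free_params": list(self.free_params),
            "optimized_params": {
                "s6": p.s6, "s8": p.s8, "sr6": p.sr6,
                "alpha6": p.alpha6, "alpha8": p.alpha8,
                "pair_s8_overrides": {
                    f"{a}-{b}": v for (a, b), v in p.pair_s8_overrides.items()
                },
            },
            "mae_per_mol": self.mae_per_mol,
            "rmse_per_mol": self.rmse_per_mol,
            "per_record_deviation": list(self.per_record_deviation),
            "objective_trace": [
                {"params": dict(pp), "objective": v} for pp, v in self.objective_trace
            ],
        }


# ---------------------------------------------------------------------------
# Deviations and objective
# ---------------------------------------------------------------------------


def interaction_deviation(
    record: FitRecord, element_table: ElementTable, params: DispersionParams
) -> float:
    """Model-minus-reference interaction energy of one record, kcal/mol.

    The reference is ``e_ref_interaction - one_body_correction`` (one-body
    exclusion; the correction is supplied per record, never computed here,
    and defaults to zero).
    """
    e_tot = dispersion_energy(record.structure, element_table, params)
    de_model = record.e_base_total + e_tot
    for frag, e_base in zip(record.fragments, record.e_base_fragments):
        sub = record.structure.select(frag)
        de_model -= e_base + dispersion_energy(sub, element_table, params)
    return de_model - (record.e_ref_interaction - record.one_body_correction)


def mae_per_molecule(deviations, n_molecules_list) -> float:
    """Mean over records of |deviation| / n_molecules."""
    dev = np.asarray(deviations, dtype=float)
    n = np.asarray(n_molecules_list, dtype=float)
    if dev.shape != n.shape:
        raise ValidationError("deviations and molecule counts differ in length")
    if np.any(n < 1):
        raise ValidationError("n_molecules must be >= 1 for every record")
    return float(np.mean(np.abs(dev) / n))


def _rmse_per_molecule(deviations, n_molecules_list) -> float:
    dev = np.asarray(deviations, dtype=float)
    n = np.asarray(n_molecules_list, dtype=float)
    return float(np.sqrt(np.mean((dev / n) ** 2)))


# ---------------------------------------------------------------------------
# Linear precomputation
# ---------------------------------------------------------------------------


def _precompute_pair_sums(records, table, params):
    """Per-record pair-class unit sums for total and fragments."""
    out = []
    for rec in records:
        total = pair_component_sums(rec.structure, table, params)
        frags = [
            pair_component_sums(rec.structure.select(f), table, params)
            for f in rec.fragments
        ]
        out.append((total, frags))
    return out


def _net_sums(total, frags):
    """total-minus-fragments unit sums per pair class."""
    net: dict[tuple, np.ndarray] = {}
    for key, (e6, e8) in total.items():
        net[key] = np.array([e6, e8])
    for fr in frags:
        for key, (e6, e8) in fr.items():
            net[key] = net.get(key, np.zeros(2)) - np.array([e6, e8])
    return net


class _Objective:
    """MAE/mol as a function of the free-parameter vector."""

    def __init__(self, records, table, free, base, mode):
        self.records = records
        self.table = table
        self.free = free
        self.base = base
        self.mode = mode
        self.nmol = [r.n_molecules for r in records]
        self.sr6_free = "sr6" in free
        self._linear = None
        if mode == "components":
            self._setup_components()
        elif not self.sr6_free:
            self._setup_linear(_precompute_pair_sums(records, table, base))

    def _setup_components(self):
        rows = []
        for rec in self.records:
            if rec.components is None:
                raise ValidationError(
                    "components mode requires precomputed (E6, E8) on every record"
                )
            net = np.array(rec.components["total"], dtype=float)
            for frag in rec.components["fragments"]:
                net = net - np.array(frag, dtype=float)
            rows.append({None: net})  # single class: the global (s6, s8) channel
        self._linear = rows

    def _setup_linear(self, pair_sums):
        self._linear = [_net_sums(tot, frags) for tot, frags in pair_sums]

    def params_from_vector(self, x) -> DispersionParams:
        kw = {}
        overrides = dict(self.base.pair_s8_overrides)
        for name, val in zip(self.free, x):
            if name.startswith("pair_s8:"):
                a, b = name.split(":", 1)[1].split("-")
                overrides[_pair_key(a, b)] = float(val)
            else:
                kw[name] = float(val)
        kw["pair_s8_overrides"] = overrides
        return self.base.replace(**kw)

    def deviations(self, x) -> np.ndarray:
        params = self.params_from_vector(x)
        devs = np.empty(len(self.records))
        if self._linear is not None:
            for m, (rec, net) in enumerate(zip(self.records, self._linear)):
                e = 0.0
                for key, (e6, e8) in net.items():
                    if key is None:
                        e += params.s6 * e6 + params.s8 * e8
                    else:
                        e += params.s6 * e6 + params.s8_for(*key) * e8
                de_model = (
                    rec.e_base_total + e - sum(rec.e_base_fragments)
                )
                devs[m] = de_model - (rec.e_ref_interaction - rec.one_body_correction)
        else:
            for m, rec in enumerate(self.records):
                devs[m] = interaction_deviation(rec, self.table, params)
        return devs

    def __call__(self, x) -> float:
        return mae_per_molecule(self.deviations(x), self.nmol)


# ---------------------------------------------------------------------------
# Fit driver
# ---------------------------------------------------------------------------


def fit_parameters(
    records: list[FitRecord],
    element_table: ElementTable | None,
    free_params: list[str],
    bounds: dict[str, tuple[float, float]] | list[tuple[float, float]],
    mode: str = "engine",
    base_params: DispersionParams | None = None,
    grid_points: int = GRID_POINTS_DEFAULT,
) -> FitReport:
    """Minimize MAE/mol over the requested scaling factors.

    *free_params* may contain ``s6``, ``s8``, ``sr6`` and per-pair
    overrides written ``pair_s8:A-B``.  *bounds* is a mapping from
    parameter name to (lo, hi), or a list aligned with *free_params*.
    The search is a coarse grid scan (*grid_points* per axis, ties broken
    toward smaller parameter values) followed by Nelder-Mead refinement
    from the grid optimum; the full evaluation trace is kept in the
    report.  Deterministic given identical inputs.
    """
    if mode not in ("engine", "components"):
        raise ValidationError(f"unknown fit mode {mode!r}")
    if not records:
        raise ValidationError("no records to fit")
    free = list(free_params)
    if not free:
        raise ValidationError("no free parameters")
    for name in free:
        if not (name in ("s6", "s8", "sr6") or name.startswith("pair_s8:")):
            raise ValidationError(f"unknown free parameter {name!r}")
    if mode == "components":
        if "sr6" in free:
            warnings.warn(
                "sr6 enters the damping nonlinearly and cannot be fit from "
                "precomputed components; it is held fixed (use engine mode)",
                stacklevel=2,
            )
            free = [p for p in free if p != "sr6"]
            if not free:
                raise ValidationError("no fittable parameters left")
        if any(p.startswith("pair_s8:") for p in free):
            raise ValidationError(
                "per-pair s8 requires pair-resolved sums; use engine mode"
            )
    if mode == "engine" and element_table is None:
        raise ValidationError("engine mode requires an element table")

    if isinstance(bounds, dict):
        blist = [tuple(bounds[p]) for p in free]
    else:
        blist = [tuple(b) for b in bounds]
    if len(blist) != len(free):
        raise ValidationError("one bounds pair required per free parameter")
    for lo, hi in blist:
        if not lo < hi:
            raise ValidationError("bounds must satisfy lo < hi")

    base = base_params if base_params is not None else DispersionParams()
    obj = _Objective(records, element_table, free, base, mode)

    axes = [np.linspace(lo, hi, grid_points) for lo, hi in blist]
    trace: list[tuple[dict, float]] = []
    best_x, best_val = None, np.inf
    for combo in itertools.product(*axes):
        val = obj(np.array(combo))
        trace.append((dict(zip(free, map(float, combo))), val))
        if val < best_val - 0.0:  # strict '<': earlier (smaller) values win ties
            best_val, best_x = val, np.array(combo)

    # flatness check along each axis through the grid optimum
    for k, name in enumerate(free):
        vals = []
        x = best_x.copy()
        for v in axes[k]:
            x[k] = v
            vals.append(obj(x))
        if max(vals) - min(vals) <= _FLAT_TOL:
            raise DegenerateFitError(
                f"objective is flat in free parameter {name!r}"
            )

    res = minimize(
        obj,
        best_x,
        method="Nelder-Mead",
        bounds=blist,
        options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 4000},
    )
    x_opt, val_opt = (res.x, float(res.fun)) if res.fun <= best_val else (
        best_x, best_val
    )
    trace.append((dict(zip(free, map(float, x_opt))), float(val_opt)))

    params_opt = obj.params_from_vector(x_opt)
    devs = obj.deviations(x_opt)
    return FitReport(
        optimized_params=params_opt,
        mae_per_mol=float(mae_per_molecule(devs, obj.nmol)),
        rmse_per_mol=_rmse_per_molecule(devs, obj.nmol),
        per_record_deviation=[float(d) for d in devs],
        objective_trace=trace,
        normalization="per-molecule",
        mode=mode,
        free_params=free,
    )
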