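"""Seeded generators for every input class with planted ground truth.

Each generator is bit-deterministic under its arguments and seed, and
returns a machine-readable truth/metadata dictionary alongside the data
(optionally written as a YAML sidecar).  The fixtures exist to make
analytic checks possible, not to emulate any specific water model:

* ``gen_fit_dataset`` builds ion-water-like clusters whose reference
  interaction energies contain a dispersion part with known (planted)
  scaling factors on top of a smooth non-dispersive pair repulsion, so
  the dispersion parameters are exactly identifiable;
* ``gen_langevin_traj`` samples free Langevin particles with the exact
  Gaussian propagator, so the diffusion constant is kB T/(m gamma);
* ``gen_harmonic_traj`` integrates independent harmonic oscillators
  analytically, so the velocity spectrum is a line at the set frequency;
* ``gen_lj_fluid_traj`` runs a small thermostatted Lennard-Jones fluid
  (structured-fluid smoke fixture, no planted truth);
* ``gen_water_box`` packs rigid gas-phase-geometry waters into a
  periodic box.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .core_io import Structure, TrajectorySeries
from .dispersion import (
    DispersionParams,
    ElementTable,
    dispersion_components,
    dispersion_energy,
)
from .errors import PackingError, StabilityError, ValidationError
from .units import A2_PER_FS_TO_1E9_M2_S, KB_AMU_A2_FS2_K
import scipy.constants as _sc

# rigid gas-phase water geometry used by the cluster/box builders
OH_BOND_A = 0.9572
HOH_ANGLE_DEG = 104.52


def _write_truth(truth: dict, truth_path) -> dict:
    if truth_path is not None:
        Path(truth_path).write_text(yaml.safe_dump(truth, sort_keys=False))
    return truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _water_template() -> np.ndarray:
    """O at origin, H's in the xz plane (rigid monomer, Angstrom)."""
    half = np.radians(HOH_ANGLE_DEG / 2.0)
    h1 = OH_BOND_A * np.array([np.sin(half), 0.0, np.cos(half)])
    h2 = OH_BOND_A * np.array([-np.sin(half), 0.0, np.cos(half)])
    return np.vstack([[0.0, 0.0, 0.0], h1, h2])


def toy_element_table(include_cl: bool = False) -> ElementTable:
    """Deterministic synthetic H/O/Mg(/Cl) table for planted-truth tests.

    Magnitudes are chosen so the C8 channel contributes a clearly
    identifiable fraction of a cluster's interaction energy; the numbers
    are synthetic and carry no relation to any published parameter set.
    """
    cov = {"H": 0.35, "O": 0.65, "Mg": 1.20}
    sq = {"H": 0.60, "O": 0.75, "Mg": 1.55}
    r0 = {
        ("H", "H"): 1.4, ("H", "O"): 1.6, ("O", "O"): 1.9,
        ("H", "Mg"): 2.0, ("Mg", "O"): 2.2, ("Mg", "Mg"): 2.8,
    }
    c6 = {
        ("H", "H"): [[0.0, 0.0, 30.0], [1.0, 1.0, 25.0]],
        ("H", "O"): [[0.0, 0.0, 60.0], [1.0, 2.0, 50.0]],
        ("O", "O"): [[0.0, 0.0, 120.0], [2.0, 2.0, 100.0]],
        ("H", "Mg"): [[0.0, 0.0, 220.0], [1.0, 0.0, 180.0]],
        ("Mg", "O"): [[0.0, 0.0, 500.0], [0.0, 2.0, 420.0]],
        ("Mg", "Mg"): [[0.0, 0.0, 2000.0]],
    }
    if include_cl:
        cov["Cl"] = 1.0
        sq["Cl"] = 1.2
        for el, r, c in [("H", 1.8, 110.0), ("O", 2.1, 200.0),
                         ("Mg", 2.6, 900.0), ("Cl", 2.9, 450.0)]:
            r0[("Cl", el)] = r
            c6[("Cl", el)] = [[0.0, 0.0, c]]
    return ElementTable(covalent_radii=cov, sqrt_q=sq, r0_pairs=r0, c6_reference=c6)


# ---------------------------------------------------------------------------
# Fit datasets with planted dispersion parameters
# ---------------------------------------------------------------------------


def _base_pair_energy(coords: np.ndarray, pairs) -> float:
    """Smooth non-dispersive repulsion A exp(-r/rho) over the given pairs."""
    a_rep, rho = 2000.0, 0.35
    e = 0.0
    for i, j in pairs:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e += a_rep * np.exp(-r / rho)
    return e


def gen_fit_dataset(
    n_records: int,
    element_table: ElementTable | None = None,
    planted_params: DispersionParams | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_waters: int = 6,
    shell_radii: tuple[float, float] = (1.95, 2.45),
    min_distance: float = 1.5,
    one_body_sigma: float = 0.0,
    with_components: bool = True,
    truth_path=None,
):
    """Random Mg-water clusters with dispersion planted in the reference.

    Each record's reference interaction energy is the base-potential
    interaction plus the dispersion interaction evaluated at
    *planted_params*, plus Gaussian noise of ``noise_sigma`` kcal/mol;
    refitting the planted parameters on a noiseless dataset therefore
    drives the objective to zero.  A nonzero ``one_body_sigma`` plants a
    per-record one-body term that is both added to the reference and
    recorded in ``one_body_correction`` (one-body exclusion leaves the
    deviations unchanged).  Returns ``(records, truth)``.
    """
    from .core_io import FitRecord

    table = element_table if element_table is not None else toy_element_table()
    params = planted_params if planted_params is not None else DispersionParams()
    rng = np.random.default_rng(seed)
    template = _water_template()
    records = []
    for _ in range(n_records):
        coords = [np.zeros((1, 3))]  # the ion at the origin
        fragments = [[0]]
        nxt = 1
        attempts = 0
        placed: list[np.ndarray] = [np.zeros((1, 3))]
        while len(placed) - 1 < n_waters:
            attempts += 1
            if attempts > 10_000:
                raise PackingError("could not pack cluster in 10^4 attempts")
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            r = rng.uniform(*shell_radii)
            mol = (template @ _random_rotation(rng).T) + u * r
            ok = True
            for other in placed:
                d = np.linalg.norm(mol[:, None, :] - other[None, :, :], axis=-1)
                if d.min() < min_distance:
                    ok = False
                    break
            if ok:
                placed.append(mol)
                coords.append(mol)
                fragments.append([nxt, nxt + 1, nxt + 2])
                nxt += 3
        xyz = np.vstack(coords)
        symbols = ["Mg"] + ["O", "H", "H"] * n_waters
        structure = Structure(symbols=symbols, coords=xyz)

        all_pairs = [(i, j) for i in range(len(xyz)) for j in range(i + 1, len(xyz))]
        intra = []
        for frag in fragments:
            intra += [(i, j) for i in frag for j in frag if i < j]
        e_base_total = _base_pair_energy(xyz, all_pairs)
        e_base_frags = [
            _base_pair_energy(xyz, [(i, j) for i in f for j in f if i < j])
            for f in fragments
        ]

        comp_total = dispersion_components(structure, table, params)
        comp_frags = [
            dispersion_components(structure.select(f), table, params)
            for f in fragments
        ]
        # full engine evaluation so pair-s8 overrides are honored too
        e_disp_net = dispersion_energy(structure, table, params)
        for f in fragments:
            e_disp_net -= dispersion_energy(structure.select(f), table, params)
        base_inter = e_base_total - sum(e_base_frags)
        obc = rng.normal(0.0, one_body_sigma) if one_body_sigma > 0 else 0.0
        noise = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        e_ref = base_inter + e_disp_net + obc + noise
        records.append(
            FitRecord(
                structure=structure,
                fragments=fragments,
                e_base_total=e_base_total,
                e_base_fragments=e_base_frags,
                e_ref_interaction=e_ref,
                one_body_correction=obc,
                n_molecules=n_waters + 1,
                components=(
                    {"total": comp_total, "fragments": comp_frags}
                    if with_components
                    else None
                ),
            )
        )
    truth = {
        "kind": "fit_dataset",
        "seed": int(seed),
        "n_records": int(n_records),
        "n_waters": int(n_waters),
        "noise_sigma": float(noise_sigma),
        "one_body_sigma": float(one_body_sigma),
        "planted": {
            "s6": params.s6, "s8": params.s8, "sr6": params.sr6,
            "pair_s8_overrides": {
                f"{a}-{b}": v for (a, b), v in params.pair_s8_overrides.items()
            },
        },
        "base_potential": "A*exp(-r/rho), A=2000 kcal/mol, rho=0.35 A",
    }
    return records, _write_truth(truth, truth_path)


# ---------------------------------------------------------------------------
# Langevin fixture with analytic diffusion
# ---------------------------------------------------------------------------


def gen_langevin_traj(
    n_particles: int,
    temperature: float,
    gamma_fs: float,
    mass_amu: float,
    dt_fs: float,
    n_steps: int,
    box: float | None = None,
    seed: int = 0,
    truth_path=None,
):
    """Free Langevin particles sampled with the exact Gaussian propagator.

    The analytic self-diffusion constant is D = kB T / (m gamma).
    Positions are stored unwrapped; when ``box`` is given it becomes the
    periodic cell (positions still unwrapped so displacement analysis is
    exact).  Returns ``(TrajectorySeries, truth)``.
    """
    if min(temperature, gamma_fs, mass_amu, dt_fs) <= 0:
        raise ValidationError("physical parameters must be positive")
    if dt_fs * gamma_fs >= 0.1:
        raise StabilityError(
            f"dt*gamma = {dt_fs * gamma_fs:.3g} >= 0.1; reduce the time step"
        )
    rng = np.random.default_rng(seed)
    vth2 = KB_AMU_A2_FS2_K * temperature / mass_amu
    c1 = np.exp(-gamma_fs * dt_fs)
    var_v = vth2 * (1.0 - c1**2)
    var_x = vth2 / gamma_fs**2 * (
        2.0 * gamma_fs * dt_fs - 3.0 + 4.0 * c1 - c1**2
    )
    cov_xv = vth2 / gamma_fs * (1.0 - c1) ** 2
    a = np.sqrt(var_v)
    b = cov_xv / a
    c = np.sqrt(max(var_x - b**2, 0.0))

    span = box if box is not None else 50.0
    x = rng.uniform(0.0, span, size=(n_particles, 3))
    v = rng.normal(0.0, np.sqrt(vth2), size=(n_particles, 3))
    pos = np.empty((n_steps + 1, n_particles, 3))
    vel = np.empty_like(pos)
    pos[0], vel[0] = x, v
    for k in range(n_steps):
        xi1 = rng.standard_normal((n_particles, 3))
        xi2 = rng.standard_normal((n_particles, 3))
        x = x + (1.0 - c1) / gamma_fs * v + b * xi1 + c * xi2
        v = c1 * v + a * xi1
        pos[k + 1], vel[k + 1] = x, v

    cell = np.eye(3) * box if box is not None else None
    pbc = (True, True, True) if box is not None else (False, False, False)
    frames = [
        Structure(symbols=["Ar"] * n_particles, coords=pos[k], cell=cell, pbc=pbc)
        for k in range(n_steps + 1)
    ]
    traj = TrajectorySeries(
        frames=frames,
        times=dt_fs * np.arange(n_steps + 1),
        velocities=vel,
        temperature=temperature,
    )
    d_a2fs = KB_AMU_A2_FS2_K * temperature / (mass_amu * gamma_fs)
    truth = {
        "kind": "langevin",
        "seed": int(seed),
        "D_A2_per_fs": float(d_a2fs),
        "D_1e9_m2_s": float(d_a2fs * A2_PER_FS_TO_1E9_M2_S),
        "temperature_K": float(temperature),
        "gamma_per_fs": float(gamma_fs),
        "mass_amu": float(mass_amu),
    }
    return traj, _write_truth(truth, truth_path)


# ---------------------------------------------------------------------------
# Harmonic-oscillator fixture for the vDOS
# ---------------------------------------------------------------------------


def gen_harmonic_traj(
    omega_cm1: float,
    temperature: float,
    dt_fs: float,
    n_steps: int,
    seed: int = 0,
    n_oscillators: int = 32,
    mass_amu: float = 1.0,
    truth_path=None,
):
    """Independent 1-D harmonic oscillators, integrated analytically.

    x(t) = x0 cos(wt) + (v0/w) sin(wt) with thermally sampled initial
    conditions -- no discretization drift, so the velocity spectrum is
    concentrated exactly at ``omega_cm1``.  Requires the run to cover at
    least 20 periods.  Returns ``(TrajectorySeries, truth)``.
    """
    if omega_cm1 <= 0 or dt_fs <= 0:
        raise ValidationError("frequency and time step must be positive")
    w_radfs = 2.0 * np.pi * _sc.c * 100.0 * 1e-15 * omega_cm1
    period_fs = 2.0 * np.pi / w_radfs
    if n_steps * dt_fs < 20.0 * period_fs:
        raise ValidationError(
            f"trajectory spans {n_steps * dt_fs:.1f} fs < 20 periods "
            f"({20 * period_fs:.1f} fs); frequency unresolvable"
        )
    rng = np.random.default_rng(seed)
    vth = np.sqrt(KB_AMU_A2_FS2_K * temperature / mass_amu)
    x0 = rng.normal(0.0, vth / w_radfs, size=n_oscillators)
    v0 = rng.normal(0.0, vth, size=n_oscillators)
    t = dt_fs * np.arange(n_steps + 1)
    x = x0[None, :] * np.cos(w_radfs * t)[:, None] + (v0 / w_radfs)[None, :] * np.sin(
        w_radfs * t
    )[:, None]
    v = -x0[None, :] * w_radfs * np.sin(w_radfs * t)[:, None] + v0[None, :] * np.cos(
        w_radfs * t
    )[:, None]
    anchors = 10.0 * np.arange(n_oscillators)
    pos = np.zeros((n_steps + 1, n_oscillators, 3))
    pos[:, :, 0] = anchors[None, :] + x
    vel = np.zeros_like(pos)
    vel[:, :, 0] = v
    frames = [
        Structure(symbols=["H"] * n_oscillators, coords=pos[k])
        for k in range(n_steps + 1)
    ]
    traj = TrajectorySeries(
        frames=frames, times=t, velocities=vel, temperature=temperature
    )
    truth = {
        "kind": "harmonic",
        "seed": int(seed),
        "omega_cm1": float(omega_cm1),
        "velocity_variance": float(np.var(v0) + 0.0),
        "temperature_K": float(temperature),
    }
    return traj, _write_truth(truth, truth_path)


# ---------------------------------------------------------------------------
# Ideal-gas fixture (flat RDF, zero-mean tetrahedral order)
# ---------------------------------------------------------------------------


def gen_ideal_gas_traj(
    n_particles: int,
    box_length: float,
    n_frames: int,
    seed: int = 0,
    symbol: str = "O",
    dt_fs: float = 1.0,
    truth_path=None,
):
    """Uncorrelated uniform positions in a periodic cubic box.

    Every frame is an independent uniform draw, so g(r) = 1 for all r
    (up to counting noise) and the tetrahedral order parameter averages
    to zero.  Returns ``(TrajectorySeries, truth)``.
    """
    if n_particles < 1 or n_frames < 1 or box_length <= 0:
        raise ValidationError("need positive particle count, frames and box")
    rng = np.random.default_rng(seed)
    cell = np.eye(3) * box_length
    frames = [
        Structure(
            symbols=[symbol] * n_particles,
            coords=rng.uniform(0.0, box_length, size=(n_particles, 3)),
            cell=cell,
            pbc=(True, True, True),
        )
        for _ in range(n_frames)
    ]
    traj = TrajectorySeries(frames=frames, times=dt_fs * np.arange(n_frames))
    truth = {
        "kind": "ideal_gas",
        "seed": int(seed),
        "g_of_r": 1.0,
        "n_particles": int(n_particles),
        "box_length_A": float(box_length),
    }
    return traj, _write_truth(truth, truth_path)


# ---------------------------------------------------------------------------
# Lennard-Jones fluid smoke fixture
# ---------------------------------------------------------------------------


def gen_lj_fluid_traj(
    n: int,
    density: float,
    temperature: float,
    dt: float = 0.005,
    n_steps: int = 1500,
    n_equil: int = 500,
    sample_every: int = 5,
    seed: int = 0,
    sigma_a: float = 3.4,
    truth_path=None,
):
    """Thermostatted Lennard-Jones fluid in reduced units.

    Velocity-Verlet with periodic velocity rescaling toward the reduced
    temperature; positions are scaled by ``sigma_a`` Angstrom on output
    and the reduced time unit is mapped to 1 fs.  A structured-fluid
    smoke fixture: g(r) shows a first-shell peak but no planted truth.
    Returns ``(TrajectorySeries, truth)``.
    """
    if density <= 0 or temperature <= 0:
        raise ValidationError("density and temperature must be positive")
    rng = np.random.default_rng(seed)
    ncell = int(np.ceil(n ** (1.0 / 3.0)))
    box = (n / density) ** (1.0 / 3.0)
    grid = np.array(
        [(i, j, k) for i in range(ncell) for j in range(ncell) for k in range(ncell)],
        dtype=float,
    )[:n]
    x = (grid + 0.5) * box / ncell
    v = rng.normal(0.0, np.sqrt(temperature), size=(n, 3))
    v -= v.mean(axis=0)
    rc2 = 2.5**2

    def forces(x):
        d = x[None, :, :] - x[:, None, :]
        d -= box * np.round(d / box)
        r2 = (d**2).sum(axis=-1)
        np.fill_diagonal(r2, np.inf)
        if np.min(r2) < 0.4:
            raise StabilityError(
                f"overlap blow-up: min r = {np.sqrt(np.min(r2)):.3f} sigma"
            )
        inv6 = np.where(r2 < rc2, (1.0 / r2) ** 3, 0.0)
        with np.errstate(invalid="ignore"):
            fmag = np.where(r2 < rc2, 24.0 * (2.0 * inv6**2 - inv6) / r2, 0.0)
        pe = 4.0 * (inv6**2 - inv6).sum() / 2.0
        f = (fmag[:, :, None] * d).sum(axis=1)
        return -f, pe

    f, _ = forces(x)
    frames_pos, frames_vel = [], []
    for step in range(n_equil + n_steps):
        v += 0.5 * dt * f
        x = (x + dt * v) % box
        f, pe = forces(x)
        v += 0.5 * dt * f
        if step % 20 == 0:
            ke = 0.5 * (v**2).sum()
            t_inst = 2.0 * ke / (3.0 * n)
            v *= np.sqrt(temperature / t_inst)
        if step >= n_equil and (step - n_equil) % sample_every == 0:
            frames_pos.append(x.copy())
            frames_vel.append(v.copy())
    cell = np.eye(3) * box * sigma_a
    frames = [
        Structure(symbols=["Ar"] * n, coords=p * sigma_a, cell=cell, pbc=(True,) * 3)
        for p in frames_pos
    ]
    traj = TrajectorySeries(
        frames=frames,
        times=dt * sample_every * np.arange(len(frames)),
        velocities=np.stack(frames_vel) * sigma_a,
        temperature=temperature,
    )
    truth = {
        "kind": "lj_fluid",
        "seed": int(seed),
        "reduced_density": float(density),
        "reduced_temperature": float(temperature),
        "box_A": float(box * sigma_a),
    }
    return traj, _write_truth(truth, truth_path)


# ---------------------------------------------------------------------------
# Periodic water-box geometry fixture
# ---------------------------------------------------------------------------


def gen_water_box(
    n_molecules: int,
    box_length: float,
    seed: int = 0,
    min_oo: float = 2.5,
    truth_path=None,
):
    """Rigid waters randomly placed/oriented in a cubic periodic box.

    Gas-phase monomer geometry (0.9572 A, 104.52 deg); the minimum-image
    O-O distance is kept above ``min_oo``.  Returns ``(Structure, truth)``.
    """
    rng = np.random.default_rng(seed)
    template = _water_template()
    oxygens: list[np.ndarray] = []
    mols: list[np.ndarray] = []
    attempts = 0
    while len(mols) < n_molecules:
        attempts += 1
        if attempts > 10_000:
            raise PackingError(
                f"could not place {n_molecules} waters with O-O >= {min_oo} A "
                f"in L = {box_length} A after 10^4 attempts"
            )
        origin = rng.uniform(0.0, box_length, 3)
        ok = True
        for o in oxygens:
            d = origin - o
            d -= box_length * np.round(d / box_length)
            if np.linalg.norm(d) < min_oo:
                ok = False
                break
        if not ok:
            continue
        mols.append((template @ _random_rotation(rng).T) + origin)
        oxygens.append(origin)
    coords = np.vstack(mols)
    structure = Structure(
        symbols=["O", "H", "H"] * n_molecules,
        coords=coords,
        cell=np.eye(3) * box_length,
        pbc=(True, True, True),
    )
    truth = {
        "kind": "water_box",
        "seed": int(seed),
        "n_molecules": int(n_molecules),
        "box_length_A": float(box_length),
        "min_oo_A": float(min_oo),
    }
    return structure, _write_truth(truth, truth_path)
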