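"""Equilibrium and dynamical observables of MD trajectories.

Estimators: radial distribution functions, mean-square-displacement
diffusion with the Yeh-Hummer finite-size correction, velocity
autocorrelation and the (optionally quantum-corrected) vibrational
density of states, hydrogen-bond angle distributions, the
Errington-Debenedetti tetrahedral order parameter, a smooth
ion-coordination collective variable, enthalpy differences between
phases, isobaric heat capacity and thermal expansion from temperature
scans, and percentile bootstrap errors.

Units follow the package conventions (kcal/mol, Angstrom, fs, K);
diffusion constants are reported in 1e-9 m^2 s^-1 and vibrational
frequencies in cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.constants as _sc
from scipy.signal import savgol_filter

from .core_io import Structure, TrajectorySeries
from .errors import ValidationError
from .units import (
    A2_PER_FS_TO_1E9_M2_S,
    CM1_K,
    KB_KCAL_MOL_K,
)

# hydrodynamic self-interaction constant for a cubic periodic box
XI_CUBIC = 2.837297

# kB in J/K, derived from the package's kcal/mol value
_KB_SI = KB_KCAL_MOL_K * _sc.calorie * 1000.0 / _sc.Avogadro


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class RadialDistribution:
    pair_label: str
    r_centers: np.ndarray  # A
    g: np.ndarray
    bin_width: float
    n_frames: int


@dataclass
class DiffusionResult:
    D_L: float  # 1e-9 m^2/s, finite box
    D_inf: float | None  # after finite-size correction
    fit_window: tuple[float, float]  # fs
    viscosity_used: float | None  # Pa s
    box_length: float | None  # A
    ci: tuple[float, float] | None
    diffusive: bool
    loglog_slope: float
    msd_times: np.ndarray  # fs
    msd: np.ndarray  # A^2


@dataclass
class SpectrumResult:
    omega: np.ndarray  # cm^-1
    vdos: np.ndarray  # raw windowed cosine transform (xQ if corrected)
    vdos_normalized: np.ndarray  # unit integral over the omega grid
    quantum_corrected: bool
    window: str
    t_max: float  # fs


@dataclass
class HBondAngles:
    theta_centers: np.ndarray  # degrees
    density: np.ndarray
    peak_deg: float
    n_angles: int
    oo_cutoff: float


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _species_indices(structure: Structure, species: str) -> np.ndarray:
    idx = np.array([i for i, s in enumerate(structure.symbols) if s == species])
    if idx.size == 0:
        raise ValidationError(f"no atoms of species {species!r}")
    return idx


def _min_image(disp: np.ndarray, cell: np.ndarray | None) -> np.ndarray:
    """Minimum-image displacement vectors (any cell; valid to half-width)."""
    if cell is None:
        return disp
    frac = disp @ np.linalg.inv(cell)
    frac -= np.round(frac)
    return frac @ cell


def _half_min_width(cell: np.ndarray) -> float:
    recip = np.linalg.inv(cell).T
    widths = 1.0 / np.linalg.norm(recip, axis=1)
    return 0.5 * float(widths.min())


# ---------------------------------------------------------------------------
# Radial distribution function
# ---------------------------------------------------------------------------


def rdf(
    trajectory: TrajectorySeries,
    species_a: str,
    species_b: str,
    r_max: float,
    bin_width: float = 0.05,
) -> RadialDistribution:
    """Pair distribution g(r) between two species.

    Minimum-image pair histogram normalized per frame by the ideal-gas
    expectation (exact spherical-shell volumes times the partner number
    density); self-pairs are excluded when the species coincide.
    Requires a periodic cell and ``r_max`` at most half the smallest box
    width.
    """
    frame0 = trajectory.frames[0]
    if frame0.cell is None or not any(frame0.pbc):
        raise ValidationError("rdf requires a periodic cell")
    if r_max > _half_min_width(frame0.cell) + 1e-9:
        raise ValidationError(
            f"r_max={r_max} exceeds half the minimum box width "
            f"({_half_min_width(frame0.cell):.3f} A)"
        )
    ia = _species_indices(frame0, species_a)
    ib = _species_indices(frame0, species_b)
    same = species_a == species_b
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    hist = np.zeros(len(edges) - 1)
    norm = 0.0
    for frame in trajectory.frames:
        cell = frame.cell
        vol = abs(np.linalg.det(cell))
        disp = frame.coords[ib][None, :, :] - frame.coords[ia][:, None, :]
        disp = _min_image(disp.reshape(-1, 3), cell)
        r = np.linalg.norm(disp, axis=1)
        if same:
            r = r[r > 1e-9]  # drop self pairs
        h, _ = np.histogram(r, bins=edges)
        hist += h
        n_partners = len(ib) - (1 if same else 0)
        norm += len(ia) * n_partners / vol
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = hist / (shell * norm)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialDistribution(
        pair_label=f"{species_a}-{species_b}",
        r_centers=centers,
        g=g,
        bin_width=bin_width,
        n_frames=len(trajectory),
    )


# ---------------------------------------------------------------------------
# MSD and diffusion
# ---------------------------------------------------------------------------


def unwrap_positions(trajectory: TrajectorySeries, indices=None) -> np.ndarray:
    """Unwrap periodic coordinates by accumulating minimum-image steps."""
    pos = trajectory.positions()
    if indices is not None:
        pos = pos[:, indices, :]
    cell = trajectory.frames[0].cell
    if cell is None:
        return pos
    steps = _min_image(
        (pos[1:] - pos[:-1]).reshape(-1, 3), cell
    ).reshape(pos.shape[0] - 1, *pos.shape[1:])
    out = np.empty_like(pos)
    out[0] = pos[0]
    out[1:] = pos[0] + np.cumsum(steps, axis=0)
    return out


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """MSD(m) averaged over time origins and atoms; r is (T, N, 3)."""
    T = r.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * T)))
    fft = np.fft.rfft(r, n=nfft, axis=0)
    acf = np.fft.irfft(fft * np.conj(fft), n=nfft, axis=0)[:T].real
    s2 = acf.sum(axis=2)  # (T, N): sum over components
    d = (r**2).sum(axis=2)  # (T, N)
    c1 = np.cumsum(d, axis=0)
    total = c1[-1]
    m = np.arange(T)
    # Q_m = 2*total - sum_{k<m} d[k] - sum_{k<m} d[T-1-k]
    head = np.vstack([np.zeros_like(total), c1[:-1]])  # sum_{k<m} d[k]
    # sum_{k=T-m}^{T-1} d[k] = total - c1[T-m-1]
    tail = np.vstack([np.zeros_like(total), (total - c1[::-1])[1:]])
    q = 2 * total[None, :] - head - tail
    denom = (T - m)[:, None].astype(float)
    msd = q / denom - 2 * s2 / denom
    return msd.mean(axis=1)


def msd_diffusion(
    trajectory: TrajectorySeries,
    species: str | None = None,
    exclude_head_fs: float | None = None,
    exclude_tail_fs: float | None = None,
    loglog_tolerance: float = 0.3,
) -> DiffusionResult:
    """Self-diffusion coefficient from the Einstein relation.

    MSD(t) is averaged over all time origins and atoms (coordinates are
    unwrapped when a cell is present); D_L is one sixth of the
    least-squares MSD slope over the retained window.  Head and tail
    exclusions default to 10% of the trajectory each.  A log-log slope
    far from 1 over the window marks the estimate as non-diffusive.
    """
    if len(trajectory) < 2:
        raise ValidationError("need at least two frames")
    idx = None
    if species is not None:
        idx = _species_indices(trajectory.frames[0], species)
    r = unwrap_positions(trajectory, idx)
    msd = _msd_fft(r)
    times = trajectory.times - trajectory.times[0]
    span = times[-1]
    head = 0.1 * span if exclude_head_fs is None else exclude_head_fs
    tail = 0.1 * span if exclude_tail_fs is None else exclude_tail_fs
    window = (times >= head) & (times <= span - tail)
    if window.sum() < 10:
        raise ValidationError("fit window shorter than 10 samples")
    tw, mw = times[window], msd[window]
    slope, intercept = np.polyfit(tw, mw, 1)
    d_l = max(slope, 0.0) / 6.0 * A2_PER_FS_TO_1E9_M2_S

    pos_mask = (mw > 0) & (tw > 0)
    if pos_mask.sum() >= 2:
        loglog = float(np.polyfit(np.log(tw[pos_mask]), np.log(mw[pos_mask]), 1)[0])
    else:
        loglog = np.nan
    diffusive = bool(np.isfinite(loglog) and abs(loglog - 1.0) <= loglog_tolerance)

    cell = trajectory.frames[0].cell
    box_l = float(cell[0, 0]) if cell is not None else None
    return DiffusionResult(
        D_L=float(d_l),
        D_inf=None,
        fit_window=(float(tw[0]), float(tw[-1])),
        viscosity_used=None,
        box_length=box_l,
        ci=None,
        diffusive=diffusive,
        loglog_slope=loglog,
        msd_times=times,
        msd=msd,
    )


def finite_size_correction(
    D_L: float, temperature: float, viscosity: float, box_length: float
) -> float:
    """Yeh-Hummer correction: D_inf = D_L + kB T xi / (6 pi eta L).

    ``D_L`` and the returned value are in 1e-9 m^2/s; ``viscosity`` in
    Pa s; ``box_length`` the cubic box edge in Angstrom (xi = 2.837297
    holds for cubic boxes only).
    """
    if viscosity <= 0:
        raise ValidationError("viscosity must be positive")
    if box_length <= 0:
        raise ValidationError("box length must be positive")
    corr_si = _KB_SI * temperature * XI_CUBIC / (
        6.0 * np.pi * viscosity * box_length * 1e-10
    )
    return float(D_L + corr_si / 1e-9)


def apply_finite_size_correction(
    result: DiffusionResult, temperature: float, viscosity: float,
    box_length: float | None = None,
) -> DiffusionResult:
    """Fill ``D_inf`` on a :class:`DiffusionResult` (cubic box only)."""
    L = box_length if box_length is not None else result.box_length
    if L is None:
        raise ValidationError("box length required for the finite-size correction")
    result.D_inf = finite_size_correction(result.D_L, temperature, viscosity, L)
    result.viscosity_used = viscosity
    result.box_length = L
    return result


# ---------------------------------------------------------------------------
# VACF and vibrational density of states
# ---------------------------------------------------------------------------


def vacf(trajectory: TrajectorySeries) -> tuple[np.ndarray, np.ndarray]:
    """Velocity autocorrelation C_vv(t) = (1/N) sum_i <v_i(0) . v_i(t)>.

    Averaged over all time origins; returns (times_fs, C_vv) with C_vv
    in (A/fs)^2.
    """
    if trajectory.velocities is None:
        raise ValidationError("trajectory has no velocities")
    v = trajectory.velocities  # (T, N, 3)
    T = v.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * T)))
    fft = np.fft.rfft(v, n=nfft, axis=0)
    acf = np.fft.irfft(fft * np.conj(fft), n=nfft, axis=0)[:T].real
    counts = (T - np.arange(T)).astype(float)
    c = acf.sum(axis=2).mean(axis=1) / counts
    return trajectory.times - trajectory.times[0], c


def quantum_factor(omega_cm1, temperature: float):
    """Harmonic quantum correction Q = x / (1 - exp(-x)), x = hbar w / kB T.

    Q -> 1 as omega -> 0; at hbar*omega = kB*T, Q = 1/(1 - 1/e).
    """
    x = CM1_K * np.asarray(omega_cm1, dtype=float) / temperature
    out = np.ones_like(x)
    nz = x > 1e-12
    out[nz] = x[nz] / (1.0 - np.exp(-x[nz]))
    if np.ndim(omega_cm1) == 0:
        return float(out)
    return out


def vdos(
    c_vv: np.ndarray,
    dt_fs: float | None = None,
    times_fs: np.ndarray | None = None,
    temperature: float = 300.0,
    quantum_correct: bool = True,
    omega_max_cm1: float | None = None,
    domega_cm1: float = 1.0,
) -> SpectrumResult:
    """Vibrational density of states from a VACF.

    vDOS(w) = Q(w) * integral_0^Tmax C_vv(t) sin^2(pi t / Tmax) cos(w t) dt
    with a Hann window over the full time span and the harmonic quantum
    factor Q applied when requested.  The frequency grid runs from 0 to
    the Nyquist frequency (or ``omega_max_cm1``) in ``domega_cm1`` steps;
    the integral uses the trapezoid rule.  The spectrum is returned both
    raw and normalized to unit integral over the grid.
    """
    c = np.asarray(c_vv, dtype=float)
    if times_fs is not None:
        t = np.asarray(times_fs, dtype=float) - times_fs[0]
        dts = np.diff(t)
        if len(dts) and np.max(np.abs(dts - dts[0])) > 1e-9 * abs(dts[0]):
            raise ValidationError("non-uniform time grid")
        dt_fs = float(dts[0])
    elif dt_fs is not None:
        t = dt_fs * np.arange(len(c))
    else:
        raise ValidationError("provide dt_fs or times_fs")
    if len(c) < 4:
        raise ValidationError("VACF too short")
    t_max = t[-1]
    window = np.sin(np.pi * t / t_max) ** 2
    cw = c * window

    nyquist_cm1 = 1.0 / (2.0 * dt_fs) * 1e15 / (_sc.c * 100.0)
    w_hi = nyquist_cm1 if omega_max_cm1 is None else omega_max_cm1
    omega = np.arange(0.0, w_hi + domega_cm1 / 2, domega_cm1)
    # angular frequency in rad/fs for each cm^-1 grid point
    w_radfs = 2.0 * np.pi * _sc.c * 100.0 * 1e-15 * omega

    spec = np.empty_like(omega)
    chunk = 2048
    for k in range(0, len(omega), chunk):
        phase = np.cos(np.outer(w_radfs[k : k + chunk], t))
        spec[k : k + chunk] = np.trapezoid(phase * cw[None, :], t, axis=1)
    if quantum_correct:
        spec = spec * quantum_factor(omega, temperature)
    integral = np.trapezoid(np.abs(spec), omega)
    normalized = spec / integral if integral > 0 else spec.copy()
    return SpectrumResult(
        omega=omega,
        vdos=spec,
        vdos_normalized=normalized,
        quantum_corrected=quantum_correct,
        window="hann",
        t_max=float(t_max),
    )


# ---------------------------------------------------------------------------
# Hydrogen-bond geometry and tetrahedral order
# ---------------------------------------------------------------------------


def hbond_angles(
    trajectory: TrajectorySeries,
    oo_cutoff: float = 3.5,
    oh_bond_cutoff: float = 1.2,
    bin_width_deg: float = 1.0,
    theta_max_deg: float = 90.0,
) -> HBondAngles:
    """Donor-side hydrogen-bond angle distribution.

    For every covalent O-H bond (O-H distance below
    ``oh_bond_cutoff``) and every acceptor oxygen within ``oo_cutoff``
    of the donor oxygen, the angle between the O_d->H and O_d->O_a
    vectors is histogrammed in degrees.  The reported peak is the vertex
    of a parabola fit through the maximal bin and its neighbors.
    """
    frame0 = trajectory.frames[0]
    io = _species_indices(frame0, "O")
    ih = _species_indices(frame0, "H")
    angles: list[np.ndarray] = []
    for frame in trajectory.frames:
        cell = frame.cell
        ro, rh = frame.coords[io], frame.coords[ih]
        d_oh = _min_image(
            (rh[None, :, :] - ro[:, None, :]).reshape(-1, 3), cell
        ).reshape(len(io), len(ih), 3)
        r_oh = np.linalg.norm(d_oh, axis=2)
        d_oo = _min_image(
            (ro[None, :, :] - ro[:, None, :]).reshape(-1, 3), cell
        ).reshape(len(io), len(io), 3)
        r_oo = np.linalg.norm(d_oo, axis=2)
        for a in range(len(io)):
            h_loc = np.where(r_oh[a] < oh_bond_cutoff)[0]
            acc = np.where((r_oo[a] < oo_cutoff) & (r_oo[a] > 1e-9))[0]
            if h_loc.size == 0 or acc.size == 0:
                continue
            u = d_oh[a, h_loc]  # (nh, 3)
            v = d_oo[a, acc]  # (na, 3)
            cosang = (u @ v.T) / (
                np.linalg.norm(u, axis=1)[:, None] * np.linalg.norm(v, axis=1)[None, :]
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))).ravel())
    all_angles = np.concatenate(angles) if angles else np.empty(0)
    edges = np.arange(0.0, theta_max_deg + bin_width_deg, bin_width_deg)
    if all_angles.size:
        hist, _ = np.histogram(all_angles, bins=edges, density=True)
    else:
        hist = np.zeros(len(edges) - 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    peak = _parabolic_peak(centers, hist) if all_angles.size else np.nan
    return HBondAngles(
        theta_centers=centers,
        density=hist,
        peak_deg=peak,
        n_angles=int(all_angles.size),
        oo_cutoff=oo_cutoff,
    )


def _parabolic_peak(x: np.ndarray, y: np.ndarray) -> float:
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        return float(x[k])
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-300:
        return float(x[k])
    shift = 0.5 * (y0 - y2) / denom
    return float(x[k] + shift * (x[1] - x[0]))


def tetrahedral_q(trajectory: TrajectorySeries) -> tuple[np.ndarray, np.ndarray]:
    """Errington-Debenedetti tetrahedral order parameter of the oxygens.

    For each oxygen and its four nearest oxygen neighbors (minimum
    image), q = 1 - 3/8 sum_{j<k} (cos psi_jk + 1/3)^2 over the six
    neighbor-pair angles; q = 1 for a perfect tetrahedron and averages
    to 0 for uncorrelated (ideal-gas) positions.

    Returns (per-frame mean q, all per-molecule q values).
    """
    frame0 = trajectory.frames[0]
    io = _species_indices(frame0, "O")
    if len(io) < 5:
        raise ValidationError("tetrahedral q needs at least 5 oxygens")
    per_frame = np.empty(len(trajectory))
    all_q: list[np.ndarray] = []
    for fidx, frame in enumerate(trajectory.frames):
        cell = frame.cell
        ro = frame.coords[io]
        disp = _min_image(
            (ro[None, :, :] - ro[:, None, :]).reshape(-1, 3), cell
        ).reshape(len(io), len(io), 3)
        r = np.linalg.norm(disp, axis=2)
        np.fill_diagonal(r, np.inf)
        qvals = np.empty(len(io))
        for a in range(len(io)):
            nn = np.argsort(r[a])[:4]
            vecs = disp[a, nn]
            vecs = vecs / np.linalg.norm(vecs, axis=1)[:, None]
            s = 0.0
            for j in range(3):
                for k in range(j + 1, 4):
                    s += (np.dot(vecs[j], vecs[k]) + 1.0 / 3.0) ** 2
            qvals[a] = 1.0 - 3.0 / 8.0 * s
        per_frame[fidx] = qvals.mean()
        all_q.append(qvals)
    return per_frame, np.concatenate(all_q)


# ---------------------------------------------------------------------------
# Ion-coordination collective variable
# ---------------------------------------------------------------------------


def coordination_cv(
    trajectory_or_frame: TrajectorySeries | Structure,
    ion_index: int,
    r0: float = 3.0,
    a: float = 4.0,
    oxygen_symbol: str = "O",
    literal: bool = False,
):
    """Smooth count of oxygens inside the ion's first shell.

    s = sum_i f(r_i) with the Fermi switching function
    f(r) = 1/(1 + exp[a (r - r0)]), so waters well inside the cutoff
    contribute ~1 and 0 <= s <= N.  ``literal=True`` evaluates the
    complementary orientation sum_i [1 - f(r_i)] instead (an
    outside-counting convention), for reproduction purposes.

    Defaults: r0 = 3.0 A (first minimum of a typical ion-oxygen RDF) and
    a = 4.0 A^-1.  Returns a scalar for a single structure, an array per
    frame for a trajectory.
    """
    frames = (
        trajectory_or_frame.frames
        if isinstance(trajectory_or_frame, TrajectorySeries)
        else [trajectory_or_frame]
    )
    n_atoms = frames[0].n_atoms
    if not 0 <= ion_index < n_atoms:
        raise ValidationError(f"ion index {ion_index} out of range (N={n_atoms})")
    out = np.empty(len(frames))
    for k, frame in enumerate(frames):
        io = np.array(
            [
                i
                for i, s in enumerate(frame.symbols)
                if s == oxygen_symbol and i != ion_index
            ]
        )
        if io.size == 0:
            raise ValidationError(f"no {oxygen_symbol!r} atoms besides the ion")
        disp = _min_image(frame.coords[io] - frame.coords[ion_index], frame.cell)
        r = np.linalg.norm(disp, axis=1)
        f = 1.0 / (1.0 + np.exp(a * (r - r0)))
        out[k] = np.sum(1.0 - f) if literal else np.sum(f)
    if isinstance(trajectory_or_frame, Structure):
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------


def enthalpy_changes(
    u_means: dict[str, float],
    pv_term: float = 0.0,
    rt_term: float | None = None,
    temperature: float | None = None,
) -> dict[str, float]:
    """Fusion and vaporization enthalpies from phase-average energies.

    ``u_means`` maps phase labels ``s``/``l``/``g`` to ensemble-average
    internal energies (kcal/mol per molecule).  dH_fus = (U_l - U_s) + PV
    and dH_vap = (U_g - U_l) + RT; RT is computed from *temperature*
    when not supplied explicitly.  Each enthalpy is computed when its two
    phases are present; at least one must be computable.
    """
    out: dict[str, float] = {}
    if "l" in u_means and "s" in u_means:
        out["dH_fus"] = (u_means["l"] - u_means["s"]) + pv_term
    if "g" in u_means and "l" in u_means:
        if rt_term is None:
            if temperature is None:
                raise ValidationError("need rt_term or temperature for dH_vap")
            rt_term = KB_KCAL_MOL_K * temperature
        out["dH_vap"] = (u_means["g"] - u_means["l"]) + rt_term
    if not out:
        raise ValidationError(
            "need phases (s, l) and/or (l, g); got " + ", ".join(sorted(u_means))
        )
    return out


def thermo_derivatives(
    series_T: np.ndarray,
    series_y: np.ndarray,
    which: str,
    smooth_window: int | None = None,
) -> np.ndarray:
    """cp(T) = dH/dT or alpha_P(T) = -(1/rho) drho/dT on a uniform T grid.

    Central differences in the interior, one-sided at the ends; an
    optional quadratic Savitzky-Golay smoothing over ``smooth_window``
    points is applied before differencing.
    """
    t = np.asarray(series_T, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < 3:
        raise ValidationError("need matching 1-D arrays with >= 3 points")
    dts = np.diff(t)
    if np.any(dts <= 0) or np.max(np.abs(dts - dts[0])) > 1e-9 * abs(dts[0]):
        raise ValidationError("non-uniform temperature grid")
    if which not in ("cp", "alpha_p"):
        raise ValidationError(f"unknown derivative {which!r}")
    if smooth_window is not None:
        if smooth_window < 3 or smooth_window % 2 == 0:
            raise ValidationError("smooth_window must be odd and >= 3")
        y = savgol_filter(y, smooth_window, polyorder=2)
    dy = np.gradient(y, t, edge_order=2)
    if which == "cp":
        return dy
    return -dy / y


# ---------------------------------------------------------------------------
# Bootstrap errors
# ---------------------------------------------------------------------------


def bootstrap_ci(
    samples,
    statistic=np.mean,
    n_resamples: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap over blocks/replicas.

    Resamples the first axis with replacement and reports the statistic
    on the original sample together with the (alpha/2, 1-alpha/2)
    percentile interval.  Fully deterministic for a given seed.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty input")
    if n_resamples < 100:
        raise ValidationError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    stats = np.empty(n_resamples)
    for k in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        stats[k] = statistic(arr[idx])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        estimate=float(statistic(arr)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
    )
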