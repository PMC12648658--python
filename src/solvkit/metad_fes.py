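"""Well-tempered metadynamics on toy potentials and FES post-processing.

The driver runs overdamped Langevin dynamics (Euler-Maruyama) on an
analytic 1-D potential while depositing Gaussian bias hills whose
heights decay with the accumulated bias (well-tempering, bias factor
gamma = (T + dT)/T > 1).  The free-energy surface is reconstructed from
the deposited bias with the standard estimator
F(s) = -gamma/(gamma - 1) * V_bias(s), shifted so its minimum is zero.
Barriers between the two deepest minima feed an exponential rate-scaling
relation k_X = k_ref * exp[(dA_ref - dA_X)/(kB T)] used to convert a
reference exchange rate into the rate implied by another model's
barrier.

Energies in this module are kJ/mol (the convention of the free-energy
literature this feeds into); the collective variable is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .units import KB_KJ_MOL_K


@dataclass
class BiasHistory:
    """Deposited Gaussians of a well-tempered metadynamics run."""

    centers: np.ndarray  # CV values
    heights: np.ndarray  # kJ/mol
    sigma: float  # CV units
    deposit_stride: int  # steps between hills
    bias_factor: float  # gamma = (T + dT)/T
    temperature: float  # K

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.centers.shape != self.heights.shape:
            raise ValidationError("centers and heights must align")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if len(self.heights) and np.any(self.heights <= 0):
            raise ValidationError("hill heights must be positive")

    def __len__(self) -> int:
        return len(self.centers)

    def bias(self, s) -> np.ndarray:
        """V_bias(s) = sum_k h_k exp(-(s - c_k)^2 / (2 sigma^2))."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if len(self) == 0:
            return np.zeros_like(s)
        diff = s[:, None] - self.centers[None, :]
        return (self.heights[None, :] * np.exp(-(diff**2) / (2 * self.sigma**2))).sum(
            axis=1
        )


@dataclass
class FESProfile:
    """Free energy on a 1-D CV grid with minima/barrier annotations."""

    s_grid: np.ndarray
    free_energy: np.ndarray  # kJ/mol, min shifted to 0
    minima: list[float] = field(default_factory=list)
    barrier: float | None = None  # kJ/mol between the two deepest minima
    saddle: float | None = None  # CV value of the barrier top

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)


# ---------------------------------------------------------------------------
# Toy potentials
# ---------------------------------------------------------------------------


def double_well(barrier_kj: float = 30.0, s_min: float = 1.0):
    """Symmetric quartic double well V(s) = B ((s/s_min)^2 - 1)^2.

    Minima at +-s_min, barrier ``barrier_kj`` at s = 0.  Returns
    (V, dV/ds) callables.
    """

    def v(s):
        return barrier_kj * ((s / s_min) ** 2 - 1.0) ** 2

    def dv(s):
        return barrier_kj * 4.0 * (s / s_min) * ((s / s_min) ** 2 - 1.0) / s_min

    return v, dv


def harmonic_well(kappa_kj: float = 20.0, s0: float = 0.0):
    """V(s) = kappa/2 (s - s0)^2 with its gradient."""

    def v(s):
        return 0.5 * kappa_kj * (s - s0) ** 2

    def dv(s):
        return kappa_kj * (s - s0)

    return v, dv


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def simulate_wtmetad(
    potential,
    gradient,
    temperature: float,
    bias_factor: float,
    w0: float,
    sigma: float,
    stride: int,
    n_steps: int,
    seed: int,
    dt: float = 1e-4,
    mobility: float = 1.0,
    s_start: float | None = None,
    grid: tuple[float, float, int] = (-3.0, 3.0, 2401),
) -> tuple[np.ndarray, BiasHistory]:
    """Overdamped Langevin dynamics with well-tempered hill deposition.

    Every ``stride`` steps a Gaussian of width ``sigma`` is deposited at
    the current CV value with height ``w0 * exp(-V_bias(s)/(kB dT))``,
    dT = (gamma - 1) T.  The accumulated bias and its gradient are kept
    on a fine grid (linear interpolation) for speed; the exact hill list
    is returned as the :class:`BiasHistory`.  Seed-deterministic.
    """
    if bias_factor <= 1.0:
        raise ValidationError("well-tempering requires bias factor > 1")
    if stride < 1 or n_steps < 0:
        raise ValidationError("stride must be >= 1 and n_steps >= 0")
    rng = np.random.default_rng(seed)
    kbt = KB_KJ_MOL_K * temperature
    kb_dt = KB_KJ_MOL_K * (bias_factor - 1.0) * temperature
    lo, hi, npts = grid
    s_grid = np.linspace(lo, hi, int(npts))
    ds = s_grid[1] - s_grid[0]
    v_bias = np.zeros_like(s_grid)
    g_bias = np.zeros_like(s_grid)

    s = 0.0 if s_start is None else float(s_start)
    noise_scale = np.sqrt(2.0 * mobility * kbt * dt)
    xi = rng.standard_normal(n_steps)
    traj = np.empty(n_steps + 1)
    traj[0] = s
    centers: list[float] = []
    heights: list[float] = []
    for step in range(n_steps):
        if (step + 1) % stride == 0:
            vb = np.interp(s, s_grid, v_bias)
            h = w0 * np.exp(-vb / kb_dt)
            centers.append(s)
            heights.append(h)
            gauss = h * np.exp(-((s_grid - s) ** 2) / (2 * sigma**2))
            v_bias += gauss
            g_bias += gauss * -(s_grid - s) / sigma**2
        force = -(gradient(s) + np.interp(s, s_grid, g_bias))
        s = s + mobility * force * dt + noise_scale * xi[step]
        s = min(max(s, lo + ds), hi - ds)  # reflecting walls at grid edge
        traj[step + 1] = s
    history = BiasHistory(
        centers=np.array(centers),
        heights=np.array(heights),
        sigma=sigma,
        deposit_stride=stride,
        bias_factor=bias_factor,
        temperature=temperature,
    )
    return traj, history


# ---------------------------------------------------------------------------
# FES reconstruction and barriers
# ---------------------------------------------------------------------------


def fes_from_bias(bias_history: BiasHistory, s_grid: np.ndarray) -> FESProfile:
    """Well-tempered FES estimate F(s) = -(gamma/(gamma-1)) V_bias(s).

    The profile is shifted so its minimum is zero, and annotated with
    local minima and the barrier between the two deepest ones.
    """
    if len(bias_history) == 0:
        raise ValidationError("empty bias history")
    s_grid = np.asarray(s_grid, dtype=float)
    gamma = bias_history.bias_factor
    f = -(gamma / (gamma - 1.0)) * bias_history.bias(s_grid)
    f -= f.min()
    profile = FESProfile(s_grid=s_grid, free_energy=f)
    _annotate_extrema(profile)
    return profile


def _local_minima(f: np.ndarray) -> np.ndarray:
    interior = np.where((f[1:-1] < f[:-2]) & (f[1:-1] <= f[2:]))[0] + 1
    return interior


def _annotate_extrema(profile: FESProfile) -> None:
    f, s = profile.free_energy, profile.s_grid
    mins = _local_minima(f)
    profile.minima = [float(s[i]) for i in mins]
    if len(mins) < 2:
        profile.barrier = None
        profile.saddle = None
        return
    order = np.argsort(f[mins])
    i1, i2 = sorted((mins[order[0]], mins[order[1]]))
    inner = f[i1 : i2 + 1]
    k = int(np.argmax(inner)) + i1
    if k in (i1, i2):
        profile.barrier = None
        profile.saddle = None
        return
    profile.barrier = float(f[k] - f[mins[order[0]]])
    profile.saddle = float(s[k])


def barrier_and_rate(
    fes_main: FESProfile | float,
    fes_reference: FESProfile | float,
    k_reference: float,
    temperature: float = 300.0,
) -> dict[str, float]:
    """Barriers plus the exchange rate from exponential scaling.

    Accepts :class:`FESProfile` objects (their annotated barriers are
    used) or plain barrier values in kJ/mol, and returns::

        {"barrier_x": ..., "barrier_ref": ..., "rate": ...}

    with k_X = k_ref * exp[(dA_ref - dA_X) / (kB T)].
    """

    def _barrier(x) -> float:
        if isinstance(x, FESProfile):
            if x.barrier is None:
                raise ValidationError(
                    "FES has no interior maximum between two minima"
                )
            return x.barrier
        return float(x)

    da_x = _barrier(fes_main)
    da_ref = _barrier(fes_reference)
    if da_x < 0 or da_ref < 0:
        raise ValidationError("barriers must be non-negative")
    rate = k_reference * np.exp((da_ref - da_x) / (KB_KJ_MOL_K * temperature))
    return {"barrier_x": da_x, "barrier_ref": da_ref, "rate": float(rate)}


# ---------------------------------------------------------------------------
# Text IO
# ---------------------------------------------------------------------------


def save_bias_history(path: str | Path, history: BiasHistory) -> None:
    """Write hills as delimited text with run metadata in the header."""
    df = pd.DataFrame(
        {
            "hill": np.arange(len(history)),
            "center": history.centers,
            "height": history.heights,
        }
    )
    with Path(path).open("w") as fh:
        fh.write(f"# sigma: {history.sigma}\n")
        fh.write(f"# deposit_stride: {history.deposit_stride}\n")
        fh.write(f"# bias_factor: {history.bias_factor}\n")
        fh.write(f"# temperature: {history.temperature}\n")
        df.to_csv(fh, index=False)


def load_bias_history(path: str | Path) -> BiasHistory:
    from .core_io import read_timeseries

    df, meta = read_timeseries(path)
    return BiasHistory(
        centers=df["center"].to_numpy(),
        heights=df["height"].to_numpy(),
        sigma=float(meta["sigma"]),
        deposit_stride=int(meta["deposit_stride"]),
        bias_factor=float(meta["bias_factor"]),
        temperature=float(meta["temperature"]),
    )


def save_fes(path: str | Path, profile: FESProfile) -> None:
    df = pd.DataFrame({"s": profile.s_grid, "free_energy_kj_mol": profile.free_energy})
    with Path(path).open("w") as fh:
        if profile.barrier is not None:
            fh.write(f"# barrier_kj_mol: {profile.barrier}\n")
        fh.write(f"# minima: {' '.join(f'{m:.6g}' for m in profile.minima)}\n")
        df.to_csv(fh, index=False)
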