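"""Trajectory observables against analytic fixtures and external oracles."""

import warnings

import numpy as np
import pytest
import scipy.constants as sc

from solvkit import synth, traj_analysis as ta
from solvkit.core_io import Structure, TrajectorySeries
from solvkit.errors import ValidationError
from solvkit.units import CM1_K, KB_KCAL_MOL_K


def _series(frames, dt=1.0, velocities=None, temperature=300.0):
    return TrajectorySeries(
        frames=frames, times=dt * np.arange(len(frames)),
        velocities=velocities, temperature=temperature,
    )


class TestRDF:
    def test_ideal_gas_is_flat(self):
        traj, _ = synth.gen_ideal_gas_traj(120, 12.0, 60, seed=3)
        res = ta.rdf(traj, "O", "O", r_max=5.0, bin_width=0.1)
        sel = res.r_centers > 2.0
        # counting-noise sigma per bin from the expected ideal-gas count
        rho = 119 / 12.0**3
        counts = 120 * rho * 4 * np.pi * res.r_centers[sel] ** 2 * 0.1 * 60
        # same-species pairs enter the histogram twice (ordered pairs), so
        # the independent count is half the tally: sigma_g = sqrt(2/counts)
        sigma = np.sqrt(2.0 / counts)
        dev = np.abs(res.g[sel] - 1.0) / sigma
        assert np.mean(dev < 3.0) > 0.95
        assert np.abs(res.g[sel].mean() - 1.0) < 3.0 * np.sqrt(2.0 / counts.sum())

    def test_two_atoms_single_bin(self):
        d = 3.14
        cell = np.eye(3) * 20.0
        s = Structure(["O", "N"], [[0, 0, 0], [d, 0, 0]], cell=cell,
                      pbc=(True,) * 3)
        res = ta.rdf(_series([s]), "O", "N", r_max=5.0, bin_width=0.1)
        occupied = res.r_centers[res.g > 0]
        assert len(occupied) == 1
        assert abs(occupied[0] - d) <= 0.05

    def test_matches_mdanalysis_oracle(self):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rdf import InterRDF

        traj, _ = synth.gen_ideal_gas_traj(60, 12.0, 25, seed=9, symbol="O")
        for f in traj.frames:
            f.symbols = ["O"] * 30 + ["N"] * 30
        mine = ta.rdf(traj, "O", "N", r_max=5.0, bin_width=0.1)

        coords = np.stack([f.coords for f in traj.frames])
        u = mda.Universe.empty(60, trajectory=True)
        u.add_TopologyAttr("name", ["O"] * 30 + ["N"] * 30)
        u.load_new(coords,
                   dimensions=np.tile([12, 12, 12, 90, 90, 90], (25, 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = InterRDF(u.select_atoms("name O"), u.select_atoms("name N"),
                           nbins=50, range=(0.0, 5.0))
            ref.run()
        assert np.allclose(mine.g, ref.results.rdf, atol=1e-10)

    def test_missing_species_and_large_rmax_rejected(self):
        traj, _ = synth.gen_ideal_gas_traj(10, 10.0, 2, seed=1)
        with pytest.raises(ValidationError, match="Mg"):
            ta.rdf(traj, "Mg", "O", r_max=4.0)
        with pytest.raises(ValidationError, match="r_max"):
            ta.rdf(traj, "O", "O", r_max=8.0)


class TestDiffusion:
    def test_static_atoms_have_zero_D(self):
        s = Structure(["O"] * 4, np.arange(12).reshape(4, 3).astype(float))
        traj = _series([s] * 50)
        res = ta.msd_diffusion(traj)
        assert res.D_L == pytest.approx(0.0, abs=1e-9)

    def test_langevin_matches_analytic_D(self):
        traj, truth = synth.gen_langevin_traj(
            300, 300.0, 0.02, 18.0, 1.0, 3000, seed=5
        )
        res = ta.msd_diffusion(traj, exclude_head_fs=200.0,
                               exclude_tail_fs=2000.0)
        assert res.D_L == pytest.approx(truth["D_1e9_m2_s"], rel=0.05)
        assert res.diffusive

    def test_ballistic_motion_flagged_nondiffusive(self):
        v = np.array([0.01, 0.0, 0.0])
        frames = [
            Structure(["O"], (v * t)[None, :]) for t in np.arange(200.0)
        ]
        res = ta.msd_diffusion(_series(frames))
        assert not res.diffusive
        assert res.loglog_slope == pytest.approx(2.0, abs=0.05)

    def test_short_window_rejected(self):
        s = Structure(["O"], [[0, 0, 0]])
        with pytest.raises(ValidationError):
            ta.msd_diffusion(_series([s] * 8))

    def test_unwrap_recovers_straight_line(self):
        # particle crossing the boundary of a 5 A box
        L = 5.0
        xs = (0.3 * np.arange(40.0)) % L
        frames = [
            Structure(["O"], [[x, 0, 0]], cell=np.eye(3) * L, pbc=(True,) * 3)
            for x in xs
        ]
        unwrapped = ta.unwrap_positions(_series(frames))
        assert np.allclose(unwrapped[:, 0, 0], 0.3 * np.arange(40.0))


class TestFiniteSizeCorrection:
    def test_closed_form_hand_value(self):
        # independent evaluation with CODATA constants
        kb, T, eta, L = sc.Boltzmann, 300.0, 0.85e-3, 24.8e-10
        expected = 2.27 + kb * T * 2.837297 / (6 * np.pi * eta * L) / 1e-9
        assert ta.finite_size_correction(2.27, 300.0, 0.85e-3, 24.8) == (
            pytest.approx(expected, rel=1e-6)
        )

    def test_infinite_viscosity_limit(self):
        assert ta.finite_size_correction(2.0, 300.0, 1e6, 24.8) == (
            pytest.approx(2.0, abs=1e-9)
        )

    def test_doubling_L_halves_correction(self):
        c1 = ta.finite_size_correction(0.0, 300.0, 0.85e-3, 20.0)
        c2 = ta.finite_size_correction(0.0, 300.0, 0.85e-3, 40.0)
        assert c1 == pytest.approx(2.0 * c2, rel=1e-12)

    def test_correction_is_positive(self):
        assert ta.finite_size_correction(1.0, 300.0, 1e-3, 25.0) > 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            ta.finite_size_correction(1.0, 300.0, 0.0, 25.0)
        with pytest.raises(ValidationError):
            ta.finite_size_correction(1.0, 300.0, 1e-3, -1.0)


class TestVACF:
    def test_constant_velocity_gives_speed_squared(self):
        v = np.array([0.1, -0.2, 0.05])
        frames = [Structure(["O"], [[0, 0, 0]]) for _ in range(32)]
        vel = np.tile(v, (32, 1, 1))
        times, c = ta.vacf(_series(frames, velocities=vel))
        assert np.allclose(c, np.dot(v, v), atol=1e-14)

    def test_harmonic_oscillator_is_cosine(self):
        w = 0.05  # rad/fs
        n = 4096
        t = np.arange(float(n))
        vel = np.zeros((n, 1, 3))
        vel[:, 0, 0] = np.cos(w * t)
        frames = [Structure(["O"], [[0, 0, 0]]) for _ in range(n)]
        _, c = ta.vacf(_series(frames, velocities=vel))
        # origin averaging leaves an O(1/(T w)) remainder on top of cos
        lags = np.arange(200)
        assert np.allclose(c[lags] / c[0], np.cos(w * lags), atol=0.02)

    def test_antisymmetric_pair_matches_single(self):
        rng = np.random.default_rng(7)
        v1 = rng.standard_normal((64, 1, 3))
        frames1 = [Structure(["O"], [[0, 0, 0]]) for _ in range(64)]
        _, c_single = ta.vacf(_series(frames1, velocities=v1))
        v2 = np.concatenate([v1, -v1], axis=1)
        frames2 = [Structure(["O", "O"], [[0, 0, 0], [5, 0, 0]])
                   for _ in range(64)]
        _, c_pair = ta.vacf(_series(frames2, velocities=v2))
        assert np.allclose(c_pair, c_single, atol=1e-12)

    def test_requires_velocities(self):
        frames = [Structure(["O"], [[0, 0, 0]])] * 4
        with pytest.raises(ValidationError):
            ta.vacf(_series(frames))


class TestVDOS:
    def test_quantum_factor_limits(self):
        assert ta.quantum_factor(0.0, 300.0) == pytest.approx(1.0)
        assert ta.quantum_factor(1e-6, 300.0) == pytest.approx(1.0, abs=1e-8)
        # at hbar*omega = kB*T the factor is 1/(1 - 1/e)
        omega_kbt = 300.0 / CM1_K
        assert ta.quantum_factor(omega_kbt, 300.0) == pytest.approx(
            1.0 / (1.0 - np.exp(-1.0)), rel=1e-12
        )

    def test_harmonic_peak_within_one_bin(self):
        traj, truth = synth.gen_harmonic_traj(1000.0, 300.0, 0.5, 4096, seed=2)
        times, c = ta.vacf(traj)
        spec = ta.vdos(c, times_fs=times, temperature=300.0,
                       quantum_correct=False, omega_max_cm1=2000.0)
        peak = spec.omega[np.argmax(spec.vdos)]
        assert abs(peak - truth["omega_cm1"]) <= 1.0

    def test_quantum_correction_scales_spectrum(self):
        traj, _ = synth.gen_harmonic_traj(800.0, 300.0, 0.5, 4096, seed=3)
        times, c = ta.vacf(traj)
        raw = ta.vdos(c, times_fs=times, temperature=300.0,
                      quantum_correct=False, omega_max_cm1=1500.0)
        cor = ta.vdos(c, times_fs=times, temperature=300.0,
                      quantum_correct=True, omega_max_cm1=1500.0)
        q = ta.quantum_factor(cor.omega, 300.0)
        assert np.allclose(cor.vdos, raw.vdos * q, atol=1e-10)

    def test_matches_discrete_transform_oracle(self):
        rng = np.random.default_rng(11)
        c = rng.standard_normal(64)
        dt = 0.5
        spec = ta.vdos(c, dt_fs=dt, quantum_correct=False,
                       omega_max_cm1=500.0, domega_cm1=25.0)
        t = dt * np.arange(64)
        tmax = t[-1]
        for k, w_cm in enumerate(spec.omega):
            w = 2 * np.pi * sc.c * 100 * 1e-15 * w_cm
            integrand = c * np.sin(np.pi * t / tmax) ** 2 * np.cos(w * t)
            expected = np.trapezoid(integrand, t)
            assert spec.vdos[k] == pytest.approx(expected, abs=1e-10)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValidationError):
            ta.vdos(np.ones(8), times_fs=np.array([0, 1, 2, 3.5, 4, 5, 6, 7.0]))


class TestHbondAngles:
    @staticmethod
    def _donor_acceptor(theta_deg, d_oo=2.8):
        """One donor water O-H and one acceptor O at angle theta."""
        th = np.radians(theta_deg)
        coords = [
            [0.0, 0.0, 0.0],                      # donor O
            [0.9572, 0.0, 0.0],                   # H along x
            [-0.24, 0.93, 0.0],                   # second H, out of the way
            [d_oo * np.cos(th), d_oo * np.sin(th), 0.0],  # acceptor O
        ]
        return Structure(["O", "H", "H", "O"], coords)

    def test_collinear_geometry_gives_zero(self):
        s = self._donor_acceptor(0.0)
        res = ta.hbond_angles(_series([s]), bin_width_deg=1.0)
        assert any(abs(a) < 1.0 for a in [res.peak_deg])
        assert res.n_angles > 0

    def test_planted_fifteen_degree_peak(self):
        s = self._donor_acceptor(15.0)
        res = ta.hbond_angles(_series([s]), bin_width_deg=1.0)
        # the donor has two O-H bonds; select the histogram peak near 15
        occupied = res.theta_centers[res.density > 0]
        assert np.any(np.abs(occupied - 15.0) <= 1.0)

    def test_acceptor_beyond_cutoff_excluded(self):
        s = self._donor_acceptor(15.0, d_oo=4.2)
        res = ta.hbond_angles(_series([s]), oo_cutoff=3.5)
        assert res.n_angles == 0

    def test_no_oxygen_rejected(self):
        s = Structure(["H", "H"], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValidationError):
            ta.hbond_angles(_series([s]))


class TestTetrahedralQ:
    def test_perfect_tetrahedron_is_one(self):
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) * 2.0
        coords = np.vstack([[0.0, 0.0, 0.0], verts])
        s = Structure(["O"] * 5, coords)
        _, all_q = ta.tetrahedral_q(_series([s]))
        assert all_q[0] == pytest.approx(1.0, abs=1e-12)

    def test_collinear_neighbors_give_minus_three(self):
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [1.1, 0, 0], [1.2, 0, 0], [1.3, 0, 0]],
            dtype=float,
        )
        s = Structure(["O"] * 5, coords)
        _, all_q = ta.tetrahedral_q(_series([s]))
        # q = 1 - 3/8 * 6 * (1 + 1/3)^2 = -3 for four parallel bonds
        assert all_q[0] == pytest.approx(-3.0, abs=1e-12)

    def test_ideal_gas_mean_is_zero(self):
        traj, _ = synth.gen_ideal_gas_traj(40, 15.0, 40, seed=8)
        _, all_q = ta.tetrahedral_q(traj)
        sem = all_q.std() / np.sqrt(len(all_q))
        assert abs(all_q.mean()) < 4.0 * sem + 0.01

    def test_too_few_oxygens_rejected(self):
        s = Structure(["O"] * 4, np.eye(4, 3) * 2.0)
        with pytest.raises(ValidationError):
            ta.tetrahedral_q(_series([s]))


class TestCoordinationCV:
    @staticmethod
    def _ion_with_waters(radii):
        coords = [[0.0, 0.0, 0.0]]
        symbols = ["Mg"]
        for k, r in enumerate(radii):
            u = np.array([np.cos(k), np.sin(k), 0.1 * k])
            u /= np.linalg.norm(u)
            coords.append(list(r * u))
            symbols.append("O")
        return Structure(symbols, coords)

    def test_switch_midpoint_gives_half(self):
        s = self._ion_with_waters([3.0])
        assert ta.coordination_cv(s, 0, r0=3.0, a=4.0) == pytest.approx(0.5)

    def test_deep_inside_counts_as_one(self):
        s = self._ion_with_waters([1.0])
        assert ta.coordination_cv(s, 0, r0=3.0, a=4.0) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_six_waters_at_first_peak_distance(self):
        # six oxygens at 2.07 A, a = 4/A, r0 = 3 A: s = 6/(1 + e^-3.72)
        s = self._ion_with_waters([2.07] * 6)
        expected = 6.0 / (1.0 + np.exp(-3.72))
        assert ta.coordination_cv(s, 0) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(5.86, abs=0.01)

    def test_literal_orientation_is_complement(self):
        s = self._ion_with_waters([2.0, 2.5, 3.5])
        inside = ta.coordination_cv(s, 0)
        outside = ta.coordination_cv(s, 0, literal=True)
        assert inside + outside == pytest.approx(3.0, abs=1e-12)

    def test_monotone_and_bounded(self):
        values = [
            ta.coordination_cv(self._ion_with_waters([r] * 4), 0)
            for r in np.linspace(1.5, 5.0, 12)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 4.0 for v in values)

    def test_bad_ion_index(self):
        s = self._ion_with_waters([2.0])
        with pytest.raises(ValidationError):
            ta.coordination_cv(s, 5)


class TestEnthalpy:
    def test_vaporization_with_rt_from_temperature(self):
        out = ta.enthalpy_changes({"g": -0.5, "l": -10.5}, temperature=300.0)
        assert out["dH_vap"] == pytest.approx(10.0 + KB_KCAL_MOL_K * 300.0)
        assert out["dH_vap"] == pytest.approx(10.5962, abs=1e-4)

    def test_equal_energies_zero_fusion(self):
        out = ta.enthalpy_changes({"s": -11.0, "l": -11.0}, pv_term=0.0)
        assert out["dH_fus"] == 0.0

    def test_explicit_rt_overrides(self):
        out = ta.enthalpy_changes({"g": 0.0, "l": -10.0}, rt_term=0.7,
                                  temperature=300.0)
        assert out["dH_vap"] == pytest.approx(10.7)

    def test_missing_phases_rejected(self):
        with pytest.raises(ValidationError):
            ta.enthalpy_changes({"s": -1.0})


class TestThermoDerivatives:
    def test_linear_enthalpy_gives_constant_cp(self):
        t = np.linspace(250.0, 330.0, 17)
        h = 0.018 * t - 11.0
        cp = ta.thermo_derivatives(t, h, "cp")
        assert np.allclose(cp, 0.018, atol=1e-10)

    def test_linear_density_alpha_closed_form(self):
        t = np.linspace(250.0, 330.0, 17)
        b = 2.5e-4
        rho = 1.1 * (1.0 - b * t)
        alpha = ta.thermo_derivatives(t, rho, "alpha_p")
        expected = b / (1.0 - b * t)
        assert np.allclose(alpha[1:-1], expected[1:-1], atol=1e-10)

    def test_alpha_crosses_zero_at_density_maximum(self):
        t = np.linspace(250.0, 330.0, 33)
        t_star = 277.0
        rho = 1.0 - 5e-7 * (t - t_star) ** 2
        alpha = ta.thermo_derivatives(t, rho, "alpha_p")
        sign_change = np.where(np.diff(np.sign(alpha)))[0]
        assert len(sign_change) == 1
        crossing = t[sign_change[0]]
        assert abs(crossing - t_star) <= (t[1] - t[0])

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValidationError):
            ta.thermo_derivatives(np.array([1.0, 2.0, 4.0]), np.ones(3), "cp")


class TestBootstrap:
    def test_zero_variance_zero_width(self):
        res = ta.bootstrap_ci(np.full(20, 3.3), n_resamples=200, seed=1)
        assert res.ci_low == res.ci_high == pytest.approx(3.3)

    def test_seed_determinism(self):
        x = np.random.default_rng(2).normal(size=30)
        r1 = ta.bootstrap_ci(x, n_resamples=300, seed=42)
        r2 = ta.bootstrap_ci(x, n_resamples=300, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_coverage_near_95_percent(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 400
        for k in range(n_rep):
            x = rng.normal(0.0, 1.0, size=25)
            res = ta.bootstrap_ci(x, n_resamples=200, seed=k)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert 0.89 <= hits / n_rep <= 0.99

    def test_empty_and_too_few_resamples_rejected(self):
        with pytest.raises(ValidationError):
            ta.bootstrap_ci([], n_resamples=200)
        with pytest.raises(ValidationError):
            ta.bootstrap_ci([1.0, 2.0], n_resamples=10)
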