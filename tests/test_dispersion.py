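"""Dispersion engine: counting function, C6 interpolation, pair sums."""

import numpy as np
import pytest

from solvkit.core_io import Structure
from solvkit.dispersion import (
    DispersionParams,
    ElementTable,
    c6_interpolated,
    coordination_numbers,
    dispersion_components,
    dispersion_energy,
)
from solvkit.errors import ValidationError
from solvkit.synth import _water_template, toy_element_table


def single_point_table() -> ElementTable:
    """CN-independent C6 (one reference point per pair): oracle-friendly."""
    return ElementTable(
        covalent_radii={"O": 0.65, "H": 0.35},
        sqrt_q={"O": 0.75, "H": 0.60},
        r0_pairs={("H", "H"): 1.4, ("H", "O"): 1.6, ("O", "O"): 1.9},
        c6_reference={
            ("H", "H"): [[0.0, 0.0, 25.0]],
            ("H", "O"): [[0.0, 0.0, 50.0]],
            ("O", "O"): [[0.0, 0.0, 100.0]],
        },
    )


class TestCoordinationNumbers:
    def test_isolated_atom_is_zero(self, toy_table):
        s = Structure(["O"], [[0.0, 0.0, 0.0]])
        assert coordination_numbers(s, toy_table) == pytest.approx([0.0])

    def test_switch_midpoint_gives_half(self, toy_table):
        # at r = k2 * (Rcov_A + Rcov_B) the counting function is exactly 1/2
        r = (4.0 / 3.0) * 2 * toy_table.covalent_radii["O"]
        s = Structure(["O", "O"], [[0, 0, 0], [r, 0, 0]])
        assert coordination_numbers(s, toy_table) == pytest.approx([0.5, 0.5])

    def test_matches_brute_force_on_water(self, toy_table):
        s = Structure(["O", "H", "H"], _water_template())
        cn = coordination_numbers(s, toy_table)
        rcov = toy_table.covalent_radii
        expected = np.zeros(3)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                r = np.linalg.norm(s.coords[i] - s.coords[j])
                rs = rcov[s.symbols[i]] + rcov[s.symbols[j]]
                expected[i] += 1.0 / (1.0 + np.exp(-16.0 * (4.0 / 3.0 * rs / r - 1.0)))
        assert cn == pytest.approx(expected, abs=1e-12)

    def test_missing_element_names_it(self, toy_table):
        s = Structure(["Cl"], [[0, 0, 0]])
        with pytest.raises(ValidationError, match="Cl"):
            coordination_numbers(s, toy_table)


class TestC6Interpolation:
    def test_single_point_is_constant(self):
        pts = [[1.0, 2.0, 42.0]]
        for cn in (0.0, 1.0, 7.3):
            assert c6_interpolated(cn, cn, pts) == pytest.approx(42.0)

    def test_symmetric_points_give_mean(self):
        pts = [[0.0, 0.0, 10.0], [2.0, 2.0, 30.0]]
        assert c6_interpolated(1.0, 1.0, pts) == pytest.approx(20.0)

    def test_matches_brute_force_weighted_sum(self, rng):
        pts = rng.uniform(0, 4, size=(4, 3))
        cn_a, cn_b = 1.3, 2.1
        w = np.exp(-4.0 * ((cn_a - pts[:, 0]) ** 2 + (cn_b - pts[:, 1]) ** 2))
        expected = float(np.dot(w, pts[:, 2]) / w.sum())
        assert c6_interpolated(cn_a, cn_b, pts) == pytest.approx(expected, rel=1e-12)

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValidationError):
            c6_interpolated(1.0, 1.0, np.empty((0, 3)))


class TestDispersionEnergy:
    def test_single_atom_is_zero(self, toy_table):
        s = Structure(["O"], [[0, 0, 0]])
        params = DispersionParams()
        assert dispersion_energy(s, toy_table, params) == 0.0
        assert dispersion_components(s, toy_table, params) == (0.0, 0.0)

    def test_isolated_pair_closed_form(self):
        # r chosen so both damping functions exceed 0.9999
        table = single_point_table()
        r = 4.5
        s = Structure(["O", "O"], [[0, 0, 0], [r, 0, 0]])
        params = DispersionParams(s6=1.2, s8=3.4)
        c6 = 100.0
        c8 = 3.0 * c6 * 0.75 * 0.75
        expected = -params.s6 * c6 / r**6 - params.s8 * c8 / r**8
        e = dispersion_energy(s, table, params)
        assert e == pytest.approx(expected, rel=1e-4)

    def test_periodic_cell_matches_replica_oracle(self):
        """Periodic image sum vs brute-force explicit 5x5x5 replica cluster."""
        table = single_point_table()
        L = 6.0
        params = DispersionParams(s8=2.0, cutoff=10.0, cn_cutoff=10.0)
        mol = Structure(
            ["O", "H", "H"], _water_template() + 2.0,
            cell=np.eye(3) * L, pbc=(True,) * 3,
        )
        e_periodic = dispersion_energy(mol, table, params)

        coords = np.vstack([
            mol.coords + np.array([i, j, k]) * L
            for i in range(5) for j in range(5) for k in range(5)
        ])
        syms = mol.symbols * 125
        central = range(62 * 3, 62 * 3 + 3)  # replica (2,2,2)
        c6_tab = {("O", "O"): 100.0, ("H", "O"): 50.0, ("O", "H"): 50.0,
                  ("H", "H"): 25.0}
        e_oracle = 0.0
        for a in central:
            for b in range(len(coords)):
                if b == a:
                    continue
                r = np.linalg.norm(coords[a] - coords[b])
                if r > params.cutoff:
                    continue
                sa, sb = syms[a], syms[b]
                c6 = c6_tab[(sa, sb)]
                c8 = 3.0 * c6 * table.sqrt_q[sa] * table.sqrt_q[sb]
                r0 = table.r0(sa, sb)
                f6 = 1.0 / (1.0 + 6.0 * (r / (params.sr6 * r0)) ** -14)
                f8 = 1.0 / (1.0 + 6.0 * (r / r0) ** -16)
                e_oracle += -0.5 * (
                    params.s6 * c6 / r**6 * f6 + params.s8 * c8 / r**8 * f8
                )
        assert abs(e_periodic - e_oracle) < 1e-8

    def test_rigid_motion_and_permutation_invariance(self, toy_table, rng):
        coords = rng.uniform(0, 5, size=(6, 3))
        symbols = ["O", "H", "H", "O", "H", "H"]
        params = DispersionParams(s8=2.5)
        e0 = dispersion_energy(Structure(symbols, coords), toy_table, params)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = coords @ q.T + np.array([3.0, -7.0, 11.0])
        e1 = dispersion_energy(Structure(symbols, moved), toy_table, params)
        perm = rng.permutation(6)
        e2 = dispersion_energy(
            Structure([symbols[i] for i in perm], coords[perm]), toy_table, params
        )
        assert e1 == pytest.approx(e0, abs=1e-9)
        assert e2 == pytest.approx(e0, abs=1e-9)

    def test_zero_distance_rejected(self, toy_table):
        s = Structure(["O", "O"], [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValidationError):
            dispersion_energy(s, toy_table, DispersionParams())


class TestComponents:
    def test_linearity_identity(self, toy_table, rng):
        coords = rng.uniform(0, 6, size=(7, 3))
        s = Structure(["Mg"] + ["O", "H", "H"] * 2, coords)
        params = DispersionParams(s6=0.7, s8=5.3)
        e6u, e8u = dispersion_components(s, toy_table, params)
        e = dispersion_energy(s, toy_table, params)
        assert params.s6 * e6u + params.s8 * e8u == pytest.approx(e, abs=1e-10)

    def test_doubling_s8_doubles_only_e8_part(self, toy_table):
        s = Structure(["O", "O"], [[0, 0, 0], [2.5, 0, 0]])
        p1 = DispersionParams(s6=1.0, s8=2.0)
        p2 = DispersionParams(s6=1.0, s8=4.0)
        e6u, e8u = dispersion_components(s, toy_table, p1)
        e1 = dispersion_energy(s, toy_table, p1)
        e2 = dispersion_energy(s, toy_table, p2)
        assert e2 - e1 == pytest.approx(2.0 * e8u, abs=1e-12)

    def test_pair_override_takes_precedence(self, toy_table):
        s = Structure(["Mg", "O"], [[0, 0, 0], [2.1, 0, 0]])
        base = DispersionParams(s8=1.75)
        tuned = DispersionParams(s8=1.75, pair_s8_overrides={("Mg", "O"): 9.01})
        assert dispersion_energy(s, toy_table, tuned) < dispersion_energy(
            s, toy_table, base
        )
        # only the Mg-O channel contributes, and it carries the override
        e_tuned, per_pair = dispersion_energy(s, toy_table, tuned, breakdown=True)
        assert per_pair[("Mg", "O")] == pytest.approx(e_tuned)
        assert all(
            v == 0.0 for k, v in per_pair.items() if k != ("Mg", "O")
        )


class TestInvariantsAndProperties:
    def test_increasing_s8_never_raises_energy(self, toy_table, rng):
        coords = rng.uniform(0, 5, size=(5, 3))
        s = Structure(["O", "H", "H", "O", "H"], coords)
        energies = [
            dispersion_energy(s, toy_table, DispersionParams(s8=v))
            for v in np.linspace(0, 12, 7)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_periodic_sum_converges_cubically_with_cutoff(self):
        """The lattice-sum tail decays as cutoff^-3 (integrated r^-6 shell).

        The absolute tail magnitude scales with rho*C6, so the check is
        on the decay: the 50->80 A change must be several times smaller
        than the 30->50 A change, and tiny relative to the total.
        """
        from solvkit.synth import gen_water_box

        box, _ = gen_water_box(16, 7.8, seed=4)
        table = single_point_table()

        def e(cutoff):
            return dispersion_energy(
                box, table, DispersionParams(cutoff=cutoff, cn_cutoff=10.0)
            )

        e30, e50, e80 = e(30.0), e(50.0), e(80.0)
        # r^-3 tail predicts (30^-3 - 50^-3)/(50^-3 - 80^-3) ~ 4.8
        assert abs(e80 - e50) < abs(e50 - e30) / 3.0
        assert abs(e50 - e30) / abs(e50) < 1e-3
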