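"""Space-frame beam solver: closed-form oracles, linearity, matrix structure."""

import numpy as np
import pytest

from orthowire.beam_fem import (
    LoadCase,
    assemble_and_solve,
    assemble_stiffness,
    discretize,
    material_preset,
    probe_deflection,
    shear_modulus_from,
    FrameSolver,
)
from conftest import straight_path

Z = np.array([0.0, 0.0, 1.0])


def straight_model(length=20.0, diameter=0.5, stations=None, max_len=1.0):
    path = straight_path(length=length)
    return discretize(
        path,
        max_element_length=max_len,
        stations=stations,
        section_diameter=diameter,
        material=material_preset("nitinol"),
    )


def bending_EI(model):
    E = model.material.youngs_modulus / 1e6
    return E * model.bending_inertia


class TestShearModulus:
    @pytest.mark.parametrize(
        "E,nu,expected,sig",
        [(8.3e7, 0.33, 3.12e7, 3), (2.1e11, 0.31, 8.015e10, 4)],
    )
    def test_published_transverse_moduli(self, E, nu, expected, sig):
        G = shear_modulus_from(E, nu)
        assert G == pytest.approx(expected, rel=5 * 10.0 ** (-sig))

    def test_zero_poisson(self):
        assert shear_modulus_from(10.0, 0.0) == 5.0

    @pytest.mark.parametrize("nu", [0.5, -1.0, 0.7])
    def test_invalid_poisson(self, nu):
        with pytest.raises(ValueError):
            shear_modulus_from(1.0, nu)


class TestDiscretize:
    def test_element_count_and_bound(self, arch_wire):
        model = discretize(arch_wire, max_element_length=1.0)
        assert model.n_elements >= 110
        chords = np.linalg.norm(np.diff(model.nodes, axis=0), axis=1)
        assert np.all(chords <= 1.0 + 1e-9)

    def test_straight_10mm_wire(self):
        model = straight_model(length=10.0)
        assert model.n_elements >= 10

    def test_station_node_inserted_exactly(self):
        model = straight_model(stations=[10.0 + 0.123])
        assert abs(model.node_stations[model.node_at(10.123)] - 10.123) < 1e-9

    def test_section_properties(self):
        model = straight_model(diameter=2.0)
        assert model.area == pytest.approx(np.pi)
        assert model.bending_inertia == pytest.approx(np.pi / 4)
        assert model.torsion_constant == pytest.approx(np.pi / 2)


class TestClosedFormOracles:
    def test_center_load_clamped_clamped(self):
        L, F = 20.0, 0.5
        model = straight_model(length=L, stations=[L / 2])
        sol = assemble_and_solve(
            model, LoadCase(station=L / 2, force=F, direction=Z, frame="y")
        )
        expected = F * L**3 / (192.0 * bending_EI(model))
        assert sol.load_point_deflection == pytest.approx(expected, rel=1e-9)
        assert probe_deflection(sol, L / 2) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("a", [3.0, 7.0, 12.5])
    def test_off_center_load(self, a):
        L, F = 20.0, 0.25
        b = L - a
        model = straight_model(length=L, stations=[a])
        sol = assemble_and_solve(
            model, LoadCase(station=a, force=F, direction=Z, frame="y")
        )
        expected = F * a**3 * b**3 / (3.0 * bending_EI(model) * L**3)
        assert sol.load_point_deflection == pytest.approx(expected, rel=1e-9)

    def test_nodal_exactness_independent_of_element_count(self):
        L, F = 20.0, 0.5
        results = []
        for max_len in (10.0, 2.5, 0.5):
            model = straight_model(length=L, stations=[L / 2], max_len=max_len)
            sol = assemble_and_solve(
                model, LoadCase(station=L / 2, force=F, direction=Z, frame="y")
            )
            results.append(sol.load_point_deflection)
        assert results[0] == pytest.approx(results[2], rel=1e-9)
        assert results[1] == pytest.approx(results[2], rel=1e-9)

    def test_clamped_ends_have_zero_motion(self):
        model = straight_model(stations=[10.0])
        sol = assemble_and_solve(
            model, LoadCase(station=10.0, force=1.0, direction=Z, frame="y")
        )
        np.testing.assert_allclose(sol.displacements[0], 0.0, atol=1e-15)
        np.testing.assert_allclose(sol.displacements[-1], 0.0, atol=1e-15)

    def test_symmetric_beam_symmetric_deflection(self):
        L = 20.0
        s = 4.0
        model = straight_model(length=L, stations=[L / 2, L / 2 - s, L / 2 + s])
        sol = assemble_and_solve(
            model, LoadCase(station=L / 2, force=1.0, direction=Z, frame="y")
        )
        assert probe_deflection(sol, L / 2 - s) == pytest.approx(
            probe_deflection(sol, L / 2 + s), rel=1e-10
        )


class TestLinearity:
    def test_deflection_linear_in_force(self):
        model = straight_model(stations=[10.0])
        solver = FrameSolver(model)
        base = solver.solve(LoadCase(station=10.0, force=0.1, direction=Z, frame="y"))
        for F in (0.2, 1.0, 10.0):
            sol = solver.solve(LoadCase(station=10.0, force=F, direction=Z, frame="y"))
            assert sol.load_point_deflection / F == pytest.approx(
                base.load_point_deflection / 0.1, rel=1e-12
            )

    def test_superposition(self, arch_wire):
        model = discretize(arch_wire, 2.0, stations=[30.0, 70.0])
        solver = FrameSolver(model)
        s1 = solver.solve(LoadCase(station=30.0, force=1.0, direction=Z, frame="y"))
        s2 = solver.solve(LoadCase(station=70.0, force=2.0, direction=Z, frame="y"))
        # sum of the two single-load solutions at each node
        combined = s1.displacements + s2.displacements
        # solve with both loads via two sequential solves of the same matrix
        f_sum = s1.displacements * 0
        n = len(model.node_stations)
        f = np.zeros(6 * n)
        for sol, st, F in ((s1, 30.0, 1.0), (s2, 70.0, 2.0)):
            f[6 * model.node_at(st) : 6 * model.node_at(st) + 3] += F * Z
        import scipy.linalg

        K = assemble_stiffness(model)
        fixed = np.r_[0:6, 6 * (n - 1) : 6 * n]
        free = np.setdiff1d(np.arange(6 * n), fixed)
        u = np.zeros(6 * n)
        u[free] = scipy.linalg.solve(
            K[np.ix_(free, free)], f[free], assume_a="pos"
        )
        np.testing.assert_allclose(
            u.reshape(n, 6), combined, rtol=1e-10, atol=1e-14
        )


class TestMatrixStructure:
    def test_global_stiffness_symmetric(self, arch_wire):
        model = discretize(arch_wire, 5.0)
        K = assemble_stiffness(model)
        assert np.abs(K - K.T).max() <= 1e-10 * np.abs(K).max()

    def test_six_rigid_body_modes_on_straight_model(self):
        model = straight_model(length=21.0, max_len=7.0)  # 3 elements
        K = assemble_stiffness(model)
        w = np.linalg.eigvalsh(K)
        near_zero = np.sum(np.abs(w) < 1e-8 * np.abs(w).max())
        assert near_zero == 6

    def test_positive_definite_after_clamping(self):
        model = straight_model(length=20.0, max_len=2.0)
        K = assemble_stiffness(model)
        n = len(model.node_stations)
        free = np.setdiff1d(np.arange(6 * n), np.r_[0:6, 6 * (n - 1) : 6 * n])
        w = np.linalg.eigvalsh(K[np.ix_(free, free)])
        assert w.min() > 0


class TestErrors:
    def test_load_at_clamp_rejected(self):
        model = straight_model()
        with pytest.raises(ValueError):
            assemble_and_solve(
                model, LoadCase(station=0.0, force=1.0, direction=Z, frame="y")
            )

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(station=5.0, force=1.0, direction=np.array([0, 0, 2.0]))

    def test_material_preset_unknown(self):
        with pytest.raises(KeyError):
            material_preset("adamantium")

    def test_preset_isotropy_mismatch_recorded(self):
        bone = material_preset("bone")
        assert 0.004 < bone.isotropy_mismatch < 0.008  # published G is ~0.6% off
        assert material_preset("enamel").isotropy_mismatch < 1e-3
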