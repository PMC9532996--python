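"""Solver verification: assembly, oracles, contact dynamics, stress recovery."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
import scipy.sparse.linalg as spla

import cannonbone as cb
from cannonbone.errors import BoundaryConditionError, InvalidInputError
from cannonbone.fea import (
    Material,
    SimulationConfig,
    assemble,
    critical_timestep,
    fracture_assessment,
    natural_frequency,
    quasi_static_deflection,
    quasi_static_prescribed,
    recover_stresses,
    simulate_impact,
)
from cannonbone.morphology import build_bone_model
from cannonbone.scaling import scale_isometric

from conftest import uniform_tube_spec

E, RHO = 20e9, 2000.0
TUBE_I = cb.annulus_second_moment(1.0, 0.5) * 1e-12  # m^4
TUBE_A = math.pi * 0.75 * 1e-6  # m^2


def coarse_config(**over):
    """Fast simulation settings for solver behaviour tests."""
    base = dict(n_output_frames=200)
    base.update(over)
    return SimulationConfig(**base)


class TestAssembly:
    def test_free_dof_count(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=50)
        system = assemble(model, material)
        assert system.n_free == 50 * 6  # 51 nodes, one clamped

    def test_mass_conservation(self, material):
        spec = cb.species_fixture("euchoreutes")
        model = build_bone_model(spec, n_elements=40)
        system = assemble(model, material)
        expected = material.density * float(
            np.sum(system.area * system.elem_length)
        )
        assert system.total_mass == pytest.approx(expected, rel=1e-12)

    def test_no_clamp_rejected(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=10)
        model.clamped_nodes = np.array([], dtype=int)
        with pytest.raises(BoundaryConditionError):
            assemble(model, material)


class TestCriticalTimestep:
    def test_element_bound_closed_form(self, material):
        # uniform rod, l_e = 0.5 mm, c = sqrt(E/rho) ~ 3162 m/s
        model = build_bone_model(uniform_tube_spec(length=25.0), n_elements=50)
        system = assemble(model, material)
        c = math.sqrt(E / RHO)
        assert critical_timestep(system, "element") == pytest.approx(
            0.5e-3 / c, rel=1e-9
        )

    def test_halving_element_length(self, material):
        m1 = build_bone_model(uniform_tube_spec(), n_elements=50)
        m2 = build_bone_model(uniform_tube_spec(), n_elements=100)
        s1, s2 = assemble(m1, material), assemble(m2, material)
        assert critical_timestep(s2, "element") == pytest.approx(
            critical_timestep(s1, "element") / 2.0, rel=1e-9
        )

    def test_eigen_bound_matches_dense_oracle(self, material):
        """2/omega_max from the full dense eigenproblem (small system)."""
        model = build_bone_model(uniform_tube_spec(), n_elements=12)
        system = assemble(model, material)
        K = system.K.toarray()
        lam = np.linalg.eigvalsh(
            np.diag(1.0 / np.sqrt(system.M)) @ K @ np.diag(1.0 / np.sqrt(system.M))
        )
        dt_oracle = 2.0 / math.sqrt(lam[-1])
        assert critical_timestep(system) == pytest.approx(dt_oracle, rel=1e-8)
        assert critical_timestep(system) <= critical_timestep(system, "element")


class TestQuasiStatic:
    def test_tip_deflection_closed_form(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=50)
        res = quasi_static_deflection(model, material, 1.0)
        expected = 1.0 * 0.025**3 / (3.0 * E * TUBE_I)
        assert res.tip_deflection == pytest.approx(expected, rel=0.01)

    def test_zero_force_zero_stress(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=20)
        res = quasi_static_deflection(model, material, 0.0)
        assert res.tip_deflection == 0.0
        assert res.peak_vm == 0.0

    def test_linearity(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=30)
        r1 = quasi_static_deflection(model, material, 1.0)
        r2 = quasi_static_deflection(model, material, 2.0)
        assert r2.tip_deflection == pytest.approx(2.0 * r1.tip_deflection, rel=1e-9)
        assert r2.peak_vm == pytest.approx(2.0 * r1.peak_vm, rel=1e-9)

    def test_prescribed_tip_root_stress(self, material):
        """delta = 2 mm on a solid 1 mm rod, L = 25 mm: sigma = 3 E delta r / L^2."""
        model = build_bone_model(
            uniform_tube_spec(r_outer=1.0, thickness=1.0), n_elements=100
        )
        res = quasi_static_prescribed(model, material, 2e-3)
        assert res.peak_vm == pytest.approx(192e6, rel=0.01)


class TestStressRecovery:
    def test_pure_axial(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=10)
        system = assemble(model, material)
        tip_dof = 6 * int(model.contact_nodes[0])  # x translation
        g2f = {g: i for i, g in enumerate(system.free)}
        rhs = np.zeros(system.n_free)
        rhs[g2f[tip_dof]] = 5.0  # 5 N along the axis
        u = spla.spsolve(system.K.tocsc(), rhs)
        u_full = np.zeros(system.n_dof)
        u_full[system.free] = u
        vm = recover_stresses(system, u_full)
        assert np.allclose(vm, 5.0 / TUBE_A, rtol=1e-9)

    def test_pure_torsion(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=10)
        system = assemble(model, material)
        rot_dof = 6 * int(model.contact_nodes[0]) + 3  # torsion DOF
        g2f = {g: i for i, g in enumerate(system.free)}
        rhs = np.zeros(system.n_free)
        T = 0.01  # N m
        rhs[g2f[rot_dof]] = T
        u = spla.spsolve(system.K.tocsc(), rhs)
        u_full = np.zeros(system.n_dof)
        u_full[system.free] = u
        vm = recover_stresses(system, u_full)
        expected = math.sqrt(3.0) * T * 1e-3 / (2.0 * TUBE_I)
        assert np.allclose(vm, expected, rtol=1e-9)


class TestNaturalFrequency:
    def test_cantilever_closed_form(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=100)
        f1 = natural_frequency(model, material, 0)
        f1_cf = (1.8751041**2 / (2 * math.pi)) * math.sqrt(
            E * TUBE_I / (RHO * TUBE_A * 0.025**4)
        )
        assert f1 == pytest.approx(f1_cf, rel=0.02)

    def test_mode_ratio(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=100)
        f1 = natural_frequency(model, material, 0)
        f2 = natural_frequency(model, material, 1)
        assert f2 / f1 == pytest.approx((4.6940911 / 1.8751041) ** 2, rel=0.02)

    def test_isometric_scaling_inverse_frequency(self, material):
        """Scaling all geometry by k scales eigenfrequencies by 1/k."""
        spec = uniform_tube_spec()
        big = scale_isometric(spec, 2.0 * spec.length)
        f_small = natural_frequency(build_bone_model(spec, 60), material, 0)
        f_big = natural_frequency(build_bone_model(big, 60), material, 0)
        assert f_big == pytest.approx(f_small / 2.0, rel=1e-6)

    def test_mode_out_of_range(self, material):
        model = build_bone_model(uniform_tube_spec(), n_elements=6)
        with pytest.raises(InvalidInputError):
            natural_frequency(model, material, 500)


class TestSimulateImpact:
    def test_first_contact_at_gap_over_speed(self, material):
        spec = cb.species_fixture("jaculus")
        model = build_bone_model(spec, n_elements=30, contact="distal_epiphysis")
        res = simulate_impact(model, material, coarse_config())
        t_first = res.time_grid[np.argmax(res.grf_series > 0.0)]
        assert t_first == pytest.approx(1e-3, rel=0.05)  # 1 mm gap at 1 m/s
        before = res.time_grid < 1e-3 - 1e-9
        assert np.all(res.grf_series[before] == 0.0)
        assert np.all(res.grf_series >= 0.0)

    def test_no_contact_returns_zero_result(self, material):
        spec = cb.species_fixture("jaculus")
        model = build_bone_model(spec, n_elements=20)
        cfg = coarse_config(plate_travel=0.5, travel_includes_gap=True)
        with pytest.warns(UserWarning):
            res = simulate_impact(model, material, cfg)
        assert res.peak_vm == 0.0
        assert res.peak_grf == 0.0
        assert not res.contact_started

    def test_deterministic_reruns(self, material):
        spec = cb.species_fixture("napaeozapus")
        model = build_bone_model(spec, n_elements=30, contact="distal_epiphysis")
        r1 = simulate_impact(model, material, coarse_config())
        r2 = simulate_impact(model, material, coarse_config())
        assert r1.peak_vm == r2.peak_vm
        assert r1.peak_grf == r2.peak_grf
        assert np.array_equal(r1.nodal_peak_vm, r2.nodal_peak_vm)

    def test_three_identical_rays_symmetric(self, material):
        """Identical rays with identical gaps develop identical peak stresses."""
        spec = cb.species_fixture("salpingotus")
        model = build_bone_model(spec, n_elements=30, contact="distal_epiphysis")
        res = simulate_impact(model, material, coarse_config())
        per_ray = [
            res.element_peak_vm[model.ray_of_element == ray].max() for ray in range(3)
        ]
        spread = (max(per_ray) - min(per_ray)) / max(per_ray)
        assert spread < 1e-6

    def test_invariants_of_result(self, material):
        spec = cb.species_fixture("jaculus")
        model = build_bone_model(spec, n_elements=30, contact="distal_epiphysis")
        res = simulate_impact(model, material, coarse_config())
        assert res.peak_vm == pytest.approx(res.nodal_peak_vm.max())
        assert 0.0 <= res.fraction_above_ultimate <= 1.0
        assert res.energy_error < 0.01


class TestFractureAssessment:
    def test_below_threshold_no_fracture(self, material):
        res = _fake_result(peak=180.2e6, n=50)
        rep = fracture_assessment(res, material)
        assert not rep.fracture
        assert rep.fraction_above_ultimate == 0.0

    def test_exactly_at_threshold_is_not_fracture(self, material):
        res = _fake_result(peak=205e6, n=50)
        rep = fracture_assessment(res, material)
        assert not rep.fracture

    def test_all_nodes_above(self, material):
        res = _fake_result(peak=300e6, n=50, fill=300e6)
        rep = fracture_assessment(res, material)
        assert rep.fracture
        assert rep.fraction_above_ultimate == 1.0
        assert rep.histogram_counts.sum() == 50


def _fake_result(peak, n, fill=None):
    """Minimal SimulationResult carrying a synthetic nodal peak field."""
    from cannonbone.fea import SimulationResult

    nodal = np.full(n, fill if fill is not None else peak * 0.5)
    nodal[0] = peak
    z = np.zeros(4)
    return SimulationResult(
        time_grid=z, grf_series=z, plate_position=z, max_vm_series=z,
        peak_grf=0.0, nodal_peak_vm=nodal, element_peak_vm=nodal,
        peak_vm=float(peak), peak_vm_element=0, peak_vm_node=0, peak_vm_time=0.0,
        fracture=peak > 205e6, fraction_above_ultimate=float(np.mean(nodal > 205e6)),
        work_series=z, kinetic_series=z, strain_series=z, contact_series=z,
        energy_error=0.0, dt=1e-8, n_steps=4, contact_started=True,
    )
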