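"""Section mechanics, fusion ratios and model discretization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cannonbone as cb
from cannonbone.errors import (
    DiscretizationError,
    InvalidGeometryError,
    InvalidInputError,
)
from cannonbone.morphology import (
    SectionProfile,
    annulus_second_moment,
    build_bone_model,
    fusion_stiffness_ratio,
    fusion_stress_ratio,
    midshaft_cortical_thickness,
    section_properties,
)

from conftest import uniform_tube_spec


def annulus_inertia_quadrature(r_outer, r_inner, n=4000):
    """Brute-force polar quadrature of I = integral of y^2 dA (oracle)."""
    r = np.linspace(r_inner, r_outer, n)
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    dr = (r_outer - r_inner) / (n - 1) if n > 1 else 0.0
    dth = 2.0 * math.pi / n
    y = rr * np.sin(tt)
    w = np.ones_like(rr)
    w[0] = w[-1] = 0.5  # trapezoid in r
    return float(np.sum(y**2 * rr * w) * dr * dth)


class TestAnnulusSecondMoment:
    @pytest.mark.parametrize(
        "ro,ri,expected",
        [
            (1.0, 1.0, 0.0),  # zero wall
            (1.0, 0.0, math.pi / 4.0),  # solid circle
            (1.0, 0.5, 0.7363107781851077),  # (pi/4)(1 - 0.0625)
        ],
    )
    def test_closed_form_values(self, ro, ri, expected):
        assert annulus_second_moment(ro, ri) == pytest.approx(expected, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        for ro, ri in [(1.0, 0.5), (2.3, 1.9), (0.4, 0.0)]:
            assert annulus_second_moment(ro, ri) == pytest.approx(
                annulus_inertia_quadrature(ro, ri), rel=1e-5
            )

    @pytest.mark.parametrize("ro,ri", [(0.5, 1.0), (-1.0, 0.0), (1.0, -0.1)])
    def test_invalid_geometry_rejected(self, ro, ri):
        with pytest.raises(InvalidGeometryError):
            annulus_second_moment(ro, ri)

    @settings(derandomize=True, max_examples=100)
    @given(
        ro=st.floats(0.01, 50.0),
        f=st.floats(0.0, 1.0),
        eps=st.floats(0.01, 1.0),
    )
    def test_monotone_and_nonnegative(self, ro, f, eps):
        """I >= 0, zero iff hollow-to-the-rim, increasing in r_o, decreasing in r_i."""
        ri = f * ro
        val = annulus_second_moment(ro, ri)
        assert val >= 0.0
        assert (val == 0.0) == (ri == ro)
        assert annulus_second_moment(ro * (1.0 + eps), ri) > val or ri == ro * (1 + eps)
        if ri > 0:
            assert annulus_second_moment(ro, ri * (1.0 - min(eps, 0.99))) >= val


class TestSectionProperties:
    def test_uniform_tube_area(self):
        prof = SectionProfile.uniform(1.0, 0.5)
        props = section_properties(prof, 0.37)
        assert props.area == pytest.approx(math.pi * 0.75, rel=1e-12)
        assert props.I_y == props.I_z
        assert props.J == pytest.approx(props.I_y + props.I_z, rel=1e-12)

    def test_solid_degenerate_wall(self):
        prof = SectionProfile.uniform(1.0, 1.0)
        props = section_properties(prof, 0.5)
        assert props.area == pytest.approx(math.pi, rel=1e-12)
        assert props.I_y == pytest.approx(math.pi / 4.0, rel=1e-12)

    def test_listed_station_is_exact(self):
        prof = SectionProfile((0.0, 0.4, 1.0), (1.0, 2.0, 1.5), (0.2, 0.3, 0.25))
        ro, ri = prof.radii_at(0.4)
        assert ro == 2.0 and ri == pytest.approx(1.7)

    def test_outer_fiber_points(self):
        prof = SectionProfile.uniform(1.3, 0.2)
        props = section_properties(prof, 0.0, n_fiber_points=16)
        radii = [math.hypot(y, z) for y, z in props.outer_fiber_points]
        assert len(radii) == 16
        assert max(radii) == pytest.approx(1.3, rel=1e-12)

    def test_station_out_of_range(self):
        prof = SectionProfile.uniform(1.0, 0.5)
        with pytest.raises(InvalidInputError):
            section_properties(prof, 1.2)


class TestFusionRatios:
    def test_thin_wall_limit_near_nine(self):
        assert fusion_stiffness_ratio(0.5, 0.05) == pytest.approx(9.0, rel=0.05)
        assert fusion_stiffness_ratio(0.5, 0.05) > 1.0

    def test_approaches_nine_monotonically(self):
        rels = [0.5, 0.2, 0.1, 0.02, 0.005]
        vals = [fusion_stiffness_ratio(1.0, t) for t in rels]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(9.0, rel=1e-4)

    def test_always_at_least_one_on_grid(self):
        """Material-conserving fusion never loses stiffness (exact-annulus oracle)."""
        for r in (0.2, 0.7, 2.0):
            for rel_t in (0.05, 0.3, 0.9, 1.6):
                t = rel_t * r
                ratio = fusion_stiffness_ratio(r, t)
                oracle = annulus_inertia_quadrature(
                    3 * r + t / 2, 3 * r - t / 2
                ) / (3 * annulus_inertia_quadrature(r + t / 2, r - t / 2))
                assert ratio == pytest.approx(oracle, rel=1e-4)
                assert ratio >= 1.0

    def test_force_controlled_stress_ratio_thin_wall(self):
        """Equal shared load: fused peak stress tends to a third of unfused."""
        assert fusion_stress_ratio(1.0, 0.1) == pytest.approx(1.0 / 3.0, rel=0.05)
        assert fusion_stress_ratio(1.0, 0.001) == pytest.approx(1.0 / 3.0, rel=1e-3)


class TestBuildBoneModel:
    def test_fused_counts(self):
        model = build_bone_model(uniform_tube_spec(), n_elements=50)
        assert model.n_nodes == 51
        assert model.n_elements == 50
        assert len(model.clamped_nodes) == 1
        assert len(model.contact_nodes) == 1

    def test_unfused_counts(self):
        spec = cb.species_fixture("salpingotus")
        model = build_bone_model(spec, n_elements=50)
        assert model.n_nodes == 3 * 51
        assert model.n_elements == 3 * 50
        assert len(model.clamped_nodes) == 3
        assert len(model.contact_nodes) == 3
        assert not model.is_link.any()

    def test_partial_link_counts(self):
        spec = cb.species_fixture("euchoreutes")  # 4 column stations, 3 rays
        model = build_bone_model(spec, n_elements=50)
        assert int(model.is_link.sum()) == 4 * 2
        assert model.n_elements == 3 * 50 + 8

    def test_too_few_elements(self):
        with pytest.raises(DiscretizationError):
            build_bone_model(uniform_tube_spec(), n_elements=3)

    def test_distal_epiphysis_contact_set(self):
        spec = uniform_tube_spec()
        model = build_bone_model(spec, n_elements=100, contact="distal_epiphysis")
        stations = model.node_positions[model.contact_nodes, 0] / spec.length
        assert stations.min() >= 0.85 - 1e-9
        assert len(model.contact_nodes) > 1


class TestMidshaftThickness:
    def test_uniform(self):
        prof = SectionProfile.uniform(1.0, 0.4)
        assert midshaft_cortical_thickness(prof) == pytest.approx(0.4)

    def test_linear_interpolation(self):
        prof = SectionProfile((0.0, 1.0), (1.0, 1.0), (0.2, 0.6))
        assert midshaft_cortical_thickness(prof) == pytest.approx(0.4)

    def test_synthetic_cylinder_pair(self):
        """Concentric-cylinder surfaces: ray-cast thickness within mesh tolerance."""
        from cannonbone.stlio import tube_surface

        outer = tube_surface(20.0, SectionProfile.uniform(1.0, 0.4), "outer")
        inner = tube_surface(20.0, SectionProfile.uniform(1.0, 0.4), "inner")
        t = midshaft_cortical_thickness((outer, inner))
        assert t == pytest.approx(0.4, abs=0.02)

    def test_bad_input(self):
        with pytest.raises(InvalidInputError):
            midshaft_cortical_thickness(42)
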