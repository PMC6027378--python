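"""Sagitta relation, cap metrics, voxelization and cross-sections."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaffoldsim.geometry import (FLUID, SOLID, BIOMASS, OccludedDomainError,
                                  UnitDesign, attachment_area,
                                  delta_from_diameter, design_metrics,
                                  diameter_from_delta, min_cross_section,
                                  voxelize)


class TestSagittaRelation:
    @pytest.mark.parametrize("delta,expected_um", [
        (7.0, 1435),     # shallow cap of the improved cultured fiber
        (17.0, 605),     # cultured fiber of the all-faces campaign
        (100.0, 200),    # inscribed fiber: minimum diameter 2r
        (50.0, 250),     # (10000 + 2500) / 50
    ])
    def test_diameter_examples(self, delta, expected_um):
        # printed values are given to the micrometre
        assert diameter_from_delta(delta, 100.0) == pytest.approx(
            expected_um, abs=1.0)

    def test_diameter_exact_values(self):
        assert diameter_from_delta(7.0, 100.0) == pytest.approx(
            10049.0 / 7.0, rel=1e-15)
        assert diameter_from_delta(17.0, 100.0) == pytest.approx(
            10289.0 / 17.0, rel=1e-15)

    def test_flat_wall_sentinel(self):
        assert math.isinf(diameter_from_delta(0.0, 100.0))
        assert delta_from_diameter(math.inf, 100.0) == 0.0

    @pytest.mark.parametrize("bad", [-1.0, 100.1, 1e3])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            diameter_from_delta(bad, 100.0)

    @pytest.mark.parametrize("D,expected", [
        (200.0, 100.0),                   # tangent case
        (10049.0 / 7.0, 7.0),             # inverse of the shallow cap
        (520.0, (520 - math.sqrt(520 ** 2 - 4e4)) / 2),
    ])
    def test_inverse_examples(self, D, expected):
        assert delta_from_diameter(D, 100.0) == pytest.approx(
            expected, rel=1e-12)

    def test_no_real_solution_below_2r(self):
        with pytest.raises(ValueError):
            delta_from_diameter(199.0, 100.0)

    @given(delta=st.floats(1e-3, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, delta):
        D = diameter_from_delta(delta, 100.0)
        assert delta_from_diameter(D, 100.0) == pytest.approx(
            delta, rel=1e-9)
        assert D >= 200.0

    def test_diameter_strictly_decreasing_in_delta(self):
        deltas = np.linspace(1.0, 100.0, 50)
        Ds = [diameter_from_delta(d, 100.0) for d in deltas]
        assert all(a > b for a, b in zip(Ds, Ds[1:]))


class TestAttachmentArea:
    def test_improved_fiber_area(self):
        # cap arc of the D = 1435 um fiber across a 200 um unit
        assert attachment_area(1435.0, 200.0, 200.0) == pytest.approx(
            4.01e-8, rel=5e-3)

    def test_half_cylinder(self):
        assert attachment_area(200.0, 200.0, 200.0) == pytest.approx(
            math.pi * 100 * 200 * 1e-12, rel=1e-12)

    def test_flat_limit(self):
        assert attachment_area(math.inf, 200.0, 200.0) == pytest.approx(
            4.0e-8, rel=1e-12)
        # large D approaches the flat face from above
        big = attachment_area(1e9, 200.0, 200.0)
        assert big == pytest.approx(4.0e-8, rel=1e-6)

    def test_decreases_toward_flat_limit(self):
        Ds = [200.0, 300.0, 1000.0, 5000.0]
        areas = [attachment_area(D, 200.0, 200.0) for D in Ds]
        assert all(a > b for a, b in zip(areas, areas[1:]))
        assert areas[-1] > 4.0e-8

    def test_chord_longer_than_diameter_rejected(self):
        with pytest.raises(ValueError):
            attachment_area(150.0, 200.0, 200.0)


class TestUnitDesign:
    def test_displacement_range_enforced(self):
        with pytest.raises(ValueError):
            UnitDesign(r=100, delta_y=150.0)
        with pytest.raises(ValueError):
            UnitDesign(r=100, delta_z=-2.0)

    def test_derived_diameters(self):
        d = UnitDesign(r=100, delta_y=7, delta_z=90)
        assert d.d_primary == pytest.approx(1435.0, abs=1.0)
        assert d.d_secondary == pytest.approx((1e4 + 8100) / 90)

    def test_attachment_angle_of_second_campaign_design(self):
        # tangent-chord angle of the D1 = 605 um cap: ~20 degrees
        d = UnitDesign(r=100, delta_y=17, delta_z=40)
        assert d.alpha == pytest.approx(20.0, abs=1.0)


class TestVoxelize:
    def test_flat_walls_all_fluid(self):
        dom = voxelize(UnitDesign(r=100), 16, dc_um=0.0)
        assert (dom.labels == FLUID).all()
        assert not dom.occluded

    def test_solid_volume_converges_to_cap_segment(self):
        # one half-cylinder pair (delta_y = r): segment area = pi r^2 / 2
        design = UnitDesign(r=100, delta_y=100, delta_z=0)
        L = 200e-6
        exact = math.pi * (100e-6) ** 2  # two half-discs x span, as volume
        exact_vol = exact / 2 * 2 * L    # 2 caps * (pi r^2/2) * span
        errs = []
        for n in (16, 32, 64):
            dom = voxelize(design, n, dc_um=0.0)
            vol = dom.solid.sum() * dom.voxel_volume_m3()
            errs.append(abs(vol - exact_vol) / exact_vol)
        assert errs[-1] < 0.02
        assert errs[0] > errs[-1]  # refinement reduces the error

    def test_biomass_shell_only_on_cultured_face(self):
        design = UnitDesign(r=100, delta_y=50, delta_z=0,
                            cultured_surfaces=("bottom",))
        dom = voxelize(design, 32)
        # biomass voxels hug the bottom cap: all in the lower half
        zs = np.argwhere(dom.biomass)[:, 2]
        assert len(zs) > 0
        assert zs.max() < 16

    def test_biomass_shell_thickness(self):
        design = UnitDesign(r=100, delta_y=0, delta_z=0,
                            cultured_surfaces=("bottom",))
        dom = voxelize(design, 32, dc_um=13.0)
        # flat wall: shell = voxels within 13 um of z = 0 (2 layers of 6.25)
        assert dom.biomass[:, :, 0].all() and dom.biomass[:, :, 1].all()
        assert not dom.biomass[:, :, 2:].any()

    def test_occluded_tangent_fibers_flagged(self):
        dom = voxelize(UnitDesign(r=100, delta_y=100, delta_z=100), 32)
        assert dom.occluded
        with pytest.raises(OccludedDomainError):
            voxelize(UnitDesign(r=100, delta_y=100, delta_z=100), 32,
                     on_occluded="error")

    def test_every_voxel_has_one_label(self, small_domain):
        assert set(np.unique(small_domain.labels)) <= {FLUID, SOLID, BIOMASS}


class TestMinCrossSection:
    def test_empty_duct(self):
        dom = voxelize(UnitDesign(r=100), 16, dc_um=0.0)
        assert min_cross_section(dom) == pytest.approx(4.0e-8, rel=1e-12)

    def test_single_half_cylinder_throat(self):
        # a single inscribed flow-parallel cap: every cross-section is a
        # square minus one half-disc, (200)^2 - pi 100^2 / 2 = 2.43e-8 m^2
        from scaffoldsim.geometry import VoxelDomain
        n = 128
        h = 200.0 / n
        c = (np.arange(n) + 0.5) * h
        Y = np.zeros((n, n, n)) + c[None, :, None]
        Z = np.zeros((n, n, n)) + c[None, None, :]
        solid = (Z - 100.0) ** 2 + Y ** 2 <= 100.0 ** 2
        dom = VoxelDomain(labels=np.where(solid, 1, 0).astype(np.int8),
                          spacing_um=(h, h, h))
        exact = (200e-6) ** 2 - math.pi * (100e-6) ** 2 / 2
        assert exact == pytest.approx(2.43e-8, rel=2e-3)
        assert min_cross_section(dom) == pytest.approx(exact, rel=0.02)

    def test_inscribed_rail_pair(self):
        # both flow-parallel rails inscribed (delta_z = r): the free area
        # is the square minus two half-discs, open at every section
        dom = voxelize(UnitDesign(r=100, delta_y=0, delta_z=100), 128,
                       dc_um=0.0)
        assert not dom.occluded
        exact = (200e-6) ** 2 - math.pi * (100e-6) ** 2
        assert min_cross_section(dom) == pytest.approx(exact, rel=0.03)

    def test_monotone_under_added_fibers(self):
        base = min_cross_section(voxelize(UnitDesign(r=100, delta_y=30),
                                          32, dc_um=0.0))
        more = min_cross_section(
            voxelize(UnitDesign(r=100, delta_y=30, delta_z=30), 32,
                     dc_um=0.0))
        assert more <= base

    def test_bounded_by_duct_area(self, small_domain):
        assert 0 <= min_cross_section(small_domain) <= (200e-6) ** 2


def test_design_metrics(improved_design):
    m = design_metrics(improved_design, resolution=32)
    assert m.attachment_area == pytest.approx(4.01e-8, rel=5e-3)
    assert m.effective_curvature == pytest.approx(1 / 1435.0, rel=1e-3)
    assert 0 < m.min_cross_section < 4e-8
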