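"""Hydrogen-group detection, geometry reconstruction, mass moments,
dummy construction, and parameter emission.

The geometric core is validated against a brute-force Cartesian oracle:
explicit coordinates of each group, with centre of mass and inertia summed
numerically (tests/oracles.py).
"""

import math

import numpy as np
import pytest

from oracles import (mass_moments_numeric, point_masses_moments,
                     threefold_group_coords, triangle_third_side)
from vsitetools.errors import (GeometryError, MissingParameterError,
                               UnknownAtomTypeError)
from vsitetools.ffstore import parse_ff_text
from vsitetools.fixtures import make_ethanol_top
from vsitetools.topio import read_topology_text
from vsitetools.vsites import (HydrogenGroup, MassMoments, alpha_from_hxh,
                               angle_constraint, build_dummies,
                               derive_vsite_parameters, emit_vsite_parameters,
                               find_groups, group_geometry, law_of_cosines,
                               mass_moments)

PROPANE_ITP = """\
[ moleculetype ]
PRP 3
[ atoms ]
 1 CT 1 PRP C1 1 0.0
 2 HC 1 PRP H11 1 0.0
 3 HC 1 PRP H12 1 0.0
 4 HC 1 PRP H13 1 0.0
 5 CT 1 PRP C2 2 0.0
 6 HC 1 PRP H21 2 0.0
 7 HC 1 PRP H22 2 0.0
 8 CT 1 PRP C3 3 0.0
 9 HC 1 PRP H31 3 0.0
10 HC 1 PRP H32 3 0.0
11 HC 1 PRP H33 3 0.0
[ bonds ]
 1 2 1
 1 3 1
 1 4 1
 1 5 1
 5 6 1
 5 7 1
 5 8 1
 8 9 1
 8 10 1
 8 11 1
"""

METHYLAMINE_ITP = """\
[ moleculetype ]
MAM 3
[ atoms ]
 1 CT 1 MAM C1 1 0.0
 2 HC 1 MAM H11 1 0.0
 3 HC 1 MAM H12 1 0.0
 4 HC 1 MAM H13 1 0.0
 5 NL 1 MAM N1 2 0.0
 6 HC 1 MAM HN1 2 0.0
 7 HC 1 MAM HN2 2 0.0
[ bonds ]
 1 2 1
 1 3 1
 1 4 1
 1 5 1
 5 6 1
 5 7 1
"""

ETHANE_ITP = """\
[ moleculetype ]
ETA 3
[ atoms ]
 1 CT 1 ETA C1 1 0.0
 2 HC 1 ETA H11 1 0.0
 3 HC 1 ETA H12 1 0.0
 4 HC 1 ETA H13 1 0.0
 5 CT 1 ETA C2 2 0.0
 6 HC 1 ETA H21 2 0.0
 7 HC 1 ETA H22 2 0.0
 8 HC 1 ETA H23 2 0.0
[ bonds ]
 1 2 1
 1 3 1
 1 4 1
 1 5 1
 5 6 1
 5 7 1
 5 8 1
"""


class TestFindGroups:
    def test_ethanol_has_methyl_and_hydroxyl(self, ethanol, store):
        groups = find_groups(ethanol, store)
        kinds = sorted((g.kind, g.center, g.anchor) for g in groups)
        assert kinds == [("single_bent", 8, 5), ("threefold", 1, 5)]
        methyl = next(g for g in groups if g.kind == "threefold")
        assert methyl.hydrogens == (2, 3, 4)
        assert methyl.center_mass == pytest.approx(12.011)
        assert methyl.hydrogen_mass == pytest.approx(1.008)

    def test_midchain_carbon_is_not_a_group(self, store):
        mol = read_topology_text(PROPANE_ITP)[0]
        groups = find_groups(mol, store)
        assert sorted(g.center for g in groups) == [1, 8]
        assert all(g.kind == "threefold" for g in groups)

    def test_primary_amine_skipped_with_warning(self, store, caplog):
        mol = read_topology_text(METHYLAMINE_ITP)[0]
        with caplog.at_level("WARNING"):
            groups = find_groups(mol, store)
        assert [g.center for g in groups] == [1]  # only the methyl
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_unknown_type_error_mentions_inspect(self, store, ethanol):
        ethanol.atoms[0].type = "QQ"
        with pytest.raises(UnknownAtomTypeError, match="inspect"):
            find_groups(ethanol, store)


class TestGroupGeometry:
    def test_tilt_is_supplement_of_axh_angle(self, ethanol, store):
        groups = find_groups(ethanol, store)
        methyl = next(g for g in groups if g.kind == "threefold")
        geom = group_geometry(methyl, ethanol, store)
        assert geom.b_ax == pytest.approx(0.15290)
        assert geom.b_xh == pytest.approx(0.10900)
        assert math.degrees(geom.alpha) == pytest.approx(180.0 - 110.70)

    def test_tetrahedral_hxh_tilt_matches_explicit_coordinates(self):
        # verify the threefold-symmetry identity geometrically: place three
        # hydrogens at the analytic tilt and measure the H-X-H angle back
        theta_hxh = math.degrees(math.acos(-1.0 / 3.0))  # 109.4712...
        alpha = alpha_from_hxh(theta_hxh)
        assert math.degrees(alpha) == pytest.approx(math.degrees(
            math.acos(1.0 / 3.0)), abs=1e-9)
        pts = threefold_group_coords(0.15, 0.11, math.degrees(alpha))
        x, h1, h2 = pts[1], pts[2], pts[3]
        v1, v2 = h1 - x, h2 - x
        measured = math.degrees(math.acos(
            float(np.dot(v1, v2))
            / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert measured == pytest.approx(theta_hxh, abs=1e-9)

    def test_hxh_fallback_used_when_axh_absent(self, ethanol, store):
        # strip the CT-CT-HC angle from a private store copy
        groups = find_groups(ethanol, store)
        methyl = next(g for g in groups if g.kind == "threefold")
        slim = parse_ff_text(
            "[ bondtypes ]\n"
            "CT CT 1 0.15290 224262.4\nCT HC 1 0.10900 284512.0\n"
            "[ angletypes ]\nHC CT HC 1 109.4712 276.1\n")
        geom = group_geometry(methyl, ethanol, slim)
        assert math.degrees(geom.alpha) == pytest.approx(
            math.degrees(math.acos(1.0 / 3.0)), abs=1e-3)

    def test_missing_angle_names_the_tuple(self, ethanol, store):
        groups = find_groups(ethanol, store)
        methyl = next(g for g in groups if g.kind == "threefold")
        bonds_only = parse_ff_text(
            "[ bondtypes ]\n"
            "CT CT 1 0.15290 224262.4\nCT HC 1 0.10900 284512.0\n")
        with pytest.raises(MissingParameterError, match="CT.*HC"):
            group_geometry(methyl, ethanol, bonds_only)

    def test_inline_bond_parameters_take_precedence(self, store):
        text = ETHANE_ITP.replace(" 1 5 1\n", " 1 5 1 0.16000 224262.4\n")
        mol = read_topology_text(text)[0]
        g = next(g for g in find_groups(mol, store) if g.center == 1)
        geom = group_geometry(g, mol, store)
        assert geom.b_ax == pytest.approx(0.16000)


class TestMassMoments:
    GEOM_KW = dict(b_ax=0.1526, b_xh=0.1090)

    def _group(self, m_x=12.011, m_h=1.008):
        return HydrogenGroup(kind="threefold", center=1, anchor=5,
                             hydrogens=(2, 3, 4), center_mass=m_x,
                             hydrogen_mass=m_h, center_element=6)

    def test_total_mass_and_dummy_mass_arithmetic(self, ethanol, store):
        from vsitetools.vsites import GroupGeometry
        geom = GroupGeometry(alpha=math.radians(70.0), **self.GEOM_KW)
        mm = mass_moments(geom, self._group())
        assert mm.m_tot == pytest.approx(12.011 + 3 * 1.008)
        con = build_dummies(mm, self._group(), ethanol)
        assert con.dummy_mass == pytest.approx(15.035 / 2)

    def test_against_cartesian_oracle_specific_case(self):
        from vsitetools.vsites import GroupGeometry
        geom = GroupGeometry(alpha=math.radians(70.0), **self.GEOM_KW)
        mm = mass_moments(geom, self._group())
        m_tot, z_com, i_axis = mass_moments_numeric(
            0.1526, 0.1090, 70.0, 12.011, 1.008)
        assert mm.m_tot == pytest.approx(m_tot, rel=1e-12)
        assert mm.z_com == pytest.approx(z_com, rel=1e-12)
        assert mm.i_axis == pytest.approx(i_axis, rel=1e-12)

    def test_flat_limit_moment_vanishes(self):
        from vsitetools.vsites import GroupGeometry
        geom = GroupGeometry(alpha=1e-9, **self.GEOM_KW)
        mm = mass_moments(geom, self._group())
        assert mm.i_axis == pytest.approx(0.0, abs=1e-12)
        expect = (12.011 * 0.1526 + 3 * 1.008 * (0.1526 + 0.1090)) / 15.035
        assert mm.z_com == pytest.approx(expect, rel=1e-9)

    def test_doubling_hydrogen_mass_doubles_axis_moment(self):
        from vsitetools.vsites import GroupGeometry
        geom = GroupGeometry(alpha=math.radians(68.0), **self.GEOM_KW)
        mm1 = mass_moments(geom, self._group(m_h=1.008))
        mm2 = mass_moments(geom, self._group(m_h=2.016))
        assert mm2.i_axis == pytest.approx(2 * mm1.i_axis, rel=1e-12)
        # and the oracle agrees
        _, _, i2 = mass_moments_numeric(0.1526, 0.1090, 68.0, 12.011, 2.016)
        assert mm2.i_axis == pytest.approx(i2, rel=1e-12)

    def test_random_sweep_matches_oracle(self, ethanol):
        from vsitetools.vsites import GroupGeometry
        rng = np.random.default_rng(42)
        for _ in range(300):
            b_ax = rng.uniform(0.10, 0.16)
            b_xh = rng.uniform(0.09, 0.14)
            alpha = rng.uniform(55.0, 80.0)
            m_x = rng.uniform(10.0, 35.0)
            m_h = rng.uniform(1.0, 2.1)
            group = self._group(m_x=m_x, m_h=m_h)
            geom = GroupGeometry(b_ax=b_ax, b_xh=b_xh,
                                 alpha=math.radians(alpha))
            mm = mass_moments(geom, group)
            m_tot, z_com, i_axis = mass_moments_numeric(
                b_ax, b_xh, alpha, m_x, m_h)
            assert mm.m_tot == pytest.approx(m_tot, rel=1e-12)
            assert mm.z_com == pytest.approx(z_com, rel=1e-10)
            assert mm.i_axis == pytest.approx(i_axis, rel=1e-10)
            con = build_dummies(mm, group, ethanol)
            dm_tot, dz_com, di_axis = point_masses_moments(
                [con.dummy_mass] * 2,
                [(con.r_d, 0.0, mm.z_com), (-con.r_d, 0.0, mm.z_com)])
            assert dm_tot == pytest.approx(mm.m_tot, rel=1e-14)
            assert dz_com == pytest.approx(mm.z_com, rel=1e-12)
            assert di_axis == pytest.approx(mm.i_axis, rel=1e-10)

    def test_degenerate_moment_raises(self, ethanol):
        mm = MassMoments(m_tot=15.0, z_com=0.2, i_axis=0.0)
        with pytest.raises(GeometryError):
            build_dummies(mm, self._group(), ethanol)


class TestAngleConstraint:
    def test_collinear_limit_exact(self):
        assert law_of_cosines(0.143, 0.096, 180.0) == 0.143 + 0.096

    def test_folded_limit_exact(self):
        assert law_of_cosines(0.143, 0.096, 0.0) == 0.143 - 0.096

    def test_specific_value_matches_coordinate_measurement(self):
        d0 = law_of_cosines(0.1430, 0.0960, 108.5)
        assert d0 == pytest.approx(0.19590, abs=5e-5)
        assert d0 == pytest.approx(
            triangle_third_side(0.1430, 0.0960, 108.5), abs=1e-15)

    def test_random_sweep_matches_coordinates(self):
        rng = np.random.default_rng(4242)
        for _ in range(300):
            b1 = rng.uniform(0.10, 0.20)
            b2 = rng.uniform(0.09, 0.14)
            theta = rng.uniform(1.0, 179.0)
            assert law_of_cosines(b1, b2, theta) == pytest.approx(
                triangle_third_side(b1, b2, theta), abs=1e-12)

    def test_hydroxyl_constraint_from_ethanol(self, ethanol, store):
        groups = find_groups(ethanol, store)
        bent = next(g for g in groups if g.kind == "single_bent")
        geom = group_geometry(bent, ethanol, store)
        ac = angle_constraint(bent, geom, ethanol)
        assert ac.type_pair == ("HO", "CT")
        assert ac.d0 == pytest.approx(
            triangle_third_side(0.1410, 0.0960, 108.5), abs=1e-12)


class TestEmission:
    def test_ethanol_emits_one_type_three_constraints(self, ethanol, store):
        cons, acs = derive_vsite_parameters(ethanol, store)
        text = emit_vsite_parameters(cons, acs, store)
        emitted = parse_ff_text(text)
        assert len(emitted.atomtypes) == 1
        (name, at), = emitted.atomtypes.items()
        assert name == "MCH3A" and at.particle_kind == "dummy"
        assert at.mass == pytest.approx((12.011 + 3 * 1.008) / 2, abs=1e-4)
        assert len(emitted.constrainttypes) == 3

    def test_two_identical_methyls_share_one_dummy_type(self, store):
        mol = read_topology_text(ETHANE_ITP)[0]
        cons, acs = derive_vsite_parameters(mol, store)
        assert len(cons) == 2 and not acs
        text = emit_vsite_parameters(cons, acs, store)
        emitted = parse_ff_text(text)
        assert len(emitted.atomtypes) == 1
        assert cons[0].dummy_type_name == cons[1].dummy_type_name
        assert len(emitted.constrainttypes) == 2  # one d_DD + one d_DA

    def test_emitted_blocks_reread_within_precision(self, ethanol, store):
        cons, acs = derive_vsite_parameters(ethanol, store)
        text = emit_vsite_parameters(cons, acs, store)
        emitted = parse_ff_text(text)
        con = cons[0]
        by_key = {c.key(): c for c in emitted.constrainttypes}
        name = con.dummy_type_name
        assert by_key[(name, name)].d0 == pytest.approx(con.d_dd, abs=1e-5)
        assert by_key[tuple(sorted((name, "CT")))].d0 == pytest.approx(
            con.d_da, abs=1e-5)
        assert all(c.funct == 2 for c in emitted.constrainttypes)

    def test_existing_equivalent_dummy_type_is_reused(self, ethanol, store):
        cons, acs = derive_vsite_parameters(ethanol, store)
        first = emit_vsite_parameters(cons, acs, store)
        grown = parse_ff_text(first)
        grown.atomtypes.update(store.atomtypes)
        grown.bondtypes = store.bondtypes
        grown.angletypes = store.angletypes
        cons2, acs2 = derive_vsite_parameters(ethanol, grown)
        text2 = emit_vsite_parameters(cons2, acs2, grown)
        assert "[ atomtypes ]" not in text2
        assert cons2[0].dummy_type_name == "MCH3A"
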