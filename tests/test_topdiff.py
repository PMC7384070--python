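"""Topology-vs-force-field diffing, torsion rewriting, rtp generation."""

import numpy as np
import pytest

from oracles import v_fourier, v_proper, v_rb
from vsitetools.dihedrals import energy
from vsitetools.errors import InconvertibleDihedralError, TopologyError
from vsitetools.ffstore import (lookup_angle, lookup_bond, lookup_dihedral,
                                read_forcefield)
from vsitetools.fixtures import (NOVEL_ATOMTYPE_COUNT,
                                 NOVEL_INTERACTION_COUNT, SCAN_RB,
                                 make_min_forcefield)
from vsitetools.topdiff import (convert_topology_dihedrals, diff_atomtypes,
                                diff_interactions, make_rtp, report_blocks)
from vsitetools.topio import read_topology_text, template_to_topology, write_rtp

GRID = np.arange(0.0, 360.0, 10.0)


class TestDiff:
    def test_planted_atomtypes_found(self, novel, store):
        new = diff_atomtypes(novel, store)
        assert sorted(at.name for at in new) == ["ZC", "ZN", "ZO"]
        assert len(new) == NOVEL_ATOMTYPE_COUNT
        assert all(at.definition_known for at in new)

    def test_resolvable_topology_diffs_empty(self, ethanol, store):
        assert diff_atomtypes(ethanol, store) == []
        assert diff_interactions(ethanol, store).is_empty()

    def test_planted_interactions_found(self, novel, store):
        rep = diff_interactions(novel, store)
        n = (len(rep.missing_bonds) + len(rep.missing_angles)
             + len(rep.missing_dihedrals))
        assert n == NOVEL_INTERACTION_COUNT
        assert len(rep.missing_bonds) == 3 and len(rep.missing_angles) == 2
        # soundness: every reported tuple really fails lookup
        for m in rep.missing_bonds:
            assert lookup_bond(store, *m.types) is None
        for m in rep.missing_angles:
            assert lookup_angle(store, *m.types) is None
        # all carried inline parameters
        assert all(m.params for m in rep.missing_bonds + rep.missing_angles)

    def test_repeated_missing_tuple_reported_once(self, store):
        text = ("[ atomtypes ]\n"
                "ZC 6 12.011 0.0 A 0.34 0.4\n"
                "ZO 8 15.999 0.0 A 0.30 0.8\n"
                "[ moleculetype ]\nM 3\n[ atoms ]\n"
                "1 ZO 1 M O1 1 0.0\n2 ZC 1 M C1 1 0.0\n3 ZO 1 M O2 1 0.0\n"
                "[ bonds ]\n1 2 1 0.14 1000.0\n2 3 1 0.14 1000.0\n")
        rep = diff_interactions(read_topology_text(text)[0], store)
        assert len(rep.missing_bonds) == 1
        assert rep.missing_bonds[0].types == ("ZC", "ZO")

    def test_novel_type_without_definition_noted(self, store):
        text = ("[ moleculetype ]\nM 3\n[ atoms ]\n1 QQ 1 M X1 1 0.0\n")
        rep = diff_interactions(read_topology_text(text)[0], store)
        assert [at.name for at in rep.new_atomtypes] == ["QQ"]
        assert not rep.new_atomtypes[0].definition_known
        assert any("QQ" in note for note in rep.notes)

    def test_append_blocks_closes_the_diff(self, tmp_path, novel):
        ff = make_min_forcefield(tmp_path / "grow.ff")
        store = read_forcefield(ff)
        rep = diff_interactions(novel, store)
        assert not rep.is_empty()
        blocks = report_blocks(rep, store.dialect)
        with open(ff / "ffbonded.itp", "a") as fh:
            fh.write("\n" + blocks)
        store2 = read_forcefield(ff)
        assert diff_interactions(novel, store2).is_empty()

    def test_completeness_removing_an_entry_reopens_diff(self, tmp_path, novel):
        # append everything except one planted bond: that bond must remain
        ff = make_min_forcefield(tmp_path / "partial.ff")
        store = read_forcefield(ff)
        rep = diff_interactions(novel, store)
        dropped = rep.missing_bonds.pop()
        blocks = report_blocks(rep, store.dialect)
        with open(ff / "ffbonded.itp", "a") as fh:
            fh.write("\n" + blocks)
        rep2 = diff_interactions(novel, read_forcefield(ff))
        assert [m.types for m in rep2.missing_bonds] == [dropped.types]


class TestConvertTopology:
    def test_rb_scan_to_proper_offset_is_constant(self, scan, store):
        mol, _ = scan
        conv, offsets = convert_topology_dihedrals(mol, "proper", store)
        assert len(offsets) == 1
        terms = [(p[0], p[1], int(p[2]))
                 for p in (d.inline_params for d in conv.dihedrals)]
        diff = v_proper(terms, GRID) - v_rb(SCAN_RB, GRID)
        assert np.max(np.abs(diff - offsets[0].offset)) < 1e-12

    def test_rb_scan_to_fourier_offset_is_constant(self, scan, store):
        mol, _ = scan
        conv, offsets = convert_topology_dihedrals(mol, "fourier", store)
        f = conv.dihedrals[0].inline_params
        assert conv.dihedrals[0].funct == 5
        diff = v_fourier(f, GRID) - v_rb(SCAN_RB, GRID)
        assert np.max(np.abs(diff - offsets[0].offset)) < 1e-12

    def test_identity_conversion_keeps_form(self, scan, store):
        mol, _ = scan
        conv, offsets = convert_topology_dihedrals(mol, "rb", store)
        assert conv.dihedrals[0].funct == 3
        assert conv.dihedrals[0].inline_params == pytest.approx(SCAN_RB)
        assert offsets[0].offset == 0.0

    def test_funct9_terms_summed_before_conversion(self, store):
        text = ("[ moleculetype ]\nM 3\n[ atoms ]\n"
                + "".join(f"{i} XS 1 M X{i} 1 0.0\n" for i in range(1, 5))
                + "[ bonds ]\n1 2 1\n2 3 1\n3 4 1\n"
                  "[ dihedrals ]\n1 2 3 4 9 0.0 1.0 1\n1 2 3 4 9 180.0 0.5 2\n")
        mol = read_topology_text(text)[0]
        conv, offsets = convert_topology_dihedrals(mol, "rb", store)
        assert len(conv.dihedrals) == 1
        c = conv.dihedrals[0].inline_params
        diff = (v_rb(c, GRID)
                - v_proper([(0.0, 1.0, 1), (180.0, 0.5, 2)], GRID))
        assert np.max(np.abs(diff - offsets[0].offset)) < 1e-12

    def test_inconvertible_names_the_atoms(self, store):
        text = ("[ moleculetype ]\nM 3\n[ atoms ]\n"
                + "".join(f"{i} XS 1 M X{i} 1 0.0\n" for i in range(1, 5))
                + "[ bonds ]\n1 2 1\n2 3 1\n3 4 1\n"
                  "[ dihedrals ]\n1 2 3 4 3 0 0 0 0 0 1.0\n")
        mol = read_topology_text(text)[0]
        with pytest.raises(InconvertibleDihedralError, match=r"1, 2, 3, 4"):
            convert_topology_dihedrals(mol, "fourier", store)

    def test_energy_after_conversion_matches_module_energy(self, scan, store):
        mol, frames = scan
        conv, offsets = convert_topology_dihedrals(mol, "proper", store)
        from vsitetools.dihedrals import ProperTerm
        terms = tuple(ProperTerm(p[0], p[1], int(p[2]))
                      for p in (d.inline_params for d in conv.dihedrals))
        angles = np.array([phi for phi, _ in frames])
        v1 = np.asarray(energy(terms, angles))
        v2 = v_rb(SCAN_RB, angles) + offsets[0].offset
        assert np.max(np.abs(v1 - v2)) < 1e-12


class TestMakeRtp:
    def test_ethanol_template(self, ethanol):
        templates = make_rtp(ethanol)
        assert len(templates) == 1
        t = templates[0]
        assert t.residue_name == "ETH"
        assert len(t.atoms) == 9 and len(t.bonds) == 8
        assert [a.charge_group for a in t.atoms] == [1, 1, 1, 1, 2, 2, 2, 3, 3]

    def test_duplicate_atom_name_is_error(self):
        text = ("[ moleculetype ]\nM 3\n[ atoms ]\n"
                "1 CT 1 RES C1 1 0.0\n2 CT 1 RES C1 1 0.0\n[ bonds ]\n1 2 1\n")
        with pytest.raises(TopologyError, match="duplicate atom name"):
            make_rtp(read_topology_text(text)[0])

    def test_roundtrip_preserves_connectivity(self, ethanol, store):
        from vsitetools.topio import read_rtp_text
        templates = make_rtp(ethanol)
        back = read_rtp_text(write_rtp(templates))
        mol2 = template_to_topology(back[0], store)
        name = lambda mol, i: mol.atom(i).atom_name
        bonds1 = {frozenset((name(ethanol, i), name(ethanol, j)))
                  for i, j in (b.atom_indices for b in ethanol.bonds)}
        bonds2 = {frozenset((name(mol2, i), name(mol2, j)))
                  for i, j in (b.atom_indices for b in mol2.bonds)}
        assert bonds1 == bonds2
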