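"""Diff a molecule topology against a force field and related tooling.

Given a freshly parameterized molecule (whose .itp typically carries its own
``[ atomtypes ]`` and inline bonded parameters) and a parent force field,
:func:`diff_interactions` lists exactly the atom types and bonded parameter
entries that would have to be added to the force field before tools that
work purely from types (pdb2gmx, the virtual-site derivation here) can
handle the molecule.  The report formats into paste-ready blocks; the
incorporation itself stays a manual, reviewable step.

Also here: rewriting every proper torsion of a topology into a chosen
functional form (with the constant energy offsets reported per dihedral),
and generating residue templates (rtp) from a topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import dihedrals as dih
from .errors import (InconvertibleDihedralError, MissingParameterError,
                     TopologyError)
from .ffstore import (AngleTypeDef, AtomTypeDef, BondTypeDef, Dialect,
                      DihedralTypeDef, ForceFieldStore, format_ff_blocks,
                      lookup_angle, lookup_bond, lookup_dihedral)
from .topio import (DEFAULT_BONDEDTYPES, Interaction, MoleculeTopology,
                    ResidueTemplate, RtpAtom)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MissingInteraction:
    """One bonded parameter entry absent from the force field."""

    types: tuple            # canonical type tuple
    funct: int
    params: Optional[tuple]  # inline parameters carried by the topology
    note: Optional[str] = None


@dataclass
class DiffReport:
    new_atomtypes: list[AtomTypeDef] = field(default_factory=list)
    missing_bonds: list[MissingInteraction] = field(default_factory=list)
    missing_angles: list[MissingInteraction] = field(default_factory=list)
    missing_dihedrals: list[MissingInteraction] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.new_atomtypes or self.missing_bonds
                    or self.missing_angles or self.missing_dihedrals)


def _canonical(types: Sequence[str]) -> tuple:
    fwd = tuple(types)
    return min(fwd, fwd[::-1])


def diff_atomtypes(mol: MoleculeTopology, store: ForceFieldStore
                   ) -> list[AtomTypeDef]:
    """Atom types used by the molecule but absent from the force field.

    Definitions are pulled from the topology's inline ``[ atomtypes ]``;
    a type defined nowhere is still listed, as a placeholder flagged
    ``definition_known=False`` (its element/mass must be filled in by hand).
    """
    inline = {at.name: at for at in mol.inline_atomtypes}
    out: list[AtomTypeDef] = []
    for token in dict.fromkeys(a.type for a in mol.atoms):
        if token in store.atomtypes:
            continue
        if token in inline:
            out.append(inline[token])
        else:
            log.warning("atom type %s has no definition anywhere; mass and "
                        "Lennard-Jones parameters are unknown", token)
            out.append(AtomTypeDef(name=token, mass=0.0, charge=0.0,
                                   particle_kind="atom", lj_sigma=0.0,
                                   lj_epsilon=0.0, definition_known=False))
    return out


def diff_interactions(mol: MoleculeTopology, store: ForceFieldStore
                      ) -> DiffReport:
    """Full diff of a molecule's types and bonded interactions vs a store.

    Type tuples are canonicalized (the lexicographically smaller of forward
    and reverse) and each missing tuple is reported once, carrying inline
    parameters when the topology has them.  Interactions that resolve only
    through wildcard entries count as present, with a note.
    """
    report = DiffReport(new_atomtypes=diff_atomtypes(mol, store))
    for at in report.new_atomtypes:
        if not at.definition_known:
            report.notes.append(
                f"atom type {at.name} lacks a definition; fill in mass and "
                f"Lennard-Jones parameters manually")
        elif at.atomic_number_inferred:
            report.notes.append(
                f"atom type {at.name}: element inferred from its mass; "
                f"verify before incorporating")

    def add(bucket: list, types: tuple, funct: int,
            params: Optional[tuple], kind: str) -> None:
        for m in bucket:
            if m.types == types and m.funct == funct:
                return
        note = None
        if params is None:
            note = "no parameters available in the topology"
            report.notes.append(f"{kind} {types}: interaction is neither in "
                                f"the force field nor parameterized inline")
        bucket.append(MissingInteraction(types, funct, params, note))

    for b in mol.bonds:
        i, j = b.atom_indices
        types = (mol.atom(i).type, mol.atom(j).type)
        if lookup_bond(store, *types) is None:
            add(report.missing_bonds, _canonical(types), b.funct,
                b.inline_params, "bond")
    for a in mol.angles:
        i, j, k = a.atom_indices
        types = (mol.atom(i).type, mol.atom(j).type, mol.atom(k).type)
        if lookup_angle(store, *types) is None:
            add(report.missing_angles, _canonical(types), a.funct,
                a.inline_params, "angle")
    for d in list(mol.dihedrals) + list(mol.impropers):
        types = tuple(mol.atom(i).type for i in d.atom_indices)
        matches = lookup_dihedral(store, *types, funct=d.funct)
        if not matches:
            add(report.missing_dihedrals, _canonical(types), d.funct,
                d.inline_params, "dihedral")
        elif any(m.specificity < 4 for m in matches):
            note = (f"dihedral {types} funct {d.funct} resolves via a "
                    f"wildcard entry; treated as present")
            if note not in report.notes:
                report.notes.append(note)
    if mol.pairs and store.pairtypes:
        for p in mol.pairs:
            i, j = p.atom_indices
            types = (mol.atom(i).type, mol.atom(j).type)
            key = tuple(sorted(types))
            if not any(pt.key() == key for pt in store.pairtypes):
                report.notes.append(
                    f"pair {types} absent from [ pairtypes ]")
    return report


def report_blocks(report: DiffReport, dialect: Optional[Dialect] = None) -> str:
    """Format a diff report as paste-ready force-field blocks.

    Entries lacking parameters cannot be formatted as numbers and appear as
    comment lines instead.
    """
    items: list = [at for at in report.new_atomtypes if at.definition_known]
    comments: list[str] = [
        f"; {at.name}: definition unknown, add by hand"
        for at in report.new_atomtypes if not at.definition_known]
    for m in report.missing_bonds:
        if m.params and len(m.params) >= 2:
            items.append(BondTypeDef(m.types[0], m.types[1], m.funct,
                                     m.params[0], m.params[1]))
        else:
            comments.append(f"; bond {' '.join(m.types)} funct {m.funct}: "
                            f"parameters unknown")
    for m in report.missing_angles:
        if m.params and len(m.params) >= 2:
            items.append(AngleTypeDef(m.types[0], m.types[1], m.types[2],
                                      m.funct, m.params[0], m.params[1]))
        else:
            comments.append(f"; angle {' '.join(m.types)} funct {m.funct}: "
                            f"parameters unknown")
    for m in report.missing_dihedrals:
        if m.params:
            items.append(DihedralTypeDef(m.types, m.funct, m.params))
        else:
            comments.append(f"; dihedral {' '.join(m.types)} funct "
                            f"{m.funct}: parameters unknown")
    text = format_ff_blocks(items, dialect)
    if comments:
        text = text + ("\n" if text and not text.endswith("\n") else "") \
            + "\n".join(comments) + "\n"
    return text


# ---------------------------------------------------------------------------
# dihedral-form conversion of a whole topology

_FUNCT_OF_FORM = {"proper": 9, "rb": 3, "fourier": 5}
_FORM_OF_FUNCT = {1: "proper", 9: "proper", 3: "rb", 5: "fourier"}


@dataclass(frozen=True)
class DihedralOffset:
    """Constant energy change (kJ/mol) from converting one torsion."""

    atom_indices: tuple
    offset: float


def _potential_of(interactions: Sequence[Interaction], mol: MoleculeTopology,
                  store: Optional[ForceFieldStore]):
    """Collect the torsion potential acting on one quadruple.

    Multiple funct-9 entries are summed into one proper-term list; inline
    parameters win over force-field lookups.
    """
    terms: list[dih.ProperTerm] = []
    other = None
    for inter in interactions:
        form = _FORM_OF_FUNCT[inter.funct]
        params = inter.inline_params
        if params is None:
            if store is None:
                raise MissingParameterError(
                    f"dihedral {inter.atom_indices} carries no inline "
                    f"parameters and no force field was given")
            types = tuple(mol.atom(i).type for i in inter.atom_indices)
            matches = lookup_dihedral(store, *types, funct=inter.funct)
            if not matches:
                raise MissingParameterError(
                    f"dihedral {inter.atom_indices} (types {types}, funct "
                    f"{inter.funct}) resolves nowhere")
            if form == "proper":
                terms.extend(dih.ProperTerm(m.params[0], m.params[1],
                                            int(m.params[2]))
                             for m in matches)
            else:
                params = matches[0].params
        elif form == "proper":
            terms.append(dih.ProperTerm(params[0], params[1], int(params[2])))
        if params is not None and form != "proper":
            if other is not None:
                # two parameterized non-proper entries on one quadruple:
                # fold both through RB and sum
                other = _sum_rb(other, params, form)
            else:
                other = dih.RBParams(tuple(params)) if form == "rb" \
                    else dih.FourierParams(tuple(params))
    if terms and other is None:
        return tuple(terms)
    if other is not None and not terms:
        return other
    # mixed forms: everything through RB
    rb = dih.convert(other, "rb").target if other is not None \
        else dih.RBParams((0.0,) * 6)
    rb2 = dih.proper_to_rb(terms).target if terms else dih.RBParams((0.0,) * 6)
    return dih.RBParams(tuple(a + b for a, b in zip(rb.c, rb2.c)))


def _sum_rb(pot, params: tuple, form: str):
    rb1 = dih.convert(pot, "rb").target
    pot2 = dih.RBParams(tuple(params)) if form == "rb" \
        else dih.FourierParams(tuple(params))
    rb2 = dih.convert(pot2, "rb").target
    return dih.RBParams(tuple(a + b for a, b in zip(rb1.c, rb2.c)))


def _params_of(potential, target: str) -> list[tuple]:
    """Inline parameter tuples (one interaction line each) for a potential."""
    if target == "rb":
        return [tuple(potential.c)]
    if target == "fourier":
        return [tuple(potential.f)]
    return [(t.phase, t.k, float(t.n)) for t in potential] or [(0.0, 0.0, 1.0)]


def convert_topology_dihedrals(mol: MoleculeTopology, target_form: str,
                               store: Optional[ForceFieldStore] = None
                               ) -> tuple:
    """Rewrite every proper torsion of a molecule into ``target_form``.

    Returns ``(new_molecule, offsets)`` where offsets is a list of
    :class:`DihedralOffset`, one per torsion quadruple (the constant energy
    shift introduced by its conversion; forces are unchanged).  Improper
    dihedrals are passed through untouched.  An inconvertible torsion raises
    :class:`InconvertibleDihedralError` naming its atoms.
    """
    if target_form not in _FUNCT_OF_FORM:
        raise ValueError(f"unknown target form {target_form!r}")
    if mol.impropers:
        log.warning("molecule %s: %d improper dihedral(s) passed through "
                    "unconverted", mol.name, len(mol.impropers))
    buckets: dict[tuple, list[Interaction]] = {}
    for inter in mol.dihedrals:
        if inter.funct not in _FORM_OF_FUNCT:
            raise InconvertibleDihedralError(
                f"dihedral {inter.atom_indices}: funct {inter.funct} is not "
                f"a proper torsion form")
        key = min(inter.atom_indices, inter.atom_indices[::-1])
        buckets.setdefault(key, []).append(inter)

    new_dihedrals: list[Interaction] = []
    offsets: list[DihedralOffset] = []
    funct = _FUNCT_OF_FORM[target_form]
    for key, inters in buckets.items():
        quad = inters[0].atom_indices
        potential = _potential_of(inters, mol, store)
        try:
            result = dih.convert(potential, target_form)
        except InconvertibleDihedralError as err:
            raise InconvertibleDihedralError(
                f"dihedral between atoms {quad}: {err}") from err
        offsets.append(DihedralOffset(quad, result.constant_offset))
        for params in _params_of(result.target, target_form):
            new_dihedrals.append(Interaction(quad, funct, params))
    new_mol = replace(mol, dihedrals=new_dihedrals)
    return new_mol, offsets


# ---------------------------------------------------------------------------
# rtp generation


def make_rtp(mol: MoleculeTopology,
             bondedtypes: tuple = DEFAULT_BONDEDTYPES
             ) -> list[ResidueTemplate]:
    """Build residue templates from a topology, one per residue name.

    Atom names, types, charges, and charge groups are carried over verbatim;
    bonds and impropers are mapped from indices to names.  Explicit proper
    dihedrals are only included when the topology carried inline parameters
    for them (otherwise pdb2gmx regenerates them from types).  Bonds
    spanning two residues are skipped with a warning.
    """
    order: list[str] = list(dict.fromkeys(a.residue_name for a in mol.atoms))
    templates = {name: ResidueTemplate(residue_name=name,
                                       bondedtypes=bondedtypes)
                 for name in order}
    residue_of: dict[int, str] = {}
    for atom in mol.atoms:
        t = templates[atom.residue_name]
        if atom.atom_name in t.atom_names():
            raise TopologyError(
                f"residue {atom.residue_name}: duplicate atom name "
                f"{atom.atom_name!r}; rtp atoms must be uniquely named")
        t.atoms.append(RtpAtom(atom.atom_name, atom.type, atom.charge,
                               atom.charge_group))
        residue_of[atom.index] = atom.residue_name
    for b in mol.bonds:
        i, j = b.atom_indices
        if residue_of[i] != residue_of[j]:
            log.warning("bond %d-%d spans residues %s/%s; omitted from rtp",
                        i, j, residue_of[i], residue_of[j])
            continue
        templates[residue_of[i]].bonds.append(
            (mol.atom(i).atom_name, mol.atom(j).atom_name, None))
    for imp in mol.impropers:
        res = {residue_of[i] for i in imp.atom_indices}
        if len(res) > 1:
            log.warning("improper %s spans residues; omitted from rtp",
                        imp.atom_indices)
            continue
        templates[res.pop()].impropers.append(
            tuple(mol.atom(i).atom_name for i in imp.atom_indices))
    for d in mol.dihedrals:
        if d.inline_params is None:
            continue
        res = {residue_of[i] for i in d.atom_indices}
        if len(res) > 1:
            continue
        templates[res.pop()].explicit_dihedrals.append(
            tuple(mol.atom(i).atom_name for i in d.atom_indices))
    return [templates[name] for name in order]
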