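"""Reader/writer for molecule topologies (.top/.itp) and residue templates
(.rtp), plus the connectivity utilities the virtual-site search needs.

A ``[ moleculetype ]`` block lists atoms with 1-based contiguous indices and
interactions that reference them; proper torsions (funct 1/3/5/9) and
impropers (funct 2/4) both live under ``[ dihedrals ]`` in the file and are
split into separate lists here.  ``#include`` directives are recorded but
not resolved — topologies routinely include force-field files that are not
co-located with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from ._parse import Line, LineReader, parse_float, parse_int, section_name
from .errors import TopologyError, UnknownAtomTypeError
from .ffstore import (AtomTypeDef, ForceFieldStore, _add_atomtype,
                      _parse_atomtype)

log = logging.getLogger(__name__)


@dataclass
class TopAtom:
    index: int                      # 1-based
    type: str
    residue_name: str
    atom_name: str
    charge: float
    mass: Optional[float] = None    # falls back to the atom type's mass
    charge_group: int = 0
    residue_number: int = 1


@dataclass(frozen=True)
class Interaction:
    atom_indices: tuple             # 2-4 1-based indices
    funct: int
    inline_params: Optional[tuple] = None


@dataclass
class MoleculeTopology:
    name: str
    nrexcl: int
    atoms: list[TopAtom] = field(default_factory=list)
    bonds: list[Interaction] = field(default_factory=list)
    pairs: list[Interaction] = field(default_factory=list)
    angles: list[Interaction] = field(default_factory=list)
    dihedrals: list[Interaction] = field(default_factory=list)
    impropers: list[Interaction] = field(default_factory=list)
    constraints: list[Interaction] = field(default_factory=list)
    exclusions: list[list[int]] = field(default_factory=list)
    inline_atomtypes: list[AtomTypeDef] = field(default_factory=list)

    def atom(self, index: int) -> TopAtom:
        return self.atoms[index - 1]


@dataclass
class RtpAtom:
    name: str
    type: str
    charge: float
    charge_group: int


@dataclass
class ResidueTemplate:
    residue_name: str
    atoms: list[RtpAtom] = field(default_factory=list)
    bonds: list[tuple] = field(default_factory=list)        # (name1, name2, params|None)
    impropers: list[tuple] = field(default_factory=list)    # 4-name tuples
    explicit_dihedrals: list[tuple] = field(default_factory=list)
    bondedtypes: Optional[tuple] = None  # funct numbers: bonds angles dih impropers ...

    def atom_names(self) -> set:
        return {a.name for a in self.atoms}


#: default [ bondedtypes ] funct numbers (bonds, angles, dihedrals, impropers)
DEFAULT_BONDEDTYPES = (1, 1, 9, 4)

_IMPROPER_FUNCTS = (2, 4)


# ---------------------------------------------------------------------------
# topology reading


def _parse_top_atom(line: Line, next_index: int) -> TopAtom:
    f = line.fields
    if len(f) < 6:
        raise TopologyError(f"{line.where}: [ atoms ] entry needs at least 6 fields")
    index = parse_int(f[0], line)
    if index != next_index:
        raise TopologyError(
            f"{line.where}: atom indices must be contiguous from 1 "
            f"(expected {next_index}, got {index})")
    charge = parse_float(f[6], line) if len(f) > 6 else 0.0
    mass = parse_float(f[7], line) if len(f) > 7 else None
    return TopAtom(index=index, type=f[1],
                   residue_number=parse_int(f[2], line), residue_name=f[3],
                   atom_name=f[4], charge_group=parse_int(f[5], line),
                   charge=charge, mass=mass)


def _parse_interaction(line: Line, arity: int, n_atoms: int, section: str,
                       default_funct: int = 1) -> Interaction:
    f = line.fields
    if len(f) < arity:
        raise TopologyError(
            f"{line.where}: [ {section} ] entry needs {arity} atom indices")
    idx = tuple(parse_int(t, line) for t in f[:arity])
    for i in idx:
        if not 1 <= i <= n_atoms:
            raise TopologyError(
                f"{line.where}: [ {section} ] references atom {i} but the "
                f"molecule has {n_atoms} atoms")
    funct = parse_int(f[arity], line) if len(f) > arity else default_funct
    params = tuple(parse_float(t, line) for t in f[arity + 1:]) or None
    return Interaction(idx, funct, params)


def _finalize(mol: MoleculeTopology, where: str) -> MoleculeTopology:
    if not mol.atoms:
        raise TopologyError(f"{where}: [ moleculetype ] {mol.name!r} has no "
                            f"[ atoms ] section")
    seen = set()
    for b in mol.bonds:
        i, j = b.atom_indices
        if i == j:
            raise TopologyError(f"molecule {mol.name}: self-bond on atom {i}")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise TopologyError(f"molecule {mol.name}: duplicate bond {key}")
        seen.add(key)
    return mol


def read_topology_text(text: str, path: Optional[Path] = None
                       ) -> list[MoleculeTopology]:
    """Parse all ``[ moleculetype ]`` blocks from topology text."""
    reader = LineReader(resolve_includes=False)
    molecules: list[MoleculeTopology] = []
    file_atomtypes = ForceFieldStore()
    current: Optional[MoleculeTopology] = None
    section: Optional[str] = None
    pending_moltype = False
    for line in reader.read_text(text, path):
        sec = section_name(line)
        if sec is not None:
            section = sec
            pending_moltype = section == "moleculetype"
            continue
        if pending_moltype:
            f = line.fields
            if len(f) < 2:
                raise TopologyError(
                    f"{line.where}: [ moleculetype ] needs a name and nrexcl")
            if current is not None:
                _finalize(current, line.where)
            current = MoleculeTopology(name=f[0], nrexcl=parse_int(f[1], line))
            molecules.append(current)
            pending_moltype = False
            continue
        if section == "atomtypes":
            _add_atomtype(file_atomtypes,
                          _parse_atomtype(line, file_atomtypes.dialect),
                          line.where)
            continue
        if section in ("defaults", "system", "molecules", None):
            continue
        if current is None:
            raise TopologyError(
                f"{line.where}: [ {section} ] entry before any [ moleculetype ]")
        n = len(current.atoms)
        if section == "atoms":
            current.atoms.append(_parse_top_atom(line, n + 1))
        elif section == "bonds":
            current.bonds.append(_parse_interaction(line, 2, n, section))
        elif section == "pairs":
            current.pairs.append(_parse_interaction(line, 2, n, section))
        elif section == "angles":
            current.angles.append(_parse_interaction(line, 3, n, section))
        elif section == "dihedrals":
            inter = _parse_interaction(line, 4, n, section, default_funct=9)
            if inter.funct in _IMPROPER_FUNCTS:
                current.impropers.append(inter)
            else:
                current.dihedrals.append(inter)
        elif section == "constraints":
            current.constraints.append(_parse_interaction(line, 2, n, section))
        elif section == "exclusions":
            idx = [parse_int(t, line) for t in line.fields]
            for i in idx:
                if not 1 <= i <= n:
                    raise TopologyError(
                        f"{line.where}: [ exclusions ] references atom {i}")
            current.exclusions.append(idx)
        else:
            log.debug("%s: ignoring section [ %s ]", line.where, section)
    if current is not None:
        _finalize(current, "<end of file>")
    if not molecules:
        raise TopologyError("no [ moleculetype ] block found")
    inline = list(file_atomtypes.atomtypes.values())
    for mol in molecules:
        mol.inline_atomtypes = list(inline)
    return molecules


def read_topology(source: Union[str, Path]) -> list[MoleculeTopology]:
    """Read one topology file; returns one entry per ``[ moleculetype ]``."""
    path = Path(source)
    if not path.is_file():
        raise TopologyError(f"topology file not found: {path}")
    return read_topology_text(path.read_text(), path)


def select_molecule(molecules: Sequence[MoleculeTopology],
                    name: Optional[str] = None) -> MoleculeTopology:
    """Pick a molecule by name; default is the first (with a warning if
    several are present)."""
    if name is not None:
        for mol in molecules:
            if mol.name == name:
                return mol
        raise TopologyError(
            f"molecule {name!r} not found; available: "
            + ", ".join(m.name for m in molecules))
    if len(molecules) > 1:
        log.warning("topology holds %d molecules; using the first (%s)",
                    len(molecules), molecules[0].name)
    return molecules[0]


# ---------------------------------------------------------------------------
# rtp reading/writing

_RTP_SUBSECTIONS = {"atoms", "bonds", "angles", "dihedrals", "impropers",
                    "exclusions", "cmap", "bondedtypes"}


def read_rtp_text(text: str, path: Optional[Path] = None) -> list[ResidueTemplate]:
    reader = LineReader(resolve_includes=False)
    templates: list[ResidueTemplate] = []
    bondedtypes: Optional[tuple] = None
    current: Optional[ResidueTemplate] = None
    section: Optional[str] = None
    for line in reader.read_text(text, path):
        sec = section_name(line)
        if sec is not None:
            raw = line.text[1:-1].strip()
            if sec in _RTP_SUBSECTIONS:
                section = sec
            else:
                current = ResidueTemplate(residue_name=raw,
                                          bondedtypes=bondedtypes)
                templates.append(current)
                section = None
            continue
        if section == "bondedtypes":
            bondedtypes = tuple(parse_int(t, line) for t in line.fields)
            for t in templates:
                if t.bondedtypes is None:
                    t.bondedtypes = bondedtypes
            continue
        if current is None:
            raise TopologyError(f"{line.where}: entry outside any residue block")
        f = line.fields
        if section == "atoms":
            if len(f) < 4:
                raise TopologyError(
                    f"{line.where}: rtp atom entry needs name/type/charge/group")
            current.atoms.append(RtpAtom(f[0], f[1], parse_float(f[2], line),
                                         parse_int(f[3], line)))
        elif section == "bonds":
            if len(f) < 2:
                raise TopologyError(f"{line.where}: rtp bond needs two atom names")
            params = tuple(parse_float(t, line) for t in f[2:]) or None
            current.bonds.append((f[0], f[1], params))
        elif section == "impropers":
            if len(f) < 4:
                raise TopologyError(f"{line.where}: rtp improper needs four names")
            current.impropers.append(tuple(f[:4]))
        elif section == "dihedrals":
            if len(f) < 4:
                raise TopologyError(f"{line.where}: rtp dihedral needs four names")
            current.explicit_dihedrals.append(tuple(f[:4]))
        # exclusions/cmap: accepted, ignored
    for t in templates:
        names = t.atom_names()
        for n1, n2, _ in t.bonds:
            for n in (n1, n2):
                if not n.startswith(("+", "-")) and n not in names:
                    raise TopologyError(
                        f"residue {t.residue_name}: bond names unknown atom {n!r}")
        for quad in t.impropers + t.explicit_dihedrals:
            for n in quad:
                if not n.startswith(("+", "-")) and n not in names:
                    raise TopologyError(
                        f"residue {t.residue_name}: improper/dihedral names "
                        f"unknown atom {n!r}")
    if not templates:
        raise TopologyError("no residue block found in rtp input")
    return templates


def read_rtp(source: Union[str, Path]) -> list[ResidueTemplate]:
    path = Path(source)
    if not path.is_file():
        raise TopologyError(f"rtp file not found: {path}")
    return read_rtp_text(path.read_text(), path)


def select_residue(templates: Sequence[ResidueTemplate],
                   name: Optional[str] = None) -> ResidueTemplate:
    if name is not None:
        for t in templates:
            if t.residue_name == name:
                return t
        raise TopologyError(
            f"residue {name!r} not found; available: "
            + ", ".join(t.residue_name for t in templates))
    if len(templates) > 1:
        log.warning("rtp holds %d residues; using the first (%s)",
                    len(templates), templates[0].residue_name)
    return templates[0]


def write_rtp(templates: Sequence[ResidueTemplate]) -> str:
    """Emit residue templates as rtp text that re-reads to equal templates."""
    out: list[str] = []
    bondedtypes = next((t.bondedtypes for t in templates
                        if t.bondedtypes is not None), DEFAULT_BONDEDTYPES)
    out.append("[ bondedtypes ]")
    out.append("; bonds  angles  dihedrals  impropers")
    out.append("  " + "  ".join(str(n) for n in bondedtypes))
    for t in templates:
        out.append("")
        out.append(f"[ {t.residue_name} ]")
        out.append(" [ atoms ]")
        for a in t.atoms:
            out.append(f"  {a.name:<6s} {a.type:<6s} {a.charge:9.4f}  "
                       f"{a.charge_group:d}")
        out.append(" [ bonds ]")
        for n1, n2, params in t.bonds:
            tail = ""
            if params:
                tail = "  " + "  ".join(f"{p:.6g}" for p in params)
            out.append(f"  {n1:<6s} {n2:<6s}{tail}")
        if t.impropers:
            out.append(" [ impropers ]")
            for quad in t.impropers:
                out.append("  " + " ".join(f"{n:<6s}" for n in quad))
        if t.explicit_dihedrals:
            out.append(" [ dihedrals ]")
            for quad in t.explicit_dihedrals:
                out.append("  " + " ".join(f"{n:<6s}" for n in quad))
    return "\n".join(out) + "\n"


def template_to_topology(template: ResidueTemplate,
                         store: Optional[ForceFieldStore] = None,
                         nrexcl: int = 3) -> MoleculeTopology:
    """Build a :class:`MoleculeTopology` from a residue template.

    Bonds naming atoms in neighbouring residues (``+``/``-`` prefixes) are
    skipped — a single residue cannot resolve them.  Masses are left to the
    atom-type fallback chain.
    """
    bt = template.bondedtypes or DEFAULT_BONDEDTYPES
    mol = MoleculeTopology(name=template.residue_name, nrexcl=nrexcl)
    index = {}
    for i, a in enumerate(template.atoms, 1):
        if a.name in index:
            raise TopologyError(
                f"residue {template.residue_name}: duplicate atom name {a.name!r}")
        index[a.name] = i
        mol.atoms.append(TopAtom(index=i, type=a.type,
                                 residue_name=template.residue_name,
                                 atom_name=a.name, charge=a.charge,
                                 charge_group=a.charge_group))
    for n1, n2, params in template.bonds:
        if n1.startswith(("+", "-")) or n2.startswith(("+", "-")):
            log.debug("residue %s: skipping inter-residue bond %s-%s",
                      template.residue_name, n1, n2)
            continue
        mol.bonds.append(Interaction((index[n1], index[n2]), bt[0], params))
    for quad in template.impropers:
        if any(n.startswith(("+", "-")) for n in quad):
            continue
        mol.impropers.append(Interaction(tuple(index[n] for n in quad),
                                         bt[3] if len(bt) > 3 else 4, None))
    for quad in template.explicit_dihedrals:
        if any(n.startswith(("+", "-")) for n in quad):
            continue
        mol.dihedrals.append(Interaction(tuple(index[n] for n in quad),
                                         bt[2] if len(bt) > 2 else 9, None))
    return _finalize(mol, f"residue {template.residue_name}")


# ---------------------------------------------------------------------------
# connectivity


def adjacency(mol: MoleculeTopology) -> dict[int, set]:
    """Symmetric bond-graph neighbour map over 1-based atom indices."""
    nbrs: dict[int, set] = {a.index: set() for a in mol.atoms}
    for b in mol.bonds:
        i, j = b.atom_indices
        nbrs[i].add(j)
        nbrs[j].add(i)
    return nbrs


def resolve_atomtype(mol: MoleculeTopology, store: Optional[ForceFieldStore],
                     type_token: str) -> AtomTypeDef:
    """Look an atom type up in the topology's inline types, then the force
    field; absence is an error pointing the user at the inspect command."""
    for at in mol.inline_atomtypes:
        if at.name == type_token:
            return at
    if store is not None and type_token in store.atomtypes:
        return store.atomtypes[type_token]
    raise UnknownAtomTypeError(
        f"atom type {type_token!r} not found in the force field or the "
        f"topology's own [ atomtypes ]; run the 'inspect' subcommand to list "
        f"everything that must be added to the force field first")


def atom_mass(mol: MoleculeTopology, store: Optional[ForceFieldStore],
              atom: TopAtom) -> float:
    """Mass fallback chain: per-atom column > inline atomtypes > force field."""
    if atom.mass is not None:
        return atom.mass
    return resolve_atomtype(mol, store, atom.type).mass


def classify_hydrogens(mol: MoleculeTopology, store: ForceFieldStore
                       ) -> dict[int, str]:
    """Classify every atom as ``"H"`` or ``"heavy"``.

    An atom is hydrogen iff its type's atomic number is 1 when known,
    otherwise iff its mass is at most 3.5 u (covering deuterium).  Masses
    just above that window without a known element (helium territory) are
    classified heavy with a warning.
    """
    out: dict[int, str] = {}
    for atom in mol.atoms:
        atdef = resolve_atomtype(mol, store, atom.type)
        if atdef.atomic_number is not None and not atdef.atomic_number_inferred:
            out[atom.index] = "H" if atdef.atomic_number == 1 else "heavy"
            continue
        mass = atom.mass if atom.mass is not None else atdef.mass
        if mass <= 3.5:
            out[atom.index] = "H"
        else:
            if mass <= 4.5:
                log.warning("atom %s (type %s, mass %.3f u): ambiguous "
                            "element, classified heavy", atom.atom_name,
                            atom.type, mass)
            out[atom.index] = "heavy"
    return out
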