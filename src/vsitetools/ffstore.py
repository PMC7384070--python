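"""Force-field directory model: atom types, bonded types, lookup, formatting.

A GROMACS force field lives in a directory whose entry file
``forcefield.itp`` includes ``ffnonbonded.itp`` (atom types) and
``ffbonded.itp`` (bond/angle/dihedral/constraint types).  This module loads
those into a :class:`ForceFieldStore` with the lookup semantics the rest of
the suite relies on:

* bond and angle lookups are symmetric under reversal of the type tuple;
* dihedral lookups honour the wildcard token ``X`` with the GROMACS-style
  precedence rule "most specific match wins";
* conflicting duplicate definitions raise instead of silently picking one.

Units follow the file conventions: lengths in nm, angles in degrees, masses
in u, energies in kJ/mol.  Trigonometry elsewhere in the package converts
to radians at the point of use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from ._parse import Line, LineReader, parse_float, parse_int, section_name
from .errors import (AmbiguousLookupError, DuplicateDefinitionError,
                     FileFormatError, ForceFieldError)

log = logging.getLogger(__name__)

#: particle-kind letters accepted in [ atomtypes ]; V and D both mean a
#: massless or dummy construction particle.
_PTYPE = {"A": "atom", "S": "shell", "V": "dummy", "D": "dummy"}
_PTYPE_OUT = {"atom": "A", "shell": "S", "dummy": "D"}

#: mass windows (u) used to infer the element when no atomic-number column
#: exists; deliberately narrow so ambiguous types stay unassigned.
_MASS_BANDS = (
    (1, 0.5, 3.5),     # H (incl. deuterium)
    (6, 10.5, 13.5),   # C
    (7, 13.5, 15.1),   # N
    (8, 15.1, 18.4),   # O
    (16, 28.0, 36.0),  # S
)

#: number of parameters expected after the funct column in [ dihedraltypes ]
DIHEDRAL_ARITY = {1: 3, 2: 2, 3: 6, 4: 3, 5: 4, 9: 3}

ELEMENT_SYMBOL = {1: "H", 6: "C", 7: "N", 8: "O", 16: "S"}


def infer_atomic_number(mass: float) -> Optional[int]:
    """Guess the element from the mass, or None when the mass is ambiguous."""
    for z, lo, hi in _MASS_BANDS:
        if lo <= mass <= hi:
            return z
    return None


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AtomTypeDef:
    """One [ atomtypes ] entry (nonbonded parameters and identity)."""

    name: str
    mass: float                      # u
    charge: float                    # e
    particle_kind: str               # "atom" | "dummy" | "shell"
    lj_sigma: float                  # nm
    lj_epsilon: float                # kJ/mol
    atomic_number: Optional[int] = None
    atomic_number_inferred: bool = False
    bonded_type: Optional[str] = None
    definition_known: bool = True    # False for placeholder entries in diffs

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom type name must be nonempty")
        if self.definition_known and (self.mass < 0 or self.lj_epsilon < 0):
            raise ValueError(f"atom type {self.name}: mass and epsilon must be >= 0")


@dataclass(frozen=True)
class BondTypeDef:
    type_i: str
    type_j: str
    funct: int
    b0: float                        # nm
    kb: float                        # kJ/(mol nm^2)

    def key(self) -> tuple:
        return tuple(sorted((self.type_i, self.type_j)))

    def content(self) -> tuple:
        return (self.key(), self.funct, self.b0, self.kb)


@dataclass(frozen=True)
class AngleTypeDef:
    type_i: str
    type_j: str
    type_k: str
    funct: int
    theta0: float                    # degrees
    ktheta: float                    # kJ/(mol rad^2)
    ub_r13: Optional[float] = None   # nm (Urey-Bradley, funct 5)
    ub_kub: Optional[float] = None

    def key(self) -> tuple:
        fwd = (self.type_i, self.type_j, self.type_k)
        return min(fwd, fwd[::-1])

    def content(self) -> tuple:
        return (self.key(), self.funct, self.theta0, self.ktheta,
                self.ub_r13, self.ub_kub)


@dataclass(frozen=True)
class DihedralTypeDef:
    types: tuple  # (type_i, type_j, type_k, type_l); "X" is a wildcard
    funct: int
    params: tuple

    def __post_init__(self):
        arity = DIHEDRAL_ARITY.get(self.funct)
        if arity is None:
            raise ValueError(f"unsupported dihedral funct {self.funct}")
        if len(self.params) != arity:
            raise ValueError(
                f"dihedraltype {self.types} funct {self.funct}: expected "
                f"{arity} parameters, got {len(self.params)}")

    @property
    def specificity(self) -> int:
        return sum(1 for t in self.types if t != "X")


@dataclass(frozen=True)
class ConstraintTypeDef:
    type_i: str
    type_j: str
    funct: int                       # 1 generates exclusions, 2 does not
    d0: float                        # nm

    def key(self) -> tuple:
        return tuple(sorted((self.type_i, self.type_j)))


@dataclass
class Dialect:
    """Column layout observed in the source [ atomtypes ] section."""

    atomtypes_has_bonded_type: bool = False
    atomtypes_has_atomic_number: bool = True


@dataclass
class ForceFieldStore:
    atomtypes: dict[str, AtomTypeDef] = field(default_factory=dict)
    bondtypes: list[BondTypeDef] = field(default_factory=list)
    angletypes: list[AngleTypeDef] = field(default_factory=list)
    dihedraltypes: list[DihedralTypeDef] = field(default_factory=list)
    constrainttypes: list[ConstraintTypeDef] = field(default_factory=list)
    pairtypes: list[BondTypeDef] = field(default_factory=list)
    atp_masses: dict[str, float] = field(default_factory=dict)
    dialect: Dialect = field(default_factory=Dialect)
    source_dir: Optional[Path] = None


# ---------------------------------------------------------------------------
# parsing


def _parse_atomtype(line: Line, dialect: Dialect) -> AtomTypeDef:
    f = line.fields
    if len(f) < 6:
        raise FileFormatError(f"{line.where}: atomtypes entry too short")
    p = len(f) - 3
    if f[p].upper() not in _PTYPE:
        raise FileFormatError(
            f"{line.where}: cannot locate particle-type column in atomtypes entry")
    name = f[0]
    mass = parse_float(f[p - 2], line)
    charge = parse_float(f[p - 1], line)
    sigma = parse_float(f[p + 1], line)
    epsilon = parse_float(f[p + 2], line)
    extras = f[1:p - 2]
    bonded_type = None
    atomic_number: Optional[int] = None
    if len(extras) == 1:
        try:
            atomic_number = int(extras[0])
        except ValueError:
            bonded_type = extras[0]
    elif len(extras) == 2:
        bonded_type = extras[0]
        atomic_number = parse_int(extras[1], line)
    elif len(extras) > 2:
        raise FileFormatError(f"{line.where}: unrecognized atomtypes layout")
    dialect.atomtypes_has_bonded_type = bonded_type is not None
    dialect.atomtypes_has_atomic_number = atomic_number is not None
    inferred = False
    if atomic_number is None:
        atomic_number = infer_atomic_number(mass)
        inferred = atomic_number is not None
    return AtomTypeDef(name=name, mass=mass, charge=charge,
                       particle_kind=_PTYPE[f[p].upper()],
                       lj_sigma=sigma, lj_epsilon=epsilon,
                       atomic_number=atomic_number,
                       atomic_number_inferred=inferred,
                       bonded_type=bonded_type)


def _parse_bondtype(line: Line) -> BondTypeDef:
    f = line.fields
    if len(f) < 5:
        raise FileFormatError(f"{line.where}: bondtypes entry needs 5 fields")
    b0 = parse_float(f[3], line)
    if b0 <= 0:
        raise FileFormatError(f"{line.where}: bond length must be positive")
    return BondTypeDef(f[0], f[1], parse_int(f[2], line), b0,
                       parse_float(f[4], line))


def _parse_angletype(line: Line) -> AngleTypeDef:
    f = line.fields
    if len(f) < 6:
        raise FileFormatError(f"{line.where}: angletypes entry needs 6 fields")
    theta0 = parse_float(f[4], line)
    if not 0.0 < theta0 < 180.0:
        raise FileFormatError(
            f"{line.where}: reference angle must lie in (0, 180) degrees")
    ub_r13 = parse_float(f[6], line) if len(f) > 7 else None
    ub_kub = parse_float(f[7], line) if len(f) > 7 else None
    return AngleTypeDef(f[0], f[1], f[2], parse_int(f[3], line), theta0,
                        parse_float(f[5], line), ub_r13, ub_kub)


def _parse_dihedraltype(line: Line) -> DihedralTypeDef:
    f = line.fields

    def is_int(tok: str) -> bool:
        try:
            int(tok)
            return True
        except ValueError:
            return False

    def is_num(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    # old two-atom form: "tj tk funct params..." (implicit X at ends)
    if len(f) >= 3 and is_int(f[2]) and int(f[2]) in DIHEDRAL_ARITY \
            and all(is_num(t) for t in f[3:]):
        types = ("X", f[0], f[1], "X")
        funct = int(f[2])
        params = tuple(parse_float(t, line) for t in f[3:])
    else:
        if len(f) < 5:
            raise FileFormatError(f"{line.where}: dihedraltypes entry too short")
        types = (f[0], f[1], f[2], f[3])
        funct = parse_int(f[4], line)
        params = tuple(parse_float(t, line) for t in f[5:])
    arity = DIHEDRAL_ARITY.get(funct)
    if arity is None:
        raise FileFormatError(f"{line.where}: unsupported dihedral funct {funct}")
    if len(params) != arity:
        raise FileFormatError(
            f"{line.where}: funct {funct} dihedral needs {arity} parameters, "
            f"got {len(params)}")
    if funct in (1, 4, 9):
        params = (params[0], params[1], float(int(params[2])))
    return DihedralTypeDef(types, funct, params)


def _parse_constrainttype(line: Line) -> ConstraintTypeDef:
    f = line.fields
    if len(f) < 4:
        raise FileFormatError(f"{line.where}: constrainttypes entry needs 4 fields")
    d0 = parse_float(f[3], line)
    if d0 <= 0:
        raise FileFormatError(f"{line.where}: constraint length must be positive")
    return ConstraintTypeDef(f[0], f[1], parse_int(f[2], line), d0)


def _add_atomtype(store: ForceFieldStore, at: AtomTypeDef, where: str) -> None:
    prev = store.atomtypes.get(at.name)
    if prev is not None and (prev.mass, prev.charge, prev.lj_sigma,
                             prev.lj_epsilon) != (at.mass, at.charge,
                                                  at.lj_sigma, at.lj_epsilon):
        raise DuplicateDefinitionError(
            f"{where}: atom type {at.name!r} redefined with different values")
    store.atomtypes[at.name] = at


def parse_ff_lines(lines: Iterable[Line], store: ForceFieldStore) -> ForceFieldStore:
    """Accumulate force-field sections from a cleaned line stream."""
    section: Optional[str] = None
    for line in lines:
        sec = section_name(line)
        if sec is not None:
            section = sec
            continue
        if section == "atomtypes":
            _add_atomtype(store, _parse_atomtype(line, store.dialect), line.where)
        elif section == "bondtypes":
            store.bondtypes.append(_parse_bondtype(line))
        elif section == "angletypes":
            store.angletypes.append(_parse_angletype(line))
        elif section == "dihedraltypes":
            store.dihedraltypes.append(_parse_dihedraltype(line))
        elif section == "constrainttypes":
            store.constrainttypes.append(_parse_constrainttype(line))
        elif section == "pairtypes":
            store.pairtypes.append(_parse_bondtype(line))
        elif section in ("defaults", "nonbond_params", "implicit_genborn_params",
                         "cmaptypes", None):
            continue
        else:
            log.debug("%s: ignoring section [ %s ]", line.where, section)
    return store


def parse_ff_text(text: str, store: Optional[ForceFieldStore] = None) -> ForceFieldStore:
    """Parse force-field sections from a text fragment (no includes)."""
    if store is None:
        store = ForceFieldStore()
    reader = LineReader(resolve_includes=False)
    return parse_ff_lines(reader.read_text(text), store)


def read_forcefield(dir_path: Union[str, Path]) -> ForceFieldStore:
    """Load a GROMACS force-field directory into a :class:`ForceFieldStore`.

    The directory must contain ``forcefield.itp`` (the entry file, whose
    ``#include`` directives are resolved relative to the directory) plus
    ``ffnonbonded.itp`` and ``ffbonded.itp``.  ``atomtypes.atp`` is read
    when present and kept as a name-to-mass map.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise ForceFieldError(f"force-field directory not found: {dir_path}")
    for required in ("forcefield.itp", "ffnonbonded.itp", "ffbonded.itp"):
        if not (dir_path / required).is_file():
            raise ForceFieldError(
                f"force-field directory {dir_path} is missing {required}")
    store = ForceFieldStore(source_dir=dir_path)
    reader = LineReader(resolve_includes=True, include_root=dir_path)
    parse_ff_lines(reader.read_path(dir_path / "forcefield.itp"), store)
    atp = dir_path / "atomtypes.atp"
    if atp.is_file():
        for line in LineReader(resolve_includes=False).read_path(atp):
            f = line.fields
            if len(f) >= 2:
                store.atp_masses[f[0]] = parse_float(f[1], line)
    return store


# ---------------------------------------------------------------------------
# lookup


def _unique_or_raise(matches: Sequence, what: str):
    distinct: dict[tuple, object] = {}
    for m in matches:
        distinct.setdefault(m.content(), m)
    if not distinct:
        return None
    if len(distinct) > 1:
        raise DuplicateDefinitionError(
            f"conflicting duplicate {what} definitions: "
            + "; ".join(repr(m) for m in distinct.values()))
    return next(iter(distinct.values()))


def lookup_bond(store: ForceFieldStore, t1: str, t2: str) -> Optional[BondTypeDef]:
    """Find the bond type for ``(t1, t2)``; symmetric in its arguments."""
    key = tuple(sorted((t1, t2)))
    return _unique_or_raise([b for b in store.bondtypes if b.key() == key],
                            f"bond {t1}-{t2}")


def lookup_angle(store: ForceFieldStore, t1: str, t2: str, t3: str
                 ) -> Optional[AngleTypeDef]:
    """Find the angle type for ``(t1, t2, t3)``; symmetric under reversal."""
    key = min((t1, t2, t3), (t3, t2, t1))
    return _unique_or_raise([a for a in store.angletypes if a.key() == key],
                            f"angle {t1}-{t2}-{t3}")


def lookup_dihedral(store: ForceFieldStore, t1: str, t2: str, t3: str, t4: str,
                    funct: int) -> list[DihedralTypeDef]:
    """Find dihedral types for a quadruple, honouring the ``X`` wildcard.

    Returns the list of entries at the best (most specific) match level —
    a list because a funct-9 torsion is legitimately described by several
    entries with different multiplicities.  An empty list means no match.
    Equally specific matches that genuinely conflict raise
    :class:`AmbiguousLookupError`.
    """
    query = (t1, t2, t3, t4)

    def matches(entry: DihedralTypeDef) -> bool:
        return any(all(et == "X" or et == qt for et, qt in zip(entry.types, q))
                   for q in (query, query[::-1]))

    cands = [d for d in store.dihedraltypes if d.funct == funct and matches(d)]
    if not cands:
        return []
    best = max(d.specificity for d in cands)
    top = []
    for d in cands:
        if d.specificity == best and d not in top:
            top.append(d)
    if funct == 9:
        by_mult: dict[int, DihedralTypeDef] = {}
        for d in top:
            n = int(d.params[2])
            if n in by_mult and by_mult[n].params != d.params:
                raise AmbiguousLookupError(
                    f"dihedral {query} funct 9 multiplicity {n}: conflicting "
                    f"entries {by_mult[n]} and {d}")
            by_mult.setdefault(n, d)
        return list(by_mult.values())
    if len(top) > 1:
        raise AmbiguousLookupError(
            f"dihedral {query} funct {funct}: equally specific matches "
            + "; ".join(repr(d.types) for d in top))
    return top


# ---------------------------------------------------------------------------
# formatting

# printing precision: lengths 5 decimals (nm), masses/charges 4 decimals,
# energies and force constants 6 significant digits.


def _fmt_len(v: float) -> str:
    return f"{v:.5f}"


def _fmt_mass(v: float) -> str:
    return f"{v:.4f}"


def _fmt_e(v: float) -> str:
    return f"{v:.6g}"


def _fmt_angle(v: float) -> str:
    return f"{v:.4f}"


def format_atomtype(at: AtomTypeDef, dialect: Dialect) -> str:
    cols = [f"{at.name:<6s}"]
    if dialect.atomtypes_has_bonded_type:
        cols.append(f"{at.bonded_type or at.name:<6s}")
    if dialect.atomtypes_has_atomic_number:
        cols.append(f"{at.atomic_number if at.atomic_number is not None else 0:>3d}")
    cols += [f"{_fmt_mass(at.mass):>10s}", f"{_fmt_mass(at.charge):>9s}",
             f"{_PTYPE_OUT[at.particle_kind]:>2s}",
             f"{_fmt_len(at.lj_sigma):>10s}", f"{_fmt_e(at.lj_epsilon):>12s}"]
    return "  ".join(cols)


def format_bondtype(b: BondTypeDef) -> str:
    return (f"{b.type_i:<6s}  {b.type_j:<6s}  {b.funct:d}  "
            f"{_fmt_len(b.b0):>9s}  {_fmt_e(b.kb):>12s}")


def format_angletype(a: AngleTypeDef) -> str:
    s = (f"{a.type_i:<6s}  {a.type_j:<6s}  {a.type_k:<6s}  {a.funct:d}  "
         f"{_fmt_angle(a.theta0):>9s}  {_fmt_e(a.ktheta):>12s}")
    if a.ub_r13 is not None and a.ub_kub is not None:
        s += f"  {_fmt_len(a.ub_r13):>9s}  {_fmt_e(a.ub_kub):>12s}"
    return s


def format_dihedral_params(funct: int, params: Sequence[float]) -> str:
    if funct in (1, 4, 9):
        return (f"{_fmt_angle(params[0]):>9s}  {_fmt_e(params[1]):>12s}  "
                f"{int(params[2]):d}")
    if funct == 2:
        return f"{_fmt_angle(params[0]):>9s}  {_fmt_e(params[1]):>12s}"
    return "  ".join(f"{_fmt_e(p):>10s}" for p in params)


def format_dihedraltype(d: DihedralTypeDef) -> str:
    head = "  ".join(f"{t:<6s}" for t in d.types)
    return f"{head}  {d.funct:d}  {format_dihedral_params(d.funct, d.params)}"


def format_constrainttype(c: ConstraintTypeDef) -> str:
    return f"{c.type_i:<6s}  {c.type_j:<6s}  {c.funct:d}  {_fmt_len(c.d0):>9s}"


_SECTION_ORDER = ("atomtypes", "bondtypes", "angletypes", "dihedraltypes",
                  "constrainttypes")


def format_ff_blocks(items: Iterable, dialect: Optional[Dialect] = None) -> str:
    """Format typed parameter entries as paste-ready ``[ section ]`` blocks.

    Items may mix the five entry kinds; they are grouped into sections in
    canonical order.  The output re-parses (via :func:`parse_ff_text`) to
    entries equal to the input within the declared printing precision.
    An empty item list yields empty text.
    """
    if dialect is None:
        dialect = Dialect()
    groups: dict[str, list[str]] = {s: [] for s in _SECTION_ORDER}
    for item in items:
        if isinstance(item, AtomTypeDef):
            groups["atomtypes"].append(format_atomtype(item, dialect))
        elif isinstance(item, BondTypeDef):
            groups["bondtypes"].append(format_bondtype(item))
        elif isinstance(item, AngleTypeDef):
            groups["angletypes"].append(format_angletype(item))
        elif isinstance(item, DihedralTypeDef):
            groups["dihedraltypes"].append(format_dihedraltype(item))
        elif isinstance(item, ConstraintTypeDef):
            groups["constrainttypes"].append(format_constrainttype(item))
        else:
            raise TypeError(f"cannot format {type(item).__name__}")
    blocks = []
    for sec in _SECTION_ORDER:
        if groups[sec]:
            blocks.append(f"[ {sec} ]\n" + "\n".join(groups[sec]) + "\n")
    return "\n".join(blocks)


def all_entries(store: ForceFieldStore) -> list:
    """All typed entries of a store in section order (for round-tripping)."""
    return (list(store.atomtypes.values()) + list(store.bondtypes)
            + list(store.angletypes) + list(store.dihedraltypes)
            + list(store.constrainttypes))
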