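"""Dummy-mass construction for threefold hydrogen groups and angle
constraints for hydroxyl-like groups.

The bond-vibration frequencies of hydrogens limit the MD timestep.  For a
freely spinning -CH3/-NH3 group the hydrogens cannot be rebuilt from bonded
heavy atoms alone, so the whole group's mass is moved onto two dummy
particles placed symmetrically about the rotation axis; constrained to each
other and to the anchor atom, they preserve the group's total mass, centre
of mass, and moment of inertia about the axis, while the hydrogens become
massless virtual sites.  For -OH/-SH a single hydrogen-to-anchor distance
constraint freezes the bending angle while leaving torsional rotation free.

Everything here is reconstructed from *equilibrium* force-field parameters:
the anchor-center bond length b_AX, the center-hydrogen bond length b_XH,
and the tilt alpha of the C-H (O-H) bond away from the extended axis.
With the anchor at the origin and the axis along z:

    z_H = b_AX + b_XH cos(alpha)        hydrogen height on the axis
    r_H = b_XH sin(alpha)               hydrogen distance from the axis
    m_tot = m_X + 3 m_H
    z_com = (m_X b_AX + 3 m_H z_H) / m_tot
    I_axis = 3 m_H r_H^2

and the two dummies of mass m_tot/2 sit at (z_com, +/- r_d) with
r_d = sqrt(I_axis / m_tot), giving the constraint lengths
d_DD = 2 r_d and d_DA = sqrt(z_com^2 + r_d^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import (GeometryError, MissingParameterError,
                     UnknownAtomTypeError)
from .ffstore import (AtomTypeDef, ConstraintTypeDef, ELEMENT_SYMBOL,
                      ForceFieldStore, format_ff_blocks, lookup_angle,
                      lookup_bond)
from .topio import (MoleculeTopology, adjacency, atom_mass,
                    classify_hydrogens, resolve_atomtype)

log = logging.getLogger(__name__)

#: two constructions sharing a dummy type must agree within these tolerances
LENGTH_TOL = 1e-5   # nm
MASS_TOL = 1e-4     # u

#: emitted constraints use funct 2: they are geometric couplings, not
#: chemical bonds, and must not generate extra exclusions
CONSTRAINT_FUNCT = 2

#: warn when explicit A-X-H and H-X-H-derived tilts disagree by more
ANGLE_CONSISTENCY_TOL_DEG = 0.5


@dataclass
class HydrogenGroup:
    """A detected -XH3 (threefold) or -OH/-SH (single_bent) group."""

    kind: str                    # "threefold" | "single_bent"
    center: int                  # atom index of the C/N (or O/S)
    anchor: int                  # the single heavy neighbour of center
    hydrogens: tuple             # 1 or 3 atom indices
    center_mass: float           # u
    hydrogen_mass: float         # u (mean over the hydrogens)
    center_element: Optional[int] = None


@dataclass
class GroupGeometry:
    """Equilibrium geometry of a hydrogen group, from force-field entries."""

    b_ax: float                  # nm, anchor-center bond
    b_xh: float                  # nm, center-hydrogen bond
    alpha: float                 # radians, tilt of X-H off the A->X axis
    sources: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.alpha < math.pi):
            raise GeometryError(f"tilt angle {math.degrees(self.alpha):.2f} "
                                f"degrees outside (0, 180)")
        if self.b_ax <= 0 or self.b_xh <= 0:
            raise GeometryError("bond lengths must be positive")


@dataclass
class MassMoments:
    """Total mass, axial centre of mass, and axial moment of inertia."""

    m_tot: float                 # u
    z_com: float                 # nm, origin at the anchor, axis toward center
    i_axis: float                # u nm^2, about the anchor-center axis


@dataclass
class DummyConstruction:
    """Two-dummy replacement of a threefold group."""

    group: HydrogenGroup
    moments: MassMoments
    dummy_mass: float            # u, each dummy (= m_tot / 2)
    r_d: float                   # nm, dummy distance from the axis
    d_dd: float                  # nm, dummy-dummy constraint
    d_da: float                  # nm, dummy-anchor constraint
    anchor_type: str
    name_root: str               # e.g. "MCH3"
    dummy_type_name: Optional[str] = None


@dataclass
class AngleConstraintOut:
    """Hydrogen-anchor constraint freezing a hydroxyl-like bending angle."""

    hydrogen: int
    anchor: int
    type_pair: tuple             # (hydrogen type, anchor type)
    d0: float                    # nm


# ---------------------------------------------------------------------------
# group detection


def find_groups(mol: MoleculeTopology, store: ForceFieldStore
                ) -> list[HydrogenGroup]:
    """Detect hydrogen groups eligible for virtual-site treatment.

    A candidate center is any heavy atom bonded to exactly one other heavy
    atom.  Three bonded hydrogens make a threefold group; a single bonded
    hydrogen on an oxygen or sulfur makes a bent (hydroxyl-like) group.
    Other patterns (-NH2, single H on carbon, ...) are skipped with a
    warning — no virtual-site model is generated for them here.
    """
    cls = classify_hydrogens(mol, store)
    nbrs = adjacency(mol)
    groups: list[HydrogenGroup] = []
    for atom in mol.atoms:
        if cls[atom.index] == "H":
            continue
        heavies = sorted(n for n in nbrs[atom.index] if cls[n] == "heavy")
        hydros = sorted(n for n in nbrs[atom.index] if cls[n] == "H")
        if len(heavies) != 1:
            continue
        atdef = resolve_atomtype(mol, store, atom.type)
        element = atdef.atomic_number
        h_masses = [atom_mass(mol, store, mol.atom(h)) for h in hydros]
        if len(hydros) == 3:
            if max(h_masses) - min(h_masses) > MASS_TOL:
                log.warning("group at atom %d: hydrogen masses differ by "
                            "%.4f u; using the mean", atom.index,
                            max(h_masses) - min(h_masses))
            groups.append(HydrogenGroup(
                kind="threefold", center=atom.index, anchor=heavies[0],
                hydrogens=tuple(hydros),
                center_mass=atom_mass(mol, store, atom),
                hydrogen_mass=sum(h_masses) / 3.0, center_element=element))
        elif len(hydros) == 1 and element in (8, 16):
            groups.append(HydrogenGroup(
                kind="single_bent", center=atom.index, anchor=heavies[0],
                hydrogens=tuple(hydros),
                center_mass=atom_mass(mol, store, atom),
                hydrogen_mass=h_masses[0], center_element=element))
        elif hydros:
            log.warning("atom %d (%s): %d bonded hydrogen(s) on element %s "
                        "- no virtual-site model for this group, skipped",
                        atom.index, atom.atom_name, len(hydros),
                        ELEMENT_SYMBOL.get(element, "?"))
    return groups


# ---------------------------------------------------------------------------
# geometry from equilibrium parameters


def _inline_bond_b0(mol: MoleculeTopology, i: int, j: int) -> Optional[float]:
    for b in mol.bonds:
        if set(b.atom_indices) == {i, j} and b.inline_params:
            return b.inline_params[0]
    return None


def _bond_length(mol: MoleculeTopology, store: ForceFieldStore,
                 i: int, j: int) -> float:
    b0 = _inline_bond_b0(mol, i, j)
    if b0 is not None:
        return b0
    ti, tj = mol.atom(i).type, mol.atom(j).type
    entry = lookup_bond(store, ti, tj)
    if entry is None:
        raise MissingParameterError(
            f"no bond parameters for type pair ({ti}, {tj}) "
            f"(atoms {i}-{j})")
    return entry.b0


def _angle_theta0(mol: MoleculeTopology, store: ForceFieldStore,
                  i: int, j: int, k: int) -> Optional[float]:
    """Equilibrium angle i-j-k in degrees, inline params first, else by type."""
    for a in mol.angles:
        if a.atom_indices in ((i, j, k), (k, j, i)) and a.inline_params:
            return a.inline_params[0]
    ti, tj, tk = (mol.atom(x).type for x in (i, j, k))
    entry = lookup_angle(store, ti, tj, tk)
    return entry.theta0 if entry is not None else None


def _mean(values: Sequence[float], what: str, tol: float) -> float:
    if max(values) - min(values) > tol:
        log.warning("%s values differ (spread %.6g); using the mean",
                    what, max(values) - min(values))
    return sum(values) / len(values)


def alpha_from_hxh(theta_hxh_deg: float) -> float:
    """Tilt angle from the H-X-H angle of a threefold-symmetric group.

    Threefold symmetry ties the two angles together through
    cos(theta_HXH) = (3 cos^2(alpha) - 1) / 2.
    """
    val = (2.0 * math.cos(math.radians(theta_hxh_deg)) + 1.0) / 3.0
    if not 0.0 <= val <= 1.0:
        raise GeometryError(
            f"H-X-H angle {theta_hxh_deg:.2f} degrees is incompatible with "
            f"threefold symmetry (needs to be at most 120 degrees)")
    return math.acos(math.sqrt(val))


def group_geometry(group: HydrogenGroup, mol: MoleculeTopology,
                   store: ForceFieldStore) -> GroupGeometry:
    """Reconstruct the equilibrium geometry of a hydrogen group.

    The tilt comes from the anchor-center-hydrogen angle when available
    (alpha = 180 degrees - theta_AXH); for threefold groups the H-X-H angle
    is used as a fallback through the threefold-symmetry identity.  When
    both are available and disagree the anchor-relative angle wins, with a
    warning.
    """
    a, x = group.anchor, group.center
    sources: dict = {}
    b_ax = _bond_length(mol, store, a, x)
    sources["b_ax"] = (mol.atom(a).type, mol.atom(x).type)
    b_xh = _mean([_bond_length(mol, store, x, h) for h in group.hydrogens],
                 f"center-hydrogen bond lengths around atom {x}", LENGTH_TOL)
    sources["b_xh"] = (mol.atom(x).type, mol.atom(group.hydrogens[0]).type)

    axh = [t for h in group.hydrogens
           if (t := _angle_theta0(mol, store, a, x, h)) is not None]
    alpha_axh = None
    if axh:
        theta = _mean(axh, f"anchor-center-H angles around atom {x}", 1e-6)
        alpha_axh = math.radians(180.0 - theta)
        sources["alpha"] = ("A-X-H", (mol.atom(a).type, mol.atom(x).type,
                                      mol.atom(group.hydrogens[0]).type))
    alpha_hxh = None
    if group.kind == "threefold":
        hxh = [t for h1 in group.hydrogens for h2 in group.hydrogens
               if h1 < h2
               and (t := _angle_theta0(mol, store, h1, x, h2)) is not None]
        if hxh:
            alpha_hxh = alpha_from_hxh(
                _mean(hxh, f"H-X-H angles around atom {x}", 1e-6))
    if alpha_axh is not None and alpha_hxh is not None:
        if abs(math.degrees(alpha_axh - alpha_hxh)) > ANGLE_CONSISTENCY_TOL_DEG:
            log.warning(
                "group at atom %d: A-X-H angle implies tilt %.3f degrees but "
                "H-X-H implies %.3f; using the anchor-relative value", x,
                math.degrees(alpha_axh), math.degrees(alpha_hxh))
        alpha = alpha_axh
    elif alpha_axh is not None:
        alpha = alpha_axh
    elif alpha_hxh is not None:
        alpha = alpha_hxh
        sources["alpha"] = ("H-X-H", (mol.atom(group.hydrogens[0]).type,
                                      mol.atom(x).type,
                                      mol.atom(group.hydrogens[-1]).type))
    else:
        raise MissingParameterError(
            f"no angle parameters fixing the geometry of the group at atom "
            f"{x}: neither ({mol.atom(a).type}, {mol.atom(x).type}, "
            f"{mol.atom(group.hydrogens[0]).type}) nor an H-X-H entry is "
            f"defined")
    return GroupGeometry(b_ax=b_ax, b_xh=b_xh, alpha=alpha, sources=sources)


# ---------------------------------------------------------------------------
# mass moments and dummy construction


def mass_moments(geom: GroupGeometry, group: HydrogenGroup) -> MassMoments:
    """Mass moments of a threefold group about the anchor-center axis."""
    z_h = geom.b_ax + geom.b_xh * math.cos(geom.alpha)
    r_h = geom.b_xh * math.sin(geom.alpha)
    m_x, m_h = group.center_mass, group.hydrogen_mass
    m_tot = m_x + 3.0 * m_h
    z_com = (m_x * geom.b_ax + 3.0 * m_h * z_h) / m_tot
    i_axis = 3.0 * m_h * r_h * r_h
    return MassMoments(m_tot=m_tot, z_com=z_com, i_axis=i_axis)


def build_dummies(mm: MassMoments, group: HydrogenGroup,
                  mol: MoleculeTopology) -> DummyConstruction:
    """Place two equal dummy masses reproducing a group's mass moments.

    Each dummy carries half the total mass at axial height z_com and radial
    offset r_d = sqrt(I_axis / m_tot); by construction the pair reproduces
    m_tot exactly and z_com / I_axis identically.
    """
    if mm.i_axis <= 0:
        raise GeometryError(
            f"group at atom {group.center}: axial moment of inertia is not "
            f"positive; the two-dummy construction is degenerate")
    r_d = math.sqrt(mm.i_axis / mm.m_tot)
    sym = ELEMENT_SYMBOL.get(group.center_element, "X")
    return DummyConstruction(
        group=group, moments=mm, dummy_mass=mm.m_tot / 2.0, r_d=r_d,
        d_dd=2.0 * r_d, d_da=math.hypot(mm.z_com, r_d),
        anchor_type=mol.atom(group.anchor).type, name_root=f"M{sym}H3")


def law_of_cosines(b1: float, b2: float, theta_deg: float) -> float:
    """Third side of a triangle with sides b1, b2 and included angle theta.

    The collinear (180 degrees) and folded (0 degrees) limits are returned
    exactly as b1 + b2 and |b1 - b2|.
    """
    t = theta_deg % 360.0
    t = min(t, 360.0 - t)
    if abs(t - 180.0) < 1e-12:
        return b1 + b2
    if t < 1e-12:
        return abs(b1 - b2)
    return math.sqrt(b1 * b1 + b2 * b2
                     - 2.0 * b1 * b2 * math.cos(math.radians(t)))


def angle_constraint(group: HydrogenGroup, geom: GroupGeometry,
                     mol: MoleculeTopology) -> AngleConstraintOut:
    """Hydrogen-anchor constraint length for a bent (-OH/-SH) group."""
    if group.kind != "single_bent":
        raise ValueError("angle constraints apply to single_bent groups only")
    theta_deg = 180.0 - math.degrees(geom.alpha)
    d0 = law_of_cosines(geom.b_ax, geom.b_xh, theta_deg)
    h = group.hydrogens[0]
    return AngleConstraintOut(
        hydrogen=h, anchor=group.anchor,
        type_pair=(mol.atom(h).type, mol.atom(group.anchor).type), d0=d0)


# ---------------------------------------------------------------------------
# orchestration and emission


def derive_vsite_parameters(mol: MoleculeTopology, store: ForceFieldStore
                            ) -> tuple:
    """Run the full pipeline on one molecule.

    Every atom type must already be present in the force field — geometry
    and mass lookups work purely from force-field entries, so a molecule
    carrying its own new types has to go through the inspect/incorporate
    step first.  Returns ``(constructions, angle_constraints)`` for all
    detected groups.
    """
    missing = sorted({a.type for a in mol.atoms} - set(store.atomtypes))
    if missing:
        raise UnknownAtomTypeError(
            f"atom type(s) {', '.join(missing)} are not present in the "
            f"force field; run the 'inspect' subcommand and incorporate its "
            f"output into the force-field files first")
    constructions: list[DummyConstruction] = []
    constraints: list[AngleConstraintOut] = []
    for group in find_groups(mol, store):
        geom = group_geometry(group, mol, store)
        if group.kind == "threefold":
            mm = mass_moments(geom, group)
            constructions.append(build_dummies(mm, group, mol))
        else:
            constraints.append(angle_constraint(group, geom, mol))
    return constructions, constraints


def _match_existing_dummy(store: ForceFieldStore, mass: float, d_dd: float
                          ) -> Optional[str]:
    """Name of a force-field dummy type already equivalent to a construction."""
    for name, at in store.atomtypes.items():
        if at.particle_kind != "dummy" or abs(at.mass - mass) > MASS_TOL:
            continue
        for c in store.constrainttypes:
            if c.type_i == name and c.type_j == name \
                    and abs(c.d0 - d_dd) <= LENGTH_TOL:
                return name
    return None


def emit_vsite_parameters(constructions: Sequence[DummyConstruction],
                          constraints: Sequence[AngleConstraintOut],
                          store: ForceFieldStore) -> str:
    """Format dummy atom types and constraint lengths as force-field blocks.

    Constructions identical within tolerance share one dummy type; names are
    the element root (MCH3, MNH3, ...) plus a letter suffix chosen to avoid
    every name already in the force field.  Existing equivalent dummy types
    in the store are reused rather than re-emitted.  Output is paste-ready
    ffnonbonded/ffbonded fragment text.
    """
    atomtypes: list[AtomTypeDef] = []
    ctypes: list[ConstraintTypeDef] = []
    taken = set(store.atomtypes)

    groups: list[list[DummyConstruction]] = []
    for con in constructions:
        for g in groups:
            ref = g[0]
            if (ref.name_root == con.name_root
                    and abs(ref.dummy_mass - con.dummy_mass) <= MASS_TOL
                    and abs(ref.d_dd - con.d_dd) <= LENGTH_TOL
                    and abs(ref.d_da - con.d_da) <= LENGTH_TOL):
                g.append(con)
                break
        else:
            groups.append([con])

    for g in groups:
        ref = g[0]
        existing = _match_existing_dummy(store, ref.dummy_mass, ref.d_dd)
        if existing is not None:
            name = existing
            log.info("reusing existing dummy type %s", name)
        else:
            for suffix in "ABCDEFGHIJKLMNOPQRSTUVWXYZ":
                name = f"{ref.name_root}{suffix}"
                if name not in taken:
                    break
            else:
                raise GeometryError(
                    f"no free dummy type name left for root {ref.name_root}")
            taken.add(name)
            atomtypes.append(AtomTypeDef(
                name=name, mass=ref.dummy_mass, charge=0.0,
                particle_kind="dummy", lj_sigma=0.0, lj_epsilon=0.0,
                atomic_number=0))
            ctypes.append(ConstraintTypeDef(name, name, CONSTRAINT_FUNCT,
                                            ref.d_dd))
        for con in g:
            con.dummy_type_name = name
        for anchor_type in dict.fromkeys(c.anchor_type for c in g):
            entry = ConstraintTypeDef(name, anchor_type, CONSTRAINT_FUNCT,
                                      ref.d_da)
            if existing is None or not any(
                    c.key() == entry.key() and abs(c.d0 - entry.d0) <= LENGTH_TOL
                    for c in store.constrainttypes):
                ctypes.append(entry)

    seen_pairs: dict[tuple, float] = {}
    for ac in constraints:
        key = tuple(sorted(ac.type_pair))
        if any(c.key() == key and abs(c.d0 - ac.d0) <= LENGTH_TOL
               for c in store.constrainttypes):
            log.info("constraint %s already present in the force field", key)
            continue
        if key in seen_pairs:
            if abs(seen_pairs[key] - ac.d0) > LENGTH_TOL:
                log.warning("constraint for type pair %s already emitted with "
                            "d0 %.5f nm; ignoring conflicting %.5f nm", key,
                            seen_pairs[key], ac.d0)
            continue
        seen_pairs[key] = ac.d0
        ctypes.append(ConstraintTypeDef(ac.type_pair[0], ac.type_pair[1],
                                        CONSTRAINT_FUNCT, ac.d0))

    if not atomtypes and not ctypes:
        return ""
    return format_ff_blocks(atomtypes + ctypes, store.dialect)
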