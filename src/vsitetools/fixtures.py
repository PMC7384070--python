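"""Deterministic generators for a minimal force field and test molecules.

Nothing here is downloaded or copied from a published force field: the
equilibrium values are chosen within chemically typical ranges (C-H bonds
near 0.109 nm, tetrahedral-ish angles, ...) purely so that the geometry
pipeline has realistic magnitudes to work on.  All output is byte-stable
across runs — no randomness, no timestamps — so golden-file comparisons
are safe.

The molecules cover the features the suite needs:

* an ethanol-like molecule (CH3-CH2-OH) exercising exactly one threefold
  group and one hydroxyl group;
* a four-atom chain with no nonbonded interactions and a single torsion
  described by a Ryckaert-Bellemans potential, together with coordinate
  frames sweeping that torsion through a full revolution (10-degree steps,
  bond angles of 109.5 degrees) — the dihedral-conversion validation
  system;
* a molecule planted with exactly 3 atom types and 5 bonded type tuples
  absent from the minimal force field, for diff testing.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Union

import numpy as np

from .topio import MoleculeTopology, read_topology_text

#: RB coefficients (kJ/mol) of the scan molecule's torsion; butane-like
#: magnitudes, C5 = 0 so the Fourier conversion exists.
SCAN_RB = (9.28, 12.156, -13.12, -3.056, 26.24, 0.0)
SCAN_BOND_NM = 0.15
SCAN_ANGLE_DEG = 109.5

#: declared content of the minimal force field (for count checks)
FF_COUNTS = {"atomtypes": 8, "bondtypes": 8, "angletypes": 8,
             "dihedraltypes": 2, "constrainttypes": 0}

_FORCEFIELD_ITP = """\
; minimal self-contained force field for the vsitetools test suite
[ defaults ]
; nbfunc  comb-rule  gen-pairs  fudgeLJ  fudgeQQ
  1       2          yes        0.5      0.8333

#include "ffnonbonded.itp"
#include "ffbonded.itp"
"""

_FFNONBONDED_ITP = """\
[ atomtypes ]
; name  at.num  mass      charge  ptype  sigma      epsilon
  CT    6       12.0110   0.0000  A      0.33997    0.457730
  HC    1        1.0080   0.0000  A      0.26495    0.065689
  OA    8       15.9994   0.0000  A      0.30001    0.711280
  HO    1        1.0080   0.0000  A      0.00000    0.000000
  SG    16      32.0600   0.0000  A      0.35600    1.046000
  HS    1        1.0080   0.0000  A      0.00000    0.000000
  NL    7       14.0070   0.0000  A      0.32500    0.711280
  XS    6       12.0110   0.0000  A      0.00000    0.000000
"""

_FFBONDED_ITP = """\
[ bondtypes ]
; i   j   funct  b0        kb
  CT  CT  1      0.15290   224262.4
  CT  HC  1      0.10900   284512.0
  CT  OA  1      0.14100   267776.0
  OA  HO  1      0.09600   462750.4
  CT  SG  1      0.18100   189953.6
  SG  HS  1      0.13360   274051.2
  CT  NL  1      0.14710   307105.6
  XS  XS  1      0.15000   200000.0

[ angletypes ]
; i   j   k   funct  theta0   ktheta
  CT  CT  HC  1      110.70   313.800
  HC  CT  HC  1      107.80   276.144
  CT  CT  OA  1      109.50   418.400
  HC  CT  OA  1      109.50   292.880
  CT  OA  HO  1      108.50   460.240
  CT  SG  HS  1       96.00   355.640
  HC  CT  NL  1      109.50   313.800
  XS  XS  XS  1      109.50   400.000

[ dihedraltypes ]
; i  j   k   l  funct  phase  k        mult
  X  CT  CT  X  9      0.00   0.650269  3
  X  CT  OA  X  9      0.00   0.736384  3
"""

_ATOMTYPES_ATP = """\
CT  12.0110
HC   1.0080
OA  15.9994
HO   1.0080
SG  32.0600
HS   1.0080
NL  14.0070
XS  12.0110
"""

ETHANOL_ITP = """\
; ethanol-like test molecule: CH3-CH2-OH
[ moleculetype ]
; name  nrexcl
  ETH   3

[ atoms ]
;  nr  type  resnr  residue  atom  cgnr  charge
   1   CT    1      ETH      C1    1     -0.1800
   2   HC    1      ETH      H11   1      0.0600
   3   HC    1      ETH      H12   1      0.0600
   4   HC    1      ETH      H13   1      0.0600
   5   CT    1      ETH      C2    2      0.1450
   6   HC    1      ETH      H21   2      0.0600
   7   HC    1      ETH      H22   2      0.0600
   8   OA    1      ETH      O     3     -0.6830
   9   HO    1      ETH      HO    3      0.4180

[ bonds ]
;  ai  aj  funct
   1   2   1
   1   3   1
   1   4   1
   1   5   1
   5   6   1
   5   7   1
   5   8   1
   8   9   1
"""

NOVEL_ITP = """\
; molecule planted with 3 atom types and 5 bonded tuples that are
; deliberately absent from the minimal force field
[ atomtypes ]
; name  at.num  mass      charge   ptype  sigma      epsilon
  ZN    7       14.0070   -0.5000  A      0.32000    0.800000
  ZC    6       12.0110    0.2000  A      0.34000    0.400000
  ZO    8       15.9994   -0.4500  A      0.29600    0.878640

[ moleculetype ]
  NOV   3

[ atoms ]
;  nr  type  resnr  residue  atom  cgnr  charge
   1   ZN    1      NOV      N1    1     -0.5000
   2   ZC    1      NOV      C1    2      0.2000
   3   ZC    1      NOV      C2    3      0.7500
   4   ZO    1      NOV      O1    4     -0.4500

[ bonds ]
;  ai  aj  funct  b0       kb
   1   2   1      0.13500  400000.0
   2   3   1      0.15000  250000.0
   3   4   1      0.14300  300000.0

[ angles ]
;  ai  aj  ak  funct  theta0  ktheta
   1   2   3   1      120.00  450.000
   2   3   4   1      111.00  420.000
"""

#: number of planted novelties in NOVEL_ITP
NOVEL_ATOMTYPE_COUNT = 3
NOVEL_INTERACTION_COUNT = 5


def _scan_itp() -> str:
    params = "  ".join(f"{c:.5f}" for c in SCAN_RB)
    return f"""\
; four-atom torsion-scan molecule: no nonbonded interactions, one torsion
[ moleculetype ]
  SCAN  3

[ atoms ]
;  nr  type  resnr  residue  atom  cgnr  charge
   1   XS    1      SCN      X1    1     0.0000
   2   XS    1      SCN      X2    2     0.0000
   3   XS    1      SCN      X3    3     0.0000
   4   XS    1      SCN      X4    4     0.0000

[ bonds ]
   1   2   1
   2   3   1
   3   4   1

[ angles ]
   1   2   3   1
   2   3   4   1

[ dihedrals ]
;  ai aj ak al funct  C0..C5 (Ryckaert-Bellemans)
   1  2  3  4  3      {params}
"""


SCAN_ITP = _scan_itp()


def make_min_forcefield(dir_path: Union[str, Path]) -> Path:
    """Write the minimal force-field directory; returns its path."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    (dir_path / "forcefield.itp").write_text(_FORCEFIELD_ITP)
    (dir_path / "ffnonbonded.itp").write_text(_FFNONBONDED_ITP)
    (dir_path / "ffbonded.itp").write_text(_FFBONDED_ITP)
    (dir_path / "atomtypes.atp").write_text(_ATOMTYPES_ATP)
    return dir_path


def make_ethanol_top() -> MoleculeTopology:
    """The 9-atom ethanol-like molecule (one methyl, one hydroxyl group)."""
    return read_topology_text(ETHANOL_ITP)[0]


def make_novel_type_top() -> MoleculeTopology:
    """The molecule with planted novel atom types and interactions."""
    return read_topology_text(NOVEL_ITP)[0]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_fourth_atom(p1, p2, p3, bond: float, angle_deg: float,
                      dihedral_deg: float) -> np.ndarray:
    """Position a fourth atom at given internal coordinates from p1-p2-p3.

    The returned point D satisfies |D - p3| = bond, angle(p2, p3, D) =
    ``angle_deg`` and dihedral(p1, p2, p3, D) = ``dihedral_deg`` in the
    same sign convention as :func:`vsitetools.dihedrals.dihedral_angle`.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    th = math.radians(angle_deg)
    ph = math.radians(dihedral_deg)
    bc = _unit(p3 - p2)
    n = _unit(np.cross(p2 - p1, bc))
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(th),
                        bond * math.sin(th) * math.cos(ph),
                        bond * math.sin(th) * math.sin(ph)])
    frame = np.column_stack([bc, m, n])
    return p3 + frame @ d_local


def make_scan_molecule(step: float = 10.0):
    """The four-atom scan molecule plus its torsion-sweep coordinate frames.

    Returns ``(molecule, frames)`` where frames is a list of
    ``(angle_degrees, coords)`` pairs, coords a (4, 3) array in nm, one
    frame per ``step`` degrees from 0 up to (not including) 360.
    """
    if 360.0 % step:
        raise ValueError("step must divide 360 degrees")
    mol = read_topology_text(SCAN_ITP)[0]
    b, theta = SCAN_BOND_NM, SCAN_ANGLE_DEG
    p2 = np.zeros(3)
    p3 = np.array([b, 0.0, 0.0])
    p1 = np.array([b * math.cos(math.radians(theta)),
                   b * math.sin(math.radians(theta)), 0.0])
    frames = []
    nsteps = int(round(360.0 / step))
    for t in range(nsteps):
        phi = t * step
        p4 = place_fourth_atom(p1, p2, p3, b, theta, phi)
        frames.append((phi, np.array([p1, p2, p3, p4])))
    return mol, frames


def write_fixture_set(dir_path: Union[str, Path]) -> dict:
    """Write the whole fixture family under one directory (for CLI runs).

    Returns a dict of paths: force-field dir, ethanol.itp, ethanol.rtp,
    novel.itp, scan.itp.
    """
    from .topdiff import make_rtp
    from .topio import write_rtp

    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    ff = make_min_forcefield(dir_path / "testff.ff")
    paths = {"forcefield": ff}
    for name, text in (("ethanol.itp", ETHANOL_ITP), ("novel.itp", NOVEL_ITP),
                       ("scan.itp", SCAN_ITP)):
        (dir_path / name).write_text(text)
        paths[name] = dir_path / name
    rtp_text = write_rtp(make_rtp(make_ethanol_top()))
    (dir_path / "ethanol.rtp").write_text(rtp_text)
    paths["ethanol.rtp"] = dir_path / "ethanol.rtp"
    return paths
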