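"""Exact interconversion among the three torsion functional forms, energy
evaluation, and the dihedral-angle geometry helper.

GROMACS supports three interconvertible descriptions of a proper torsion
about the angle phi (IUPAC convention, cis = 0):

* proper terms      ``V = k (1 + cos(n phi - phi_s))``          (funct 1/9)
* Ryckaert-Bellemans ``V = sum_m C_m cos^m(psi)``, psi = phi - 180  (funct 3)
* Fourier series    ``V = 1/2 [F1(1+cos phi) + F2(1-cos 2phi)
  + F3(1+cos 3phi) + F4(1-cos 4phi)]``                          (funct 5)

The three spans differ: the RB polynomial is the most general (degree 5 in
cos psi), the Fourier series cannot represent a constant or a degree-5
component, and proper terms with phases other than 0/180 degrees leave the
cosine-polynomial space entirely.  Conversions therefore either succeed
exactly, succeed up to a reported constant energy offset (which leaves
forces untouched), or raise :class:`InconvertibleDihedralError`.

The algebra rests on two classical identities: ``cos(n phi)`` is the n-th
Chebyshev polynomial of ``cos phi``, and ``cos phi = -cos psi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from numpy.polynomial import chebyshev as _cheb

from .errors import GeometryError, InconvertibleDihedralError

#: tolerance below which a residual C5 coefficient is treated as zero
C5_TOL = 1e-9
#: tolerance (degrees) for recognising 0/180 proper-term phases
PHASE_TOL_DEG = 1e-6
#: proper terms with |k| below this are dropped from conversion output
K_DROP = 1e-12


@dataclass(frozen=True)
class ProperTerm:
    """One periodic torsion term k (1 + cos(n phi - phase))."""

    phase: float  # degrees
    k: float      # kJ/mol
    n: int        # multiplicity, >= 1

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True)
class RBParams:
    """Ryckaert-Bellemans coefficients C0..C5 in kJ/mol."""

    c: tuple

    def __post_init__(self):
        if len(self.c) != 6:
            raise ValueError("RB potential has exactly six coefficients")


@dataclass(frozen=True)
class FourierParams:
    """Fourier coefficients F1..F4 in kJ/mol."""

    f: tuple

    def __post_init__(self):
        if len(self.f) != 4:
            raise ValueError("Fourier potential has exactly four coefficients")


#: a torsion potential in any of the three forms (proper = tuple of terms)
DihedralPotential = Union[RBParams, FourierParams, tuple, list, ProperTerm]


@dataclass(frozen=True)
class ConversionResult:
    """A converted potential plus the constant offset V_target - V_source."""

    target: DihedralPotential
    constant_offset: float  # kJ/mol, independent of phi


# ---------------------------------------------------------------------------
# energy evaluation


def energy(potential: DihedralPotential, phi_deg) -> Union[float, np.ndarray]:
    """Torsion energy in kJ/mol at dihedral angle(s) ``phi_deg`` (degrees)."""
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    if isinstance(potential, ProperTerm):
        potential = (potential,)
    if isinstance(potential, RBParams):
        cos_psi = -np.cos(phi)  # psi = phi - 180 deg
        v = np.polynomial.polynomial.polyval(cos_psi, np.asarray(potential.c))
    elif isinstance(potential, FourierParams):
        f1, f2, f3, f4 = potential.f
        v = 0.5 * (f1 * (1 + np.cos(phi)) + f2 * (1 - np.cos(2 * phi))
                   + f3 * (1 + np.cos(3 * phi)) + f4 * (1 - np.cos(4 * phi)))
    else:
        v = np.zeros_like(phi)
        for term in potential:
            v = v + term.k * (1 + np.cos(term.n * phi - math.radians(term.phase)))
    return v if v.ndim else float(v)


# ---------------------------------------------------------------------------
# conversions (RB is the hub form)


def fourier_to_rb(F: FourierParams) -> ConversionResult:
    """Convert a Fourier series to RB coefficients.  Always exact (offset 0)."""
    f1, f2, f3, f4 = F.f
    c = (f2 + 0.5 * (f1 + f3),
         0.5 * (-f1 + 3 * f3),
         -f2 + 4 * f4,
         -2 * f3,
         -4 * f4,
         0.0)
    return ConversionResult(RBParams(c), 0.0)


def rb_to_fourier(C: RBParams) -> ConversionResult:
    """Convert RB coefficients to a Fourier series.

    Impossible when C5 is nonzero (the Fourier form is degree 4), and the
    constant component C0 is not representable — it is returned as the
    constant offset instead.
    """
    c0, c1, c2, c3, c4, c5 = C.c
    if abs(c5) > C5_TOL:
        raise InconvertibleDihedralError(
            f"cannot express a degree-5 Ryckaert-Bellemans potential as a "
            f"Fourier series: C5 = {c5:g} kJ/mol is nonzero")
    f = (-2 * c1 - 1.5 * c3, -c2 - c4, -0.5 * c3, -0.25 * c4)
    c0_back = f[1] + 0.5 * (f[0] + f[2])
    return ConversionResult(FourierParams(f), c0_back - c0)


def proper_to_rb(terms: Sequence[ProperTerm]) -> ConversionResult:
    """Convert a sum of proper terms (one torsion quadruple) to RB form.

    Requires every phase to be 0 or 180 degrees (mod 360) and every
    multiplicity at most 5; other combinations leave the cosine-polynomial
    space or exceed RB's degree and raise.  Exact (offset 0).
    """
    c = np.zeros(6)
    for term in terms:
        if term.n > 5:
            raise InconvertibleDihedralError(
                f"proper term with multiplicity {term.n} exceeds the RB "
                f"polynomial degree of 5")
        phase = term.phase % 360.0
        if min(phase, 360.0 - phase) <= PHASE_TOL_DEG:
            sign = 1.0
        elif abs(phase - 180.0) <= PHASE_TOL_DEG:
            sign = -1.0
        else:
            raise InconvertibleDihedralError(
                f"proper term with phase {term.phase:g} degrees is not a "
                f"polynomial in cos(phi); only 0 and 180 are convertible")
        # k (1 + s cos(n phi)); cos(n phi) = T_n(cos phi), cos phi = -cos psi
        tn = _cheb.cheb2poly([0.0] * term.n + [1.0])
        signs = (-1.0) ** np.arange(len(tn))
        c[:term.n + 1] += term.k * sign * tn * signs
        c[0] += term.k
    return ConversionResult(RBParams(tuple(c)), 0.0)


def rb_to_proper(C: RBParams) -> ConversionResult:
    """Convert RB coefficients to proper terms (multiplicities 1..5).

    Always possible: the cosine polynomial is re-expressed in the
    cos(n phi) basis; each component becomes a term with nonnegative k and
    phase 0 or 180, and the constant remainder is reported as the offset.
    """
    power = np.asarray(C.c) * (-1.0) ** np.arange(6)  # coefficients in cos phi
    a = _cheb.poly2cheb(power)                         # V = sum a_j cos(j phi)
    terms = []
    for j in range(1, len(a)):
        if abs(a[j]) > K_DROP:
            terms.append(ProperTerm(phase=0.0 if a[j] > 0 else 180.0,
                                    k=abs(float(a[j])), n=j))
    offset = float(sum(t.k for t in terms) - a[0])
    return ConversionResult(tuple(terms), offset)


def convert(potential: DihedralPotential, target: str) -> ConversionResult:
    """Convert any potential to ``target`` in {"proper", "rb", "fourier"}.

    Offsets compose: the reported constant is always V_target - V_source.
    """
    if target not in ("proper", "rb", "fourier"):
        raise ValueError(f"unknown target form {target!r}")
    if isinstance(potential, ProperTerm):
        potential = (potential,)
    source = ("rb" if isinstance(potential, RBParams)
              else "fourier" if isinstance(potential, FourierParams)
              else "proper")
    if source == target:
        return ConversionResult(potential, 0.0)
    if source == "rb":
        as_rb, up_offset = potential, 0.0
    elif source == "fourier":
        res = fourier_to_rb(potential)
        as_rb, up_offset = res.target, res.constant_offset
    else:
        res = proper_to_rb(potential)
        as_rb, up_offset = res.target, res.constant_offset
    if target == "rb":
        return ConversionResult(as_rb, up_offset)
    down = rb_to_fourier(as_rb) if target == "fourier" else rb_to_proper(as_rb)
    return ConversionResult(down.target, up_offset + down.constant_offset)


# ---------------------------------------------------------------------------
# dihedral-angle geometry


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Dihedral angle (degrees, IUPAC convention) of four points in nm.

    Cis (atoms 1 and 4 eclipsed) is 0; the result lies in (-180, 180], and
    mirror-image conformations have negated angles.  Collinear consecutive
    triples make the angle undefined and raise :class:`GeometryError`.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale1 = np.linalg.norm(b1) * np.linalg.norm(b2)
    scale2 = np.linalg.norm(b2) * np.linalg.norm(b3)
    if scale1 == 0 or scale2 == 0 or \
            np.linalg.norm(n1) < 1e-10 * scale1 or \
            np.linalg.norm(n2) < 1e-10 * scale2:
        raise GeometryError(
            "dihedral angle undefined: three consecutive atoms are collinear")
    b2u = b2 / np.linalg.norm(b2)
    phi = math.degrees(math.atan2(float(np.dot(np.cross(n1, n2), b2u)),
                                  float(np.dot(n1, n2))))
    if phi <= -180.0:
        phi += 360.0
    return phi
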