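# Methods

## Model and assumptions

The package treats a molecule as a bond graph with force-field-typed atoms
and reconstructs group geometry purely from *equilibrium* bonded
parameters, never from coordinates.  This matches how constraint-based
virtual-site machinery operates: once hydrogens are constrained or
virtualized, the group sits at its ideal geometry by construction, so the
ideal geometry is the right source for the derived lengths.

**Threefold groups.**  A heavy atom (the *center*, X) with exactly one
heavy neighbour (the *anchor*, A) and three bonded hydrogens is modelled as
a rigid symmetric rotor: all three X–H bonds share one length `b_XH` and
one tilt `α` off the A→X axis, with 120° azimuthal spacing.  The tilt is
taken from the A–X–H equilibrium angle (`α = 180° − θ_AXH`); when only the
H–X–H angle is parameterized, the threefold-symmetry identity
`cos θ_HXH = (3 cos²α − 1)/2` supplies it.  If both are available and
disagree by more than 0.5° the anchor-relative angle wins with a warning
(it fixes the tilt directly; the H–X–H route is a derived quantity).  If
the three X–H bond entries differ (asymmetric parameterizations), their
arithmetic mean is used and the spread is reported — the two-dummy model
is inherently threefold-symmetric and cannot honour the asymmetry anyway.

The two dummy particles each carry half the group mass.  Placing them at
`(z_com, ±r_d)` with `r_d = √(I_axis/m_tot)` preserves the total mass
exactly and the axial centre of mass and axial moment of inertia
identically (an algebraic identity, verified numerically in the tests).
Only the moment about the rotation axis can be preserved: two point masses
have zero moment about their own connecting axis, so the perpendicular
moments necessarily change.  This is a known property of the construction,
not an approximation error; the perpendicular inertia is dominated by the
heavy-atom skeleton the dummies are constrained to.

**Bent groups.**  For –OH/–SH the hydrogen–anchor constraint is the third
side of the triangle with arms `b_AX`, `b_XH` and included equilibrium
angle `θ_AXH` (law of cosines).  The degenerate limits are returned
exactly (`θ = 180° → b_AX + b_XH`, `θ = 0° → |b_AX − b_XH|`) rather than
through the cosine expression, avoiding last-ulp noise where the result is
analytic.  Only oxygen and sulfur centers are accepted; a single hydrogen
on another element, or two hydrogens (–NH₂), has no model here and is
skipped with a warning.

**Hydrogen identification.**  An atom is hydrogen iff its type's atomic
number is 1 when the force field declares one; otherwise iff its mass is
≤ 3.5 u (covering deuterium).  Masses in the helium window without a
declared element are classified heavy with a warning.  When the atom-type
table has no atomic-number column, elements are inferred from narrow mass
bands and flagged as inferred so downstream consumers can demand
confirmation.

## Torsion-form algebra

The three GROMACS proper-torsion forms are interconverted exactly through
the Ryckaert–Bellemans polynomial as hub, using `cos(nφ) = T_n(cos φ)`
(Chebyshev) and `cos φ = −cos ψ`:

* Fourier → RB is always exact (the standard linear coefficient map).
* RB → Fourier exists iff `C5 = 0`; the constant `C0` is not representable
  and is returned as the offset.
* proper → RB requires every phase ∈ {0°, 180°} and multiplicity ≤ 5;
  anything else leaves the cosine-polynomial space (or exceeds degree 5)
  and raises.
* RB → proper always exists: the polynomial is re-expanded in the
  `cos(nφ)` basis (numpy's Chebyshev transforms), each component becomes a
  term with `k = |a_n| ≥ 0` and phase 0 or 180°, and the constant
  remainder becomes the offset.

Offsets compose additively along conversion chains and are always
reported, never discarded — they change absolute energies, not forces, but
users comparing energy outputs must know about them; the CLI prints one
line per converted torsion.  Zero-amplitude terms (|k| < 1e-12 kJ/mol) are
dropped from conversion output.

Tolerances: a residual `|C5| ≤ 1e-9 kJ/mol` and phases within 1e-6° of
0/180° are accepted, absorbing float noise in real topology files without
masking genuine inconvertibility.  These are this package's documented
choices; nothing mandates particular values.

Multiple funct-9 entries on one atom quadruple are summed into a single
potential before conversion, and mixed functional forms on one quadruple
are folded through RB.  Improper dihedrals (funct 2/4) are never converted
— they are passed through with a warning, since their functional forms
serve a different purpose (planarity/chirality restraints).

The torsion-scan validation builds a four-atom chain (bonds 0.15 nm,
angles 109.5°, no nonbonded interactions) whose single torsion carries a
Ryckaert–Bellemans potential with all of C0..C4 nonzero and C5 = 0, sweeps
the dihedral through a full revolution in 10° steps (36 frames, built by
internal-coordinate placement and independently re-measured with the
dihedral-angle routine), and checks that the three forms' energy series
pairwise differ by constants with matching central-difference gradients.

## Force-field and topology I/O

* Lookup semantics: bonds and angles are symmetric under tuple reversal;
  dihedral lookups accept the wildcard `X` with most-specific-match-wins
  precedence (exact > 3 fixed positions > 2 > …).  Equally specific,
  genuinely conflicting matches raise instead of silently picking one,
  as do conflicting duplicate bond/angle definitions.  A funct-9 lookup
  returns all multiplicity entries at the best match level, so multi-term
  torsions survive the round trip.
* The preprocessor scope is deliberately small: `#include` (resolved
  relative to the force-field directory; only recorded for topologies),
  `#define` as token substitution, and `#ifdef` taking the branch for the
  symbol being undefined (with a warning) unless the files themselves
  defined it.
* Printing precision: lengths 5 decimals (nm), masses and charges
  4 decimals (u, e), angles 4 decimals (degrees), energies and force
  constants 6 significant digits.  Format → parse → format is a fixed
  point, and parse → format → parse preserves entries within those
  precisions.
* Angles are stored in degrees (the file convention) and converted to
  radians at the point of trigonometric use.
* Mass fallback: per-atom mass column > topology-inline `[ atomtypes ]` >
  force-field `[ atomtypes ]`.
* The `vsites` flow demands that every atom type be present in the force
  field itself — the derivation works purely from force-field entries, so
  molecules carrying their own new types must go through the
  inspect/incorporate step first; the error says so.

## Emission choices

* Emitted constraints use funct 2 (no exclusion generation): dummy–anchor
  and hydrogen–anchor couplings are geometric, not chemical bonds.
* Dummy types are named `M<element>H3` plus a letter suffix (`MCH3A`,
  `MCH3B`, …) per distinct parameter set, skipping any name already in the
  force field; constructions identical within 1e-5 nm / 1e-4 u share one
  type, and an existing force-field dummy type matching within those
  tolerances is reused instead of re-emitted.
* Dummy atom types are written with particle-type letter `D` and zero
  charge/Lennard-Jones.  Some GROMACS force fields ship their dummy-mass
  types with particle type `A` (they are, after all, integrated
  particles); if a target force field follows that convention the letter
  can be edited when pasting — the constraint lengths and masses are what
  matter.
* Incorporation into force-field files is deliberately manual: the tools
  print paste-ready blocks but never edit files in place, keeping the
  change reviewable and avoiding silent errors.

## Synthetic test inputs

The fixture generator writes a minimal but complete force-field directory
(8 atom types, 8 bond types, 8 angle types, 2 wildcard torsion types) and
three molecules (ethanol-like, torsion-scan chain, planted-novelty
molecule).  Equilibrium values are chemically typical (C–H 0.109 nm,
C–C 0.1529 nm, C–O–H 108.5°, …) but are *not* taken from any published
force field; tests therefore validate the machinery, not any particular
parameter set.  Everything is byte-deterministic.

What the fixtures do not emulate — and hence what passing tests cannot
show: real force-field scale (thousands of types, deep include trees),
exotic dialects (CHARMM Urey–Bradley columns are parsed but not exercised
end-to-end; cmap, polarizable and tabulated sections are out of scope),
multi-residue polymers with inter-residue bonds, and the behaviour of the
emitted parameters inside an actual MD integrator, which would require
GROMACS itself.

## Validation sizes

The acceptance script and test suite use 36-frame torsion scans and
1,000-draw seeded random sweeps (coefficients in ±40 kJ/mol; geometry in
b_AX ∈ [0.10, 0.16] nm, b_XH ∈ [0.09, 0.14] nm, α ∈ [55°, 80°],
m_X ∈ [10, 35] u, m_H ∈ [1, 2.1] u), sizes at which the whole validation
completes in seconds while covering the parameter ranges real force
fields occupy.  Agreement with the brute-force Cartesian oracles is at
the 1e-10 relative level or better throughout (in practice, machine
precision).

## Known limitations

* `[ virtual_sites3 ]` construction entries and `.vsd` database entries
  are not generated — `pdb2gmx` creates those from the rtp output.
* Aliphatic (non-rotor) hydrogens need no extra parameters and are left to
  GROMACS.
* Groups with two hydrogens and threefold centers beyond C/N work
  mathematically but are outside the supported detection rules.
* Perpendicular moments of inertia of threefold groups are not preserved
  by any two-particle construction (see above).
* Only simple `#define` substitution is honoured; full conditional
  preprocessing of force fields is not.
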