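# vsitetools

Tools for deriving the extra parameters GROMACS needs to run **virtual
interaction sites** on arbitrary molecules — ligands, noncanonical amino
acids, lipids, small drug-like compounds — so that simulations can use
timesteps beyond the usual 2 fs limit imposed by hydrogen bond vibrations.

## The problem

With virtual sites, hydrogen positions are rebuilt each integration step
from nearby heavy atoms instead of being integrated, which removes the
fastest degrees of freedom and allows ~5 fs timesteps.  Two kinds of group
need parameters that do not exist outside the standard residue databases:

* **Threefold rotors (–CH₃, –NH₃⁺).**  A spinning methyl's hydrogens are
  not determined by the bonded heavy atoms.  The fix is to redistribute the
  whole group's mass onto **two dummy particles** placed on either side of
  the rotation axis and tied by a triangle of constraints to the anchor
  atom.  With the anchor at the origin and the axis along *z*, the group's
  mass moments are

      m_tot = m_X + 3 m_H
      z_com = (m_X b_AX + 3 m_H z_H) / m_tot,   z_H = b_AX + b_XH cos α
      I_axis = 3 m_H (b_XH sin α)²

  and two dummies of mass `m_tot/2` at `(z_com, ±r_d)` with
  `r_d = √(I_axis/m_tot)` reproduce the total mass, the centre of mass and
  the axial moment of inertia exactly.  The emitted constraints are
  `d_DD = 2 r_d` (dummy–dummy) and `d_DA = √(z_com² + r_d²)`
  (dummy–anchor).

* **Bent single-hydrogen groups (–OH, –SH).**  Here a single
  hydrogen–anchor distance constraint freezes the bending angle while the
  torsion stays free: `d₀² = b_AX² + b_XH² − 2 b_AX b_XH cos θ` (law of
  cosines on the equilibrium bond lengths and angle).

All inputs come from equilibrium force-field parameters: the package reads
a GROMACS force-field directory and a molecule topology (`.itp`/`.top`) or
residue template (`.rtp`), finds the eligible groups from the bond graph,
reconstructs their ideal geometry, and prints paste-ready `[ atomtypes ]`
and `[ constrainttypes ]` blocks.

Supporting tooling covers the workflow around that core:

* **`inspect`** diffs a topology against the force field, listing atom
  types and bonded parameters that must be incorporated first (new ligand
  parameterizations usually carry their own), as paste-ready blocks;
* exact interconversion of torsion potentials between the **proper**
  (`k(1+cos(nφ−φs))`), **Ryckaert–Bellemans** (degree-5 polynomial in
  cos ψ, ψ = φ−180°) and **Fourier** four-term forms, reporting the
  constant energy offset a conversion introduces (gradients, and hence
  forces, are untouched);
* residue-template (`rtp`) generation from a topology, so `pdb2gmx` can
  build complete topologies — including all virtual-site constructions —
  directly from a structure.

## Worked example

The test fixtures include a minimal force field and an ethanol-like
molecule (CH₃–CH₂–OH), which has exactly one threefold and one hydroxyl
group:

```sh
python - <<'EOF'
import tempfile
from vsitetools.fixtures import write_fixture_set
from vsitetools.cli import main
paths = write_fixture_set(tempfile.mkdtemp())
main(["vsites", str(paths["ethanol.rtp"]),
      "-ff", str(paths["forcefield"]), "-r", "ETH"])
EOF
```

prints (summary lines on stderr, parameter blocks on stdout):

```
threefold group at atom 1 (anchor 5): dummy type MCH3A, mass 7.5175 u, d(dummy-dummy) 0.09146 nm, d(dummy-anchor) 0.16703 nm
bent group: constraint H 9 - anchor 5 (HO-CT), d0 0.19413 nm
[ atomtypes ]
MCH3A     0      7.5175     0.0000   D     0.00000             0

[ constrainttypes ]
MCH3A   MCH3A   2    0.09146
MCH3A   CT      2    0.16703
HO      CT      2    0.19413
```

Reading the output: the methyl group (C 12.011 u + 3 H × 1.008 u =
15.035 u) becomes two dummies of 7.5175 u each, 0.09146 nm apart, each
0.16703 nm from the anchor carbon; the hydroxyl hydrogen is held 0.19413 nm
from its anchor carbon, which freezes the C–O–H angle at its equilibrium
108.5° while the hydroxyl can still rotate.  The blocks paste directly into
`ffnonbonded.itp`/`ffbonded.itp`.

The same pipeline is available as a library
(`vsitetools.derive_vsite_parameters`, `vsitetools.emit_vsite_parameters`),
and `vsitetools inspect molecule.itp -ff ff.dir [--convert rb|fourier|proper]
[--rtp-out out.rtp]` drives the diff/convert/rtp side.

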