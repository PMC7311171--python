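# Methods

This note records the models, numerical choices and synthetic-data design
behind `ciliageom`, and what the tests do and do not establish.

## Coordinate and numbering conventions

Residue numbering is author numbering throughout; mmCIF label numbering is
mapped onto author numbering at parse time (gemmi).  Residue ranges are
inclusive on both ends and 1-based, matching the "aa 543–793" convention of
the structural literature.  Insertion codes sort after their base number.
Non-standard residues map to `X` in sequences (never matching any motif
class) while their geometry is retained.  All distances are in Å; nm values
(e.g. the 250 nm ciliary diameter) are converted at the interface.

## Rigid-body geometry

Superposition is the least-squares SVD solution with a reflection guard
(determinant forced to +1) so chirality is preserved; degenerate inputs
(<3 pairs, collinear sets) raise.  The test suite checks it against an
independently implemented closed-form quaternion (Horn) method.  Rotation
magnitudes come from the axis–angle decomposition, `arccos((tr R − 1)/2)`;
values below ~10⁻⁴ degrees are numerically indistinguishable from identity
because of the arccos derivative at 1.

**Domain rotation protocol.**  Two conformations are aligned on a
stationary reference module (for a BBSome-like complex, the base/corkscrew
subunits); the mobile domain's Cα atoms common to both models (matched by
chain, author number and insertion code) are then superposed and the
residual rotation angle is reported.  The protocol is validated on a
two-module fixture with a planted rotation and a confounding global rigid
motion; recovery is exact to 10⁻⁶ degrees.

## Membrane placement

The membrane reference surface is the headgroup (phosphate-level) plane.
An amphipathic anchor helix constrains it three ways: (a) helix axis
parallel to the plane, (b) helix Cα centroid at `headgroup_depth` below it
(default 3 Å — roughly half a headgroup layer), and (c) no heavy atom of
the complex beyond the plane by more than `penetration_tolerance`
(default 2 Å).  That leaves a roll of the normal about the helix axis (and,
for the orientation search, a tilt within `parallelism_tolerance`,
default 10°).

* **Helix axis.**  For traces of ≥6 residues the axis is the smallest
  principal direction of the Cα second differences, which point radially in
  a regular helix; unlike the raw principal axis this is unbiased for
  partial turns.  Shorter traces fall back to the coordinate principal axis.
* **Roll.**  The hydrophobicity profile is fitted as one helical-wheel
  harmonic of the angular position around the axis,
  H_i ≈ a + b·cos ψ_i + c·sin ψ_i; the normal points along the fitted
  hydrophobic-face direction (membrane on the hydrophobic face).  The
  intercept and normal equations correct for the uneven angular sampling of
  short helices, where the plain hydrophobic-moment vector sum is biased.
  If the fitted amplitude is < 0.3 (apolar or symmetric helix, e.g.
  poly-Ala) the roll is chosen to minimise the maximum penetration instead.
* **Feasibility.**  If the preferred roll violates (c), the nearest
  feasible roll on a 2° grid is taken; if no roll is feasible an
  infeasibility report (smallest achievable violation) is returned rather
  than a plane.

The orientation search for the minimum cargo-patch/membrane distance scans
roll (0–360°) × tilt (±tolerance) on a deterministic grid (default 2°,
configurable down to sub-degree), keeps feasible orientations, and
optionally polishes the best grid point with a local Nelder–Mead step
confined to the feasible region.  Minima from nested grids are monotone by
construction, and the 2° grid agrees with a 0.5° oracle to ≲0.05 Å on the
test fixtures.

**Curvature.**  A cylinder of the ciliary radius is placed tangent to the
headgroup plane at the membrane-facing centroid, axis along the requested
in-plane direction (or the in-plane principal axis of the membrane-facing
atoms), with the complex inside the tube.  Reported are the count of heavy
atoms beyond the wall and the fraction of membrane-facing atoms within a
contact shell (default 8 Å) of the wall.  The 250 nm figure for the cilium
is interpreted as a diameter (radius 1250 Å); both interpretations are one
constructor argument apart.

**Charge census.**  Charged residues are tallied when their side-chain
representative atom — terminal charged-group atom if present (NZ, CZ, CG,
CD, NE2), else Cβ, else Cα — lies within `slab_depth` below the plane.
K/R = +1, D/E = −1, His configurable (default 0).  This residue-level count
deliberately replaces continuum electrostatics.

## Tether reach

Reach is a hard geometric bound: `n` inter-residue steps × 3.5 Å/residue
extended, or × 1.5 Å/residue helical.  The constants are exactly the rise
of the synthetic extended chain and ideal α-helix generators, so generator
extents and the reach table agree identically.  Step counts are differences
of author numbers (543→549 = 6), not inclusive residue counts.  A state is
compatible with a measured site–membrane distance d when d ≤ reach; "must
be unfolded" is issued exactly when the extended chain reaches and the
helix does not.  No polymer-physics (worm-like-chain) statistics are
attempted — the bounds are maxima, not expectations.

## Sequence analyses

* **Hydrophobic moment.**  μH = |Σ H_n·exp(i·n·δ)|/N on the Eisenberg
  consensus scale, δ = 100°/residue by default.  The scale is a parameter
  and is named in report headers; μH values are scale-relative.
* **Helix-8 annotation.**  With a known TM7 end, the window is the 17
  residues following it (17 matches the span of a canonical H8 such as SMO
  543–559).  Without one, candidate windows in the first 25 tail residues
  are scored by *helical periodicity* — the R² of the one-harmonic
  helical-wheel fit — rather than raw μH: the R² localises an amphipathic
  stretch more sharply, because raw μH also rewards windows that trade
  coherent residues for lucky flanking ones.  On planted cohorts the R²
  score recovers ≥90% of windows to within ±2 residues; raw μH plateaus
  near 80%.
* **Motif scanning.**  Patterns are ordered residue classes with bounded
  gaps; all matches (including overlaps) are reported with author-numbered
  positions.  The strict `[WFY]R`, relaxed `[WFY][KR]` and one-gap
  `[WFY]x[KR]` BBSome-motif variants are censused separately and never
  merged, since the strict and relaxed cohort counts answer different
  questions.  The PIP motif is `K x{3..8} [KR] x R`.  The scanner is tested
  for exact equality against brute-force enumeration of index tuples on 10³
  random sequences per pattern.
* **Theoretical pI.**  Bisection on the Henderson–Hasselbalch net charge
  under a Bjellqvist-style pKa set, including the residue-specific
  N-terminal α-amino corrections; cross-checked against Biopython's
  implementation.  pI values depend on the pKa set, which is configurable
  and recorded in outputs; no exact agreement with any particular published
  pI value is claimed.

## Lipid-site occlusion

A lipid-bound template PH domain is superposed onto the query PH domain on
a positional Cα correspondence (≥20 pairs required) and its ligand is
carried into the query frame.  Clashes are environment heavy atoms within
3.0 Å of any ligand heavy atom, excluding the PH domain itself; with
several templates for one site, the clash count is the median, making the
verdict insensitive to any single outlier template.  Verdicts: *blocked*
when the median count reaches the clash threshold (default 1 — any clash
blocks); otherwise *distant* when the ligand-centroid distance to the
membrane plane exceeds 10 Å (1 nm); otherwise *open*.  The centroid is the
documented reference point for the membrane distance.  Template libraries
are consumed from a directory of PDB files with a JSON manifest.

## Synthetic data: what it emulates, what it does not

All generators are seeded and deterministic, and return machine-readable
ground truth.

* The **membrane fixture** plants a plane, a 14-residue amphipathic anchor
  helix (the length of an ARF-family N-terminal helix preceding a core
  domain starting at residue 15) painted with a graded hydrophobicity
  pattern (amplitude 1.0 on the Eisenberg scale, σ = 0.03 paint noise,
  quantised to an uncharged residue palette), a 120-atom cytoplasmic body,
  and optional exact counts of in-slab charged residues.  Plane recovery on
  this fixture is within 5° / 2 Å (empirically ≤3.1° over 300 seeds).
* The **cohort generator** emulates GPCR cytoplasmic tails: a motif-free
  prefix, a graded-amphipathic H8 window (uncharged palette, so motif
  content is fully controlled), and a random tail.  Motifs are planted at
  exact counts — aromatic–R for the strict pattern, aromatic–K for
  relaxed-only — at face positions whose successor lies on the polar side,
  as in a genuine H8 motif.  Negative sequences are rejection-sampled to
  carry no in-window match.
* The **PH-site fixture** plants an exact clash count by placing
  environment atoms 1.8–2.9 Å from the transformed ligand and decoys ≥8 Å
  away.

These are Cα-level caricatures: no side chains, no real secondary-structure
irregularity, no membrane physics.  Passing tests therefore establish the
*correctness of the geometry and counting machinery* under known truth, not
the biological accuracy of any particular placement on real coordinates;
analyses of deposited models additionally depend on the documented defaults
(headgroup depth, penetration tolerance, patch definition) that real
structures require.

## Problem sizes

Test-suite and acceptance runs use desk-scale sizes chosen for tight
oracles: 14-residue anchors, 120–140-atom fixtures, 26–30-sequence cohorts,
20-residue random sequences for scanner/oracle equality (10³ per pattern),
and 0.5° dense grids as orientation-search oracles.  The full synthetic
reproduction completes in ~1 s.

## Known limitations

* The membrane is a plane (or tangent cylinder); no bilayer deformation,
  insertion energetics, or electrostatics.
* PH-domain correspondence is positional; genuinely divergent folds need a
  user-supplied pairing.
* The orientation search parameterises rotations about the anchor-helix
  axis with bounded tilt; anchors far from helical geometry would need a
  different parameterisation.
* Motif patterns are deterministic classes, not probabilistic models; no
  attempt is made to score motif strength.
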