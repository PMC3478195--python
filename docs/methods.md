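# Methods

## The problem and the model

`acedock` predicts the binding site formed by two rigid protein subunits
A (mobile, m atoms) and B (fixed, n atoms).  Both subunits are treated
as ordered sequences of heavy atoms; a *configuration* (pose) is a rigid
transform of A with B held fixed.  Among all enumerated, clash-free
configurations the one with the lowest Atomic Contact Energy (ACE) is
selected, and the residue pairs connected by an atom pair within 4.5 Å
in that configuration are reported as the predicted interface.

ACE is a statistical desolvation potential over 18 heavy-atom types.
Each type pair carries a log-likelihood contact energy

    T[i, j] = −ln[(N_ij / C_ij) / ((N_i0 / C_i0)(N_j0 / C_j0))]

(type 0 = solvent; N observed, C expected contact counts), and a pose is
scored by summing `T` over every cross-subunit atom pair within the
contact cutoff d = 6 Å:

    E_ACE = Σ_{s∈A, t∈B, ‖s−t‖ ≤ d} T[type(s), type(t)].

Lower is better (a more favorable desolvation change on binding).  The
score is distance-flat inside the cutoff: all structure in the landscape
comes from which pairs are in range, not how close they are.

The shipped parameter file (`data/ace_table_synthetic.txt`) is a
constructed stand-in: a chemically sensible 18-class typing of the 20
standard residues' heavy atoms with placeholder energies generated from
a per-type apolar propensity.  It exercises the full machinery and is
editable; `build_table` rebuilds `T` from user-supplied contact counts
when a real statistical table is available.  All algorithm tests use
explicit toy tables, so nothing in the validation depends on the
stand-in values.

## Search strategy

Enumerating all rigid placements of A is organized around two *anchor
interaction pairs* (a_i, b_i′) and (a_j, b_j′) — atoms of A presumed to
touch atoms of B:

1. **d-ball grid.** Candidate positions for a_i are a cubic lattice of
   pitch εd anchored at b_i′, clipped to the closed ball of radius d.
   With the published operating point ε = 0.1 this is O((1/ε)³) points.
2. **Sphere cap.** With a_i placed at P, atom a_j must lie on the
   sphere of radius |a_i − a_j| about P and inside the d-ball of b_j′ —
   a spherical cap.  The cap is sampled from its pole (the sphere point
   nearest b_j′) outwards in polar rings with arc spacing ≈ εd.
3. **Axis rotations.** With both anchors fixed, A rotates about the
   a_i–a_j axis in fixed angular steps (1° at the published operating
   point; 360/step poses).

Candidate anchors come from a sequence-level pre-filter:

* **Local alignment (stage 1).** A minimizing Smith–Waterman dynamic
  program aligns the two atom sequences, scoring a match column by
  `T[type_a, type_b]` and a gap column by +1.  All non-overlapping
  segments with total score ≤ 0 are extracted best-first
  (Waterman–Eggert-style row/column masking after each extraction; ties
  break on the lexicographically smallest end cell).
* **Surface window filter.** Each segment is scanned with a sliding
  window of 15 alignment columns; a window qualifies when ≥ 10 atoms on
  *each* side are surface atoms, in which case it is emitted as a
  fragment pair and its columns removed before the scan continues at
  the same position (a failing window advances by one column).  Gap
  columns count toward window length but contribute no surface atom.
* **Fragment threshold (stage 2).** Each fragment pair's endpoints are
  used as anchors; the pair survives if some clash-free pose scores the
  fragment atoms below the energy threshold (400 by default).
* **Final search (stage 3).** The 2k endpoints of the k surviving
  pairs give ≤ C(2k, 2) anchor combinations; every combination is
  enumerated, scoring the *full* structures, and the clash-free poses
  are ranked by energy (ascending; ties by lexicographic grid index so
  the result is reproducible bit-for-bit).

Stage-2 scores fragments only; whether the final ranking re-scores full
structures is an open design point, and we rank by full-structure energy
(`score_span_*` arguments expose the switch).

## Surface atoms and clashes

A 1 Å lattice is laid over each subunit with the origin at
`floor(min coordinate) − margin` (margin = 2 Å + 1 Å spacing), so the
lattice phase is a pure function of the coordinates.  A lattice point
within 2 Å (inclusive) of any atom is a *protein* point; a protein point
whose six axis neighbors are all protein is *interior*, otherwise
*surface*; out-of-box neighbors count as empty, and the margin
guarantees the box edge is never protein.  An atom is a surface atom iff
it lies within 1.5 Å (inclusive) of some surface lattice point.

For the clash test both posed subunits are laid on one shared lattice;
interior masks are computed per subunit as if the partner were absent,
and the pose clashes when the shared interior count X exceeds
θ·min(X_A, X_B), θ = 0.17 by default.  The clash lattice is rebuilt per
pose for correctness; B's interior mask is memoized per lattice geometry
as a pure optimization (results are identical with caching disabled).
All distance comparisons throughout the package read "within" as
inclusive (≤); the one deliberate exception is the experimental
interface definition below.

## Evaluation statistics

* **Predicted interface**: residue pairs with a cross atom pair within
  4.5 Å (inclusive) in the chosen pose.
* **Actual interface** (from an experimental complex): residue pairs
  with a cross atom pair strictly closer than the sum of the two atoms'
  van der Waals radii plus 1 Å.  Radii are element-based (C 1.70,
  N 1.55, O 1.52, S 1.80, P 1.80, default 1.70 Å) and editable.
* **Accuracy / coverage**: correctly predicted residues over predicted /
  over actual, in percent.  Reported pooled over both subunits by
  default (side-tagged so identical residue ids never collide);
  per-subunit modes are available.  An empty prediction has accuracy 0
  and is flagged; an empty actual set leaves coverage undefined and is
  an error.
* **F-score**: 2·Acc·Cov/(Acc+Cov) on the 0–1 scale.
* **Success**: accuracy ≥ 50 % (boundary inclusive); the success rate
  is the percentage of successful cases.
* **iRMSD**: the interface residues of the *native* complex are taken,
  their Cα atoms collected from both subunits, the predicted complex is
  superposed onto the native by least squares (Kabsch), and the residual
  RMSD reported.  Which atoms and which superposition enter an
  interface RMSD is a convention; this CAPRI-style choice (native
  interface, Cα only) is ours and is documented as such.  Requires ≥ 3
  interface Cα atoms.
* **Fraction of native contacts**: native residue contacts are cross
  pairs with minimum heavy-atom distance < 4.5 Å; the score is the
  percentage also present in the prediction.

## The planted-complex generator

Real benchmark complexes require structure downloads, so the test bed
is a seeded generator of toy subunits with an analytically known
interface (`acedock.synthetic`):

* A is a straight rod of 4-atom pseudo-residues (N/CA/C/O names, 1.8 Å
  atom spacing); its last four residues (16 atoms, the *peg*) carry one
  contact type.
* B is a *pocket*: 13 lining atoms on a helix of radius 2.5 Å around
  the peg's docked position, one floor atom 4 Å below the deepest
  anchor, plus a sparse bulk shell at radius 7 Å.  The 16 pocket atoms
  form one contiguous run in B's atom sequence.
* The toy table makes peg–lining contacts −10, peg–bulk and rod–lining
  contacts +6, everything else +1.  The lining sits one atom spacing
  below the matching peg atoms, which places the in-register docked
  pose at the contact-count optimum: any 3 Å lattice shift, lateral
  offset, or cap tilt loses favorable contacts or picks up penalties.

Two constructions make the planted pose *exactly* representable on the
enumeration grid: the first pocket atom is offset from the docked first
peg anchor by exactly one lattice pitch (so the planted a_i position is
a d-ball grid point), and the floor atom lies on the peg axis (so the
planted a_j position is the sphere-cap pole).  Because the rod is
collinear with the anchor axis, the axis-rotation degree of freedom does
not move it, and the identity rotation (grid index 0) wins ties
deterministically.  The surface lattice is phase-sensitive — an isolated
atom near a lattice cell center can sit ~1.55 Å from every surface
lattice point and be mislabeled interior — so the generator searches a
seeded sequence of global sub-lattice translations (applied to A and B
jointly, which changes no docking-relevant geometry) until every peg and
pocket-run atom is surface-labelled.  Every generated complex verifies
its own invariants at construction: the native pose is clash-free,
reproduces the planted interface exactly, covers exactly the peg and
pocket-run residues, and scores a favorable fragment energy.

What the toy bed does *not* emulate: amino-acid chemistry and packing,
side-chain flexibility, realistic atom densities (the rod is thin, so
its clash envelope is small), or the 70–120 candidate fragments seen on
real proteins (the toy pipeline yields one).  Passing the recovery tests
therefore demonstrates the correctness of the search machinery — grid
exactness, clash handling, deterministic ranking, interface extraction —
not predictive accuracy on real complexes, which additionally depends on
a real ACE parameterization.

## Numerical and scale choices

* Default parameters are the published operating point (ε = 0.1, 1°
  rotations, d = 6 Å, θ = 0.17, window 15/10, threshold 400, x = 0).
  The test configuration (`TEST_PARAMS`) coarsens to ε = 0.5 (3 Å
  pitch) and 60° rotations, at which one toy dock enumerates ~1 800
  poses and runs in seconds; the recovery study uses 20 seeds and the
  acceptance script 5.
* Rotations are validated orthonormal (det +1) to 1e-9; anchor
  transforms map a_i exactly and a_j to 1e-6; anchors closer than twice
  the grid pitch are skipped as degenerate (the cap becomes
  ill-conditioned).
* Tie-breaks are lexicographic everywhere (alignment end cells, grid
  indices), making every pipeline stage deterministic.
* PDB I/O keeps the first model, drops HETATM/waters/hydrogens (the
  contact statistics are heavy-atom based; a flag keeps hydrogens for
  I/O fidelity), and resolves alternate locations by highest occupancy
  with ties to altloc 'A'.  Coordinates round-trip at the format's
  1e-3 Å precision.

## Known limitations

* Subunits are rigid; no refinement, flexibility, or FFT-style search.
* The shipped energy table is a labelled synthetic stand-in (see above).
* Frame equivariance of the full pipeline holds exactly for
  whole-lattice translations of B; arbitrary sub-Å motions of B can
  relabel the clash/surface lattices and perturb results near label
  boundaries — inherent to phase-anchored grids.
* The published O-notation grid counts leave the lattice geometry open;
  the cubic/polar constructions here are documented choices, so absolute
  pose counts are implementation-specific even though the contracts
  (membership, pole inclusion, determinism) are exact.
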