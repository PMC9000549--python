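# Methods

`channelgate` implements the trajectory-analysis layer used to
characterize gating of a voltage-gated proton channel (Hv1-type
voltage-sensor domain): water-wire connectivity, hydrogen-bond and
salt-bridge tracking, helix/sidechain z-kinematics, and pore-radius
profiling.  It analyzes trajectories; it does not run molecular
dynamics, build systems, or model proton transfer.

## Conventions

Coordinates are Å throughout; *z* increases toward the extracellular
side, with the membrane slab given as `(z_lo, z_hi)` (default ±18 Å,
i.e. a 36 Å membrane).  The four transmembrane helices are the residue
ranges S1 = 97–120, S2 = 133–157, S3 = 166–188, S4 = 193–214
(configurable).  Times are ns; neither supported trajectory dialect
carries time stamps, so frame times are `index × dt` with `dt` a reader
argument (default 0.1 ns).  All readers round coordinates to 3 decimals
(PDB precision), which makes write/read round-trips bitwise exact.

Van der Waals radii come from a bundled Bondi-type element table
(C 1.70, N 1.55, O 1.52, H 1.20, S/P 1.80 Å, ...); unknown elements get
1.70 Å with a logged warning.

## Water-wire classification

A frame is *continuous* when the water oxygens inside the channel form a
chain across the membrane with every adjacent O–O distance **strictly
below** 3.4 Å.  Operational choices the criterion itself leaves open:

- *In the channel* means inside a cylinder of radius 8 Å (default) about
  the z-axis through the centroid of the four-helix heavy atoms, with z
  within the membrane slab widened by a 2 Å boundary margin.  No
  selection volume is canonical here; the cylinder is the simplest shape
  matching a near-axial pore.
- *Connecting the two sides* means the adjacency graph has one connected
  component containing an oxygen with z ≥ z_hi and one with z ≤ z_lo.
- Only water oxygens participate; hydrogens and protein atoms never
  bridge a wire.
- The reported spanning path is the fewest-hop chain, ties broken toward
  the smallest atom-index sequence, so outputs are reproducible.

Occupancy is the mean of the per-frame booleans over the analyzed
(post-equilibration) frames; run lengths of consecutive continuous
frames measure wire lifetime.  Raising the cutoff can only add edges, so
continuity is monotone in the cutoff (property-tested).

## Hydrogen bonds and salt bridges

A D–H···A triple is a hydrogen bond when the donor-heavy to
acceptor-heavy distance is ≤ 3.4 Å **and** the D–H···A deviation from
linearity is ≤ 30°.  The distance is heavy–heavy by default — the same
3.4 Å number as the water-wire criterion — with an H···A mode available;
note the deliberate asymmetry that the H-bond cutoff is inclusive (≤)
while the wire cutoff is strict (<).  Donor–hydrogen pairs are detected
geometrically (H within 1.2 Å of an N/O in the same residue), so any
topology with explicit hydrogens works without bond tables; topologies
without hydrogens can use a distance-only mode.

A salt bridge is the subset of H-bonds with an Arg/Lys sidechain
nitrogen donating to an Asp/Glu carboxylate oxygen.  The partner table
reports, per (basic, acidic) pair, the fraction of frames with at least
one such bond, plus the dominant partner per acidic residue — the
summary in which partner switching of the S4 arginines (Asp108 → Asp181)
appears.

## Kinematics

Helix motion: per frame, the z of each helix's Cα centroid minus the z
of the **pooled** Cα centroid over the union of the four ranges (not a
mean of means).  With the pooled center, the atom-count-weighted sum of
the four series is identically zero — an exact invariant we test — and
whole-channel translation cancels.  Series are optionally re-zeroed at
the first analyzed frame (displacements rather than absolute offsets);
both forms are available because either could be plotted.

Sidechain tracks (e.g. the S4 arginines, or the Phe146/Leu143 gate
against the Asp108 anchor) are the z of the sidechain-heavy-atom
centroid (heavy atoms beyond the backbone) after rigidly superposing
each frame onto the first analyzed frame using the anchor residue's
heavy atoms.  Superposition uses the Kabsch least-squares rotation
(via SVD, reflections excluded by flipping the smallest singular vector)
with unweighted geometric centroids — no mass weighting, matching the
Cα-centroid convention.  Collinear fit selections are rejected as
degenerate.

Equilibration detection slides a least-squares line of length `window`
(default 10 frames) along the RMSD-vs-frame series and returns the start
of the first window whose |slope| < `slope_tol` (default 1e-3 Å/frame).
A constant series yields 0; if no window qualifies the latest start is
returned with a warning.  The plateau criterion itself is a design
choice — only "determined by RMSD" is canonical.

## Pore profiling

For each z-slice the pore radius is

    radius(z) = max over centers c in the slice plane of
                min over atoms i of ( |c − x_i| − vdw_i ),

clamped to [0, r_max] (default 10 Å), over all atoms of the four helix
ranges.  Candidate centers are confined to the structure's radial extent
about the axis (capped at r_max): without that bound the maximization
escapes past the wall into open solvent for any structure narrower than
r_max.  The inner objective is 1-Lipschitz in c, so a coarse grid
(default 0.25 Å) is refined by deterministic branch-and-bound: keep
candidates whose Lipschitz upper bound can still beat the incumbent,
halve the spacing, and stop when the bound guarantees the optimum within
0.005 Å.  Candidates falling outside the search disc are projected onto
its boundary rather than dropped, so boundary maxima stay covered.

This differs from the classic HOLE approach in two documented ways: the
sphere center is confined to the slice plane (adequate for near-axial
pores; no tilted-axis tracing), and the stochastic Monte-Carlo/annealing
walk is replaced by the deterministic bounded search — repeated runs are
bitwise identical.  Deleting an atom raises the objective pointwise and
so never shrinks any slice radius, *except* in the edge case where the
deleted atom alone defined the radial search extent; the monotonicity
tests use deletions that preserve the extent.

A pore is passable for water when its minimum radius reaches 1.15 Å, the
accepted single-file water threshold; equality passes.

## Isoelectric points

Net charge is the Henderson–Hasselbalch sum over sidechain groups
(Arg, Lys, His basic; Asp, Glu, Cys, Tyr acidic) plus optional termini,
and the pI is its unique root on pH 0–14 (the charge is strictly
decreasing), found by bisection to 1e-9 pH — far tighter than needed,
so the "charge vanishes at pI" property holds to 1e-6.  Two standard
pKa tables are bundled (EMBOSS-style and Lehninger-style).  Published
pI values for the same peptide differ between tools precisely because
of the table; we therefore treat helix pI *rankings*
(S3 < S1 < S2 < S4: S3 most acidic, S4 arginine-rich most basic) as the
meaningful output, not absolute values.  Helix sequences are user input;
the test suite uses synthetic stand-in peptides whose composition
mirrors the helices' charge makeup.

## Synthetic ground truth

The generator builds a four-helix scaffold — four quadrant arcs of
pseudo-helix carbon atoms (default 19 rings of 3 atoms per helix, wall
radius 8 Å, length 36 Å), one residue per ring numbered inside the
helix ranges — plus idealized gate residues (Asp108, Leu143, Phe146,
Phe178, Arg204) with inward-pointing sidechains; the arginine carries
explicit hydrogens at ~1.0 Å so angle criteria are exactly computable.
It then plants facts a scientist would want to recover:

- **Wire frames**: exactly `round(fraction × n_frames)` frames (the
  product must be integral) drawn without replacement by a seeded RNG
  carry an axial water chain at 2.8 Å spacing spanning the slab; every
  other frame gets exactly one 4.0 Å gap at a seeded interior position —
  unambiguously beyond the 3.4 Å cutoff.
- **Helix schedules**: per-frame rigid z-offsets per helix.
- **Contacts**: on scheduled frames the Arg guanidinium is placed
  against the Asp carboxylate in ideal bidentate geometry (two linear
  N–H···O bonds at 2.9 Å); off-frames park it 6 Å away.
- **Gate drift**: a linear z-drift of one gate sidechain.

All planted facts go into a manifest (JSON-serializable), and
`verify_manifest` re-runs hydration, kinematics, interactions and pore
stages and diffs against it — the pipeline's end-to-end oracle.
Coordinates are rounded to 3 decimals at generation, so emitted
multi-model PDB round-trips are bitwise exact and planted offsets are
recovered to ~1e-3 Å (exactly, for offsets with ≤3 decimals).  The
geometry is idealized: no force field, no thermal noise, no sidechain
conformational realism.  Passing these tests shows the *analysis* is
correct on unambiguous inputs; it says nothing about force-field or
sampling quality of real simulations.

## Problem sizes and reproducibility

Tests run the generator at 4–200 frames and ~300 atoms, pore oracles on
20–50-atom slices against an exhaustive 0.005 Å grid, and superposition
against an Euler-grid rotation search — sizes chosen so the whole suite
and the acceptance script complete in a couple of minutes on one core.
Pipeline CSVs use fixed 6-decimal formatting and contain no timestamps;
identical configurations reproduce byte-identical outputs.

## Known limitations

- The pore profiler assumes a near-axial, z-aligned pore; strongly bent
  channels need HOLE-style axis tracing, which is out of scope.
- Water selection is a static cylinder; real pores have irregular lumen
  shapes, so the cylinder radius is a sensitivity parameter.
- The H-bond donor inference is geometric; exotic protonation states are
  only as good as the hydrogen placement in the input.
- No periodic-boundary imaging: inputs are assumed whole (true for the
  synthetic systems and for typical post-processed trajectories).
- Membrane thickness for the field bookkeeping (E = V/z) is a user
  input, default 36 Å; how it is best measured is left to the user.
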