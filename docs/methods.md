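# Methods

## Scope and model

`vacuform` analyses a protein's transfer between three environments —
bulk solution, vacuum, and re-solvation — from structures and replica
trajectories alone. It performs no dynamics: inputs are conformations
(single- or multi-model PDB, optionally XYZ), and all physics enters
through three geometric observables (collision cross-section, solvent-
accessible surface area, van-der-Waals volume), distance-based contact
and hydrogen-bond criteria, and a rule-based protonation protocol.

Coordinates are Å everywhere; residue indices are 0-based in code and
1-based in files and reports. Structures may be heavy-atom only; the
only analysis that prefers hydrogens is hydrogen-bond counting, which
otherwise falls back to a flagged donor-heavy-atom distance proxy.

## Protonation protocol

Electrosprayed proteins carry a fixed net charge; to model the vacuum
species the solution structure's charge must be raised to that state.
The protocol mirrors standard practice for charge-state assignment:

1. **Solution charges** at pH 7: Asp/Glu −1, Lys/Arg +1, His 0, +1/−1
   on each chain's N/C terminus (rule table configurable).
2. **Candidate exposure.** Per-residue SASA (sum of member-atom
   accessible areas) is averaged over a set of solution frames;
   residues of the six high-gas-phase-basicity types (Lys, Arg, His,
   Gln, Asp, Glu) with mean SASA below **50 Å²** are discarded —
   buried residues are unlikely to meet excess protons. The threshold
   is strict `<`: a residue at exactly 50 Å² survives.
3. **Ranking.** Survivors are sorted by gas-phase basicity descending;
   ties break by larger SASA, then lower residue index. The shipped GPB
   table (kJ/mol: Arg 1006.6, Lys 951.0, His 950.2, Gln 937.8, Glu
   909.0, Asp 886.0) follows the literature ordering; only the ordering
   matters and the table is user-overridable.
4. **Coulomb exclusion.** A candidate adjacent to a +1 residue is
   skipped. "Adjacent" defaults to sequence position ±1 in the same
   chain — the only parameter-free reading — with an optional spatial
   mode (charged-group centroid within a cutoff). Backbone termini
   count as charges here, since the repulsion argument applies equally.
5. **Symmetric assignment.** The ranked, non-excluded list is walked;
   each accepted position is protonated in *all* sequence-identical
   chains simultaneously (consuming n_chains charge units), stopping
   exactly at the target. Protonating Asp/Glu neutralizes the
   carboxylate (−1→0); His/Gln gain +1; Lys/Arg are already protonated
   at pH 7 and are recorded but never re-protonated. A deficit not
   divisible by the chain count is a parity error; exhausting the list
   reports the shortfall.

Every visited site is recorded with its outcome (selected / excluded
and why), so the emitted plan is a complete audit trail.

## Geometry kernels

**SASA (Shrake–Rupley).** Each atom's sphere is expanded by the probe
radius (default 1.4 Å, water-like) and sampled with a deterministic
Fibonacci lattice (default 960 points); the accessible fraction is the
share of points inside no other expanded sphere. Deterministic for a
fixed point count; the isolated-sphere closed form 4π(r+p)² is exact.

**Volume.** Voxel counting (default 0.3 Å) of grid centers inside at
least one atom sphere, over a bounding box padded by the largest
radius. Single-sphere error at 0.2 Å voxels is under 3 %.

**CCS (projection approximation).** The rotationally averaged area of
the 2-D projection of probe-expanded spheres (default probe 1.0 Å,
helium-like). Orientations are seeded uniformly random rotations; the
per-orientation union area is measured by deterministic rasterization
at 0.5 Å pixels, so randomness enters only through the orientation
draw and the reported Monte-Carlo standard error is the
orientation-to-orientation s.e.m. (scales as 1/√n). A fine-grid oracle
(fixed Fibonacci viewing directions, 0.1 Å pixels, ≤100 atoms) serves
as an independent cross-check; the two agree within 1 % on small
systems. No trajectory-method calibration is applied: the plain
projection approximation is the defined quantity, and an optional
multiplicative calibration constant defaults to 1.0. Absolute CCS
values therefore carry method-level offsets relative to calibrated
estimators; within-pipeline comparisons (compaction, recovery) do not.

## Trajectory metrics

RMSD uses Kabsch least-squares superposition (proper rotations only;
<3 atoms or collinear selections are rejected). Replica series report
mean ± sd across replicas at each time point; time-window averages
report the s.e.m. of the pooled values — the two-level convention for
replica ensembles. The ensemble-average structure is computed
iteratively (superpose all frames on the running mean until it moves
<1e-6 Å), and RMSF is measured about it per residue (Cα by default).
Contacts use minimum heavy-atom distance ≤ 3.5 Å; occupancy is the
fraction of (replica, frame) observations showing the contact, so 0
means "never, in any replica". Hydrogen bonds require donor–acceptor
≤ 3.5 Å and H–D–A angle ≤ 30° (GROMACS-like defaults), donors being
N/O with an attached H (≤1.25 Å); intra-residue pairs are ignored.

## Recovery quantification

All three size metrics are treated uniformly. With tail averages over
the final `tail_fraction` of each series (default 0.1 — the analogue of
a 50 ns tail on 500 ns trajectories):

- compaction % = 100 · (bulk − vacuum_tail) / bulk,
- recovery % = 100 · (1 − |bulk − rehydration_tail| / bulk).

Recovery uses the absolute gap deliberately: over-expansion past the
bulk reference is also a failure to recover. Contact maps are binarized
at occupancy ≥ 0.5 (explicit config; raw matrices are always emitted)
and compared as sets of unordered off-diagonal pairs: the restored
fraction |bulk ∩ rehyd|/|bulk| and the persistence of vacuum-only
contacts |(vac \ bulk) ∩ rehyd|/|vac \ bulk|.

## Synthetic data and what it does (not) show

The generator produces a deterministic toy homodimer — two identical
24-residue chains of N/CA/C/O/CB pseudo-atoms on a helical body with
one protruding hairpin loop each (a stand-in for the FG-loop-like
periphery of a real coat protein), a fixed residue census (2 Asp, 3
Glu, 3 Lys, 3 Arg, 1 His, 2 Gln per chain → +2 e dimer at pH 7, so the
+10 e target needs exactly 4 sites per chain), and an interface tuned
to a 3.2 Å closest approach. Phase ensembles are affine: frames are the
reference scaled about its centroid by s(t) = s_∞ + (s_0 − s_∞)e^(−t/τ)
plus Gaussian jitter, with designated far-apart residue pairs toggled
into contact per frame with set probabilities.

Defaults (the study conditions for all end-to-end tests): 8 replicas ×
50 frames over a nominal 500 ns per phase; vacuum scale 1 → 0.96
(τ = 60 ns) with 3× loop jitter, ten artificial contacts at p = 0.9;
rehydration scale 0.96 → 0.995 with one contact kept at p = 0.9 and
nine dropped to p = 0.05 (90 % reversal); bulk stationary. Jitter is
σ = 0.05 Å per coordinate: the geometry functionals are nonlinear in
the coordinates, so ensemble averages of CCS/SASA/volume are slightly
inflated relative to the noiseless scaled reference, and σ is kept
small enough that this bias stays well below the programmed effects
(at σ = 0.25 Å the bias would rival the compaction signal itself).

`ground_truth()` evaluates the same geometry kernels directly on the
deterministically scaled (and deterministically toggled, for p ≥ 0.5)
reference — no ensemble sampling — yielding expected compaction and
recovery percentages, expected RMSF σ√3·boost, expected pair
occupancies, and expected contact-set fractions.

Passing these tests shows the *measurement chain* is unbiased and
exactly reproducible under a generative model whose truth is known. It
does not validate force fields, real compaction physics, proton
mobility, or absolute CCS calibration; scale, jitter and toggles are
caricatures of compaction, fluctuation and contact formation.

## Numerical choices and degenerate inputs

- Fibonacci lattices for sphere points and oracle view directions:
  deterministic, quasi-uniform, no RNG.
- Rasterization pixel 0.5 Å (production) / 0.1 Å (oracle); voxel 0.3 Å.
- Candidate ranking ties: GPB ↓, then SASA ↓, then residue index ↑,
  then chain id — a total order, so plans are unique.
- Coincident atoms in SASA are both kept (a zero-area outcome is
  legal) with a logged warning; unknown elements get a 1.5 Å default
  radius and a warning.
- Kabsch on collinear/undersized selections raises instead of
  returning an arbitrary rotation.
- Empty contact windows, empty bulk contact sets, and empty selections
  raise typed errors rather than returning NaNs; the one deliberate
  NaN is the persistence fraction when vacuum introduced no novel
  contacts.
- Pipeline runs are deterministic: every CCS orientation seed derives
  from the config seed and the (phase, replica, frame) index; reports
  serialize with sorted keys, and re-runs are byte-identical.

## Problem sizes

The default scenario (2×24 residues, 3 phases × 8 replicas × 50
frames, 16 CCS orientations/frame) was chosen so a full pipeline run
completes in a few minutes on one CPU while leaving Monte-Carlo errors
an order of magnitude below the programmed effects. Larger ensembles
only tighten the statistics; the acceptance comparisons hold already at
this size.

## Known limitations

- The PDB reader covers ATOM/HETATM/MODEL/TER records only — no
  altLocs, insertion codes, or header metadata.
- The projection approximation systematically underestimates CCS of
  concave shapes relative to scattering-based methods; use the
  calibration constant if absolute values must match a calibrated tool.
- H-bond proxy mode over-counts (every close N/O pair qualifies); its
  counts are comparable across phases but not absolute.
- The spatial neighbour-exclusion mode approximates charged groups by
  their charged-atom centroid, which is crude for long side chains.
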