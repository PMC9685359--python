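# vacuform

Analytics for proteins transferred from solution into vacuum and back.

Native mass spectrometry and related gas-phase techniques electrospray a
protein out of solution, fix its net charge, and interrogate it *in
vacuo*. Two questions follow for anyone interpreting such experiments
with molecular models: **how much does vacuum exposure distort the
structure** (proteins compact by a few percent in collision
cross-section, with enhanced mobility of peripheral loops), and **how
much of the solution conformation returns when the structure is
re-solvated**? `vacuform` packages the full analysis chain used to
answer both questions, together with a synthetic-data generator that
makes every statistic testable against analytic ground truth.

The pieces, usable independently or as one pipeline:

- **Vacuum protonation-site assignment** — electrospray leaves the
  protein at a known charge state (e.g. +10 e for a coat-protein dimer
  whose solution net charge is +2 e). Extra protons are assigned to the
  six residue types with appreciable gas-phase basicity (Lys, Arg, His,
  Gln, Asp, Glu) by: per-residue solvent-accessible surface area (SASA)
  averaged over solution frames, a 50 Å² exposure threshold, ranking by
  gas-phase basicity (GPB), exclusion of candidates with a positively
  charged neighbour, and chain-symmetric assignment until the target
  charge is met exactly. Protonating Asp/Glu neutralizes (−1→0);
  protonating His/Gln adds +1.
- **Geometry kernels** — Shrake–Rupley SASA (deterministic Fibonacci
  sphere points), grid-voxel van-der-Waals volume, and the
  projection-approximation collision cross-section

  CCS = ⟨ A(ω) ⟩_ω,

  the union area of probe-expanded atomic discs projected along a
  uniformly random orientation ω, averaged by seeded Monte Carlo with a
  reported standard error. A deterministic fine-grid oracle cross-checks
  the estimator on small systems.
- **Trajectory metrics** — Kabsch least-squares superposition RMSD,
  iterative ensemble-average structures, per-residue RMSF, residue
  contact maps (minimum heavy-atom distance ≤ 3.5 Å) with occupancy
  over replicas, and geometric hydrogen-bond counting (3.5 Å / 30°,
  with a flagged distance-only proxy for hydrogen-free models).
- **Recovery arithmetic** — tail-window averages (last 10 % of each
  trajectory), compaction % = 100·(bulk − vacuum)/bulk, recovery % =
  100·(1 − |bulk − rehydrated|/bulk), contact-set restoration and
  persistence fractions, charge bookkeeping.
- **Synthetic three-phase ensembles** — a toy homodimer (two identical
  chains, one protruding hairpin loop each) and bulk/vacuum/rehydration
  replica ensembles generated by time-dependent isotropic scaling plus
  heteroscedastic jitter, with analytically known compaction, recovery,
  fluctuation and contact statistics.

## Worked example

Run the default synthetic scenario end to end (a 2×24-residue homodimer,
8 replicas × 50 frames per phase; vacuum compacts the structure to scale
0.96 and rehydration relaxes it back to 0.995):

```sh
vacuform all --seed 7 --outdir out/
```

which prints the recovery report (abridged):

```
| metric      | bulk ref      | vacuum tail   | rehydration tail | compaction % | recovery % |
| ccs [Å²]    | 1042.0 (±3.8) | 1000.7 (±4.8) | 1042.2 (±4.8)    | 3.96         | 99.98      |
| sasa [Å²]   | 6517.0 (±1.3) | 6411.0 (±4.0) | 6534.8 (±4.6)    | 1.63         | 99.73      |
| volume [Å³] | 2480.2 (±0.7) | 2460.9 (±1.4) | 2485.1 (±1.6)    | 0.78         | 99.80      |

Restored bulk contacts: 1.000 (of 33)
Persistent vacuum-only contacts: 0.077 (of 13)
```

Reading: in vacuum the dimer's rotationally averaged projected area
dropped by 3.96 % (the generator's analytic expectation for scale 0.96
is 3.78 %); after rehydration the cross-section returned to within
0.02 % of the bulk reference; every contact present in the bulk phase
was restored, and 1 of 13 vacuum-induced contacts persisted — the
programmed 90 % reversal. `out/` also contains the per-frame geometry
series (CSV), occupancy matrices (TSV), RMSD curves against both the
bulk and final-vacuum references, the protonation plan, and a run log
with the config hash.

The protonation stage alone, on the same toy dimer:

```
Residue    SASA [Å²]          Solution  Vacuum
HIS16  (A)   116.49 (±1.23)   +0        +1
HIS16  (B)   115.25 (±1.61)   +0        +1
...
Target charge +10 e; resulting +10 e
```

Four sites per chain take the dimer from its +2 e solution state to the
+10 e vacuum charge state, identically in both chains, each site above
the 50 Å² exposure threshold and free of positive sequence neighbours.

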