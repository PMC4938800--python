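# Methods

This note documents the models, conventions and parameter choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Constraint-based conformer generation

The engine rebuilds equilibrium conformers from a single structure by
distance-geometry projection. From the (reduced) structure it extracts a
bound table:

| class | pairs | bounds (Å) |
|---|---|---|
| covalent | sequential Cα–Cα (virtual bond) | 3.80 ± 0.05 (lower 2.90 before proline, admitting the cis form) |
| ligation | flanks of an engineered deletion | 3.80 ± 0.05 |
| hbond | backbone N···O within 3.5 Å, non-labile | d ± 0.15 |
| salt_bridge | opposite-charge side-chain centroids within 5 Å | d ± 0.25 |
| contact | remaining Cα pairs within 8 Å | d ± 1.0 (lower floor 0.5) |

A hydrogen bond is *labile* when its midpoint shell (radius 4.5 Å) contains
polar/charged side-chain heavy atoms or is solvent-exposed: the score is the
polar count plus one when fewer than 10 heavy atoms occupy the shell, and a
score ≥ 3 demotes the bond to loose contact bounds. Releasing solvated
hydrogen bonds is what lets ensembles cross local conformational barriers.

Each conformer starts from the reference jittered uniformly inside a
per-atom box (half-width 1.5 Å) and is swept over the constraints in a
per-conformer reshuffled random order; a violated pair is projected
symmetrically to its nearest bound. Convergence requires the largest
violation of a *fresh verification pass* to fall below 0.05 Å (the in-sweep
maximum alone is not sufficient, because later corrections can re-violate
earlier pairs); the iteration limit is 500 sweeps. Ligation bounds are
rebuild targets — the edited reference still has the deletion gap open — so
they are exempt from the pre-iteration consistency check that otherwise
rejects a bound table the reference violates. Retained conformers are
re-checked against every bound by an independent vectorized pass, and the
ensemble is superposed on all Cα (Kabsch least squares) before return.
Per-conformer seeds are spawned from the master seed, making ensembles
bit-reproducible. The sweep kernel is compiled with numba; all verification
paths are plain numpy.

**Sampling caveat.** Projection of i.i.d. per-atom jitter onto the feasible
set excites short-wavelength deformations efficiently but collective soft
modes only weakly: the sampled amplitude of a domain-scale hinge motion is
set by the jitter's overlap with that mode, not by the full width of the
feasible set. Relative flexibilities across a structure are therefore
meaningful (loose linkers fluctuate more than tightly cross-linked domains,
which the engine tests verify on a two-solenoid fixture with tight
intra-domain and loose linker bounds), but absolute soft-mode amplitudes are
systematically conservative compared with samplers that equilibrate within
the feasible set. The reduced representation (backbone + side-chain
centroid, Cα-only for fixtures) compounds this: results on real structures
are scaled, not literal.

## Synthetic fixtures

**Segmented rod.** An ideal α-helical Cα trace (radius 2.3 Å, rise
1.5 Å/residue, −100°/residue so the Cα virtual dihedral is the right-handed
≈ +50°) is split into segments joined by hinges. Per conformer each hinge
draws a bend angle (axis ⊥ preceding segment) and a twist angle (axis ∥
preceding segment) from a harmonic N(0, σ) or two-state ½N(+Δ,σ)+½N(−Δ,σ)
well and rotates everything downstream about the last Cα before the hinge.

Because the phase repeats every 18 residues (100°/residue), Cα pairs 18
apart give chords exactly parallel to the segment axis, and triplets
(a, a+9, a+18) span planes whose normals are exactly perpendicular to it.
These are the generator's frame vectors and double as the measurement
anchors, so the analysis recovers the planted σ exactly up to sampling
error. The ring anchors are offset by 4 residues from the segment start so
that the bend axis is perpendicular to the inter-segment junction chord —
with the axis parallel to that chord, bending is a pure lever-arm motion
that barely deforms the junction-spanning 4-residue fragments (≈0.23 Å RMSD
even at σ = 30°) and fragment encoding cannot see the hinge; the offset
makes the local deformation commensurate with the bend, as it is at real
protein hinges where bending breaks local backbone geometry.

What the rod does not emulate: side-chain chemistry, anharmonic coupling
between hinges, internal segment elasticity (segments are rigid), and
realistic loop geometry. Passing tests therefore demonstrate correctness of
the estimators on piecewise-rigid motion with known statistics, not fidelity
to any particular protein.

**Potts alignments.** Sequences are Gibbs-sampled (vectorized over chains,
150 burn-in sweeps) from a pairwise model with fields h ~ N(0, 0.3) and
ferromagnetic couplings J·δ(a,b) on planted pairs; defaults L = 8+8, q = 8,
J = 2, n = 2000 — enough sequences that the planted pair separates cleanly
from the finite-size MI background, the regime the redundancy-filtered
biological alignments (>1,400 effective sequences) are in. Couplings
|J| > 6 trigger a non-mixing warning. Synthetic organisms carry one gene
pair each with gene distance |N(18, 24)| to exercise locus-proximity
pairing. Phylogenetic correlation between sequences is *not* emulated
(chains are independent), so sequence reweighting is exercised only by
duplication tests.

## Essential dynamics

PCA is Cα-only and mass-unweighted; population (divide-by-N) statistics
everywhere, so Σλ equals total coordinate variance exactly and per-PC
projection variances equal λ. Eigenvector signs are fixed by making each
vector's largest-magnitude component positive. Conformer spread is
σ = √Σ_{k∈S} λ_k converted Å→nm, with a bootstrap SD obtained by resampling
conformers in projection space. PC pseudo-trajectories are mean + a·√λ_k·v_k
on an amplitude grid; attributing an angle width to a single PC uses
standard-normal weights on the grid, which reproduces the ensemble width
when the angle responds linearly along the mode (curvature enters at
O(σ²) ≈ 1–2% at σ = 10°, inside the stated 10% tolerance).

## Structural alphabet

Fragments are 4 consecutive Cα, indexed by their first residue; windows
never bridge numbering gaps or deletion sites. Encoding is
minimum-Kabsch-RMSD over the library (ties to the lowest letter index),
batched with a closed-form SVD RMSD over conformers. The shipped 25-letter
library is a synthetic stand-in built from idealized Cα internal geometry
(virtual bond 3.8 Å; virtual-angle/dihedral basins of helix, sheet and
loop); it is adequate for fixtures built from the same geometry family and
for contract testing, but it is not a fitted fragment library — encoding of
real structures should substitute a library derived from the PDB via the
same JSON format (id, 12 coordinates, class per letter).

## Correlation networks

nMI = (I − ε)/H_joint in bits, clamped to [0, 1], with the first-order
finite-size bias ε = (B_i−1)(B_j−1)/(2N ln 2), B the observed state counts;
H_joint = 0 defines nMI = 0. Both the normalization and ε can be switched
off, which is how oracle tests pin the plug-in quantities to 1e-12. PC
projections are discretized into equal-occupancy (quantile) bins, default
10 — equal-width bins concentrate mass pathologically for the heavy-tailed
projections of hinged systems. Significance is the 95th percentile of
within-column shuffle nulls (default 200 shuffles, seeded). Centrality is
the principal eigenvector of the thresholded matrix by power iteration
(tolerance 1e-10), scaled to max 1. Nodes are profile peaks with prominence
≥ 0.2 × profile max (scipy find_peaks); the prominence default is this
package's own choice.

## Hinge mechanics

Vectors are configuration data: lines through two Cα anchors or normals of
three-Cα planes, resolved per conformer; difference angles are referenced to
the ensemble-average structure (0°). Angles are unsigned unless the pair
names a sign vector, in which case the sign of (v₁×v₂)·n̂ applies — rotation
pairs need signed ± histograms, bending pairs usually do not. Histogram fits
(Freedman–Diaconis bins, least squares on bin centers) compare
a·exp(−½((x−x₀)/b)²) against the symmetric two-state form
a·[exp(−½((x−x₀)/b)²)+exp(−½((x+x₀)/b)²)]; the higher R² is preferred and a
non-converging fit is recorded, not raised. Torsional stiffness is the
equipartition value κ = k_B T/σ_rad² with exact k_B and default T = 300 K
(so k_BT = 4.142 pN·nm); κ is reported per well width — the single fit's b
for a one-state well, the per-state b for a two-state well — and which
width definition a published number used must be known before comparing.
Coupling relations between two angle series are classified linear /
saturating end-state (clamped linear) / parabolic elastic well by adjusted
R²; the clamp model nests the linear one, so the parameter penalty decides
when the data never saturate.

## Coevolution

Redundancy filtering is greedy keep-first at 80% identity over non-gap
matched columns (the output is a fixed point of the filter). Pairing is
per-organism by smallest |locus_A − locus_B| with each sequence used once
and pairs at ≥ the gene-distance cap (default 100) discarded; the default
matcher is greedy, with optimal assignment (linear_sum_assignment) available
for few-paralog organisms. mfDCA: inverse-cluster-size reweighting at 80%
identity, pseudocount 0.5 as a fraction (fᵢ ← (1−λ)fᵢ + λ/q), gap treated as
an ordinary 21st state when present, couplings from −C⁻¹ over the first q−1
states, and direct information from the two-site model with self-consistent
single-site fields. APC-MI subtracts MIᵢ·MI·ⱼ/MI·· over off-diagonal
entries; on a rank-one background the residual is O(1/L), not exactly zero.
The top-fraction selector reports the empirical 2σ/3σ upper-tail fractions
alongside the edge list rather than asserting which convention a published
cutoff used.

## Pipeline

One master seed fans out through SHA-256 into named per-stage streams
(ensemble, shuffles, bootstrap, coevolution), so stages can be rerun in
isolation and the full report is bit-identical under a fixed config+seed
(hashed and asserted in tests). Configs reject unknown keys. Deletion runs
regenerate the edited structure with the engine and report per-hinge σ
deltas against the native run; `compare_ensembles` aligns on common residues
and errors on unrelated molecules.

## Problem sizes

Defaults were chosen so a full test run and the acceptance script each
complete in minutes on one CPU: fixture ensembles of 1,024–4,096 conformers
(4,096 where a 5% recovery tolerance needs the sampling error below it),
engine ensembles of 200–500 conformers on ~30–60 atom fixtures, 20 replicate
2,000-sequence alignments for the DCA rank-1 rate, and 100–200 shuffles for
null thresholds. The engine accepts the scale the original full-atom
workflow used (65,536 conformers) through the same `n` parameter.

## Known limitations

- The engine is a reduced-representation analogue: no solvent model, no
  side-chain rebuilding, no full-atom packing; absolute amplitudes on real
  accessions are scaled/approximate by construction.
- The shipped structural alphabet is synthetic (see above).
- The shipped FliM/FliG vector configuration carries placeholder anchor
  residue ids meant to be edited against the structure in hand.
- Ensembles are unordered samples: no time-correlation or kinetic quantity
  is defined anywhere in the package.
- The two-state well recovery assumes the symmetric equal-weight form;
  asymmetric bimodality is reported only through the R² of the symmetric
  fits.
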