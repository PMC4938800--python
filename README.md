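# rotormech

Conformational-ensemble mechanics of the bacterial flagellar switch complex
— and of any other hinged multi-domain assembly you can express as a
structure plus distance constraints.

## The problem

Switching of flagellar rotation is driven by the FliM–FliG rotor ring: CheY
binding at the FliM middle domain (FliM_M) must reorient a distant FliG
C-terminal "torque helix" that contacts the stators. Crystal structures show
single snapshots; the mechanics live in the conformational ensemble around
them. This package rebuilds that analysis chain as a tested library:

1. **Ensemble generation** — equilibrium conformers are rebuilt from one
   structure by iterative satisfaction of pair-distance bounds (covalent,
   hydrogen-bond, salt-bridge and loose contact classes, with solvated
   "labile" hydrogen bonds demoted to loose bounds), in a reduced
   representation (backbone N/CA/C/O + side-chain centroid).
2. **Essential dynamics** — PCA of Cα fluctuations: the covariance
   C = ⟨Δx Δxᵀ⟩ is eigendecomposed, the first few eigenvectors span the
   collective motions, λ_k their variances (Å²), and the conformer spread
   σ = √(λ₁+λ₂+λ₃) (nm) measures overall flexibility.
3. **Structural-alphabet networks** — each overlapping 4-residue Cα fragment
   of each conformer is encoded as the nearest letter of a fragment library;
   normalized mutual information nMI = (I−ε)/H_joint between fragment
   columns (nMI_local) and between columns and binned PC projections
   (nMI_PC) localizes the hinges that generate the collective modes;
   eigenvector centrality of the nMI network ranks them.
4. **Hinge mechanics** — signed difference angles between named structure
   vectors (Cα lines and plane normals) quantify bending/rotation per hinge;
   single vs symmetric-double Gaussian fits discriminate harmonic from
   two-state wells; κ = k_BT/σ² converts well widths to torsional
   stiffnesses; serial hinges are tested for amplification.
5. **Coevolution** — paired inter-protein alignments (organism + genomic
   locus proximity matching), mean-field direct coupling analysis and
   APC-corrected mutual information recover coupled residue pairs, which are
   classified against structure contacts and the dynamic network.
6. **Deletion mimics** — residue deletions (with ligation of the flanks in
   the constraint table) emulate rotation-locking linker deletions; paired
   native/deleted runs report per-hinge flexibility changes.

Every stage is testable without downloads: a synthetic-fixtures module
generates segmented-rod ensembles with known hinge bend/twist statistics
(harmonic or two-state wells) and Potts-model paired alignments with planted
couplings, so parameter recovery is checked against exact ground truth.

## Worked example

```python
import numpy as np
from rotormech import fixtures, dynamics, mechanics, network
from rotormech.alphabet import default_library, encode_ensemble

gt = fixtures.HingeGroundTruth(
    segment_lengths=(36, 36),
    hinges=(fixtures.HingeSpec(bend_sigma=10.0, twist_sigma=6.0),),
    seed=1)
ens, gt = fixtures.make_hinge_ensemble(gt, n=4096, seed=1)

defs = fixtures.hinge_vector_definitions(gt)
pairs = fixtures.hinge_angle_pairs(gt)
bend = mechanics.angle_sigma(mechanics.angle_series(ens, pairs["hinge0_bend"], defs))
twist = mechanics.angle_sigma(mechanics.angle_series(ens, pairs["hinge0_twist"], defs))
print(f"bend sigma  = {bend:.2f} deg   (generator: 10.00)")
print(f"twist sigma = {twist:.2f} deg   (generator:  6.00)")

pca = dynamics.fit_pca(ens)
frac = pca.eigvals[:3] / pca.eigvals.sum()
print(f"PC1-3 variance fractions = {frac[0]:.3f}, {frac[1]:.3f}, {frac[2]:.3f}")

ft = encode_ensemble(ens, default_library())
prof = network.nmi_pc_profile(ft, pca, 1)
nodes = network.call_nodes(prof, ft.positions)
print("called hinge nodes (first residue of fragment):",
      [key for _, key in nodes])
```

prints

```
bend sigma  = 9.96 deg   (generator: 10.00)
twist sigma = 5.98 deg   (generator:  6.00)
PC1-3 variance fractions = 0.973, 0.015, 0.009
called hinge nodes (first residue of fragment): [('A', 34)]
```

The two-segment rod has one hinge between residues 36 and 37: the angle
series recovers the generator's bend and twist widths to within sampling
error, PC1 carries ~97% of the variance (a single dominant collective
motion), and the nMI_PC profile calls exactly one node, at the fragment
window spanning the hinge.

A `rotormech` console script exposes the stages
(`fixture hinge|potts`, `ensemble generate`, `dynamics`, `encode`, `run`,
`compare`, `coevolve`); `rotormech run --config cfg.json` executes the whole
pipeline from a single JSON config with one master seed and writes a
machine-readable report that is bit-identical on reruns.

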