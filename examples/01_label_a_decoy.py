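"""Generate a decoy of a toy protein and compute its ground-truth lDDT.

Builds an idealized 30-residue reference from dihedral angles, perturbs the
backbone dihedrals of a random 30% of residues by 10 degrees (sd), rebuilds
the chain and scores it against the reference with the local Distance
Difference Test (CA atoms, 15 A inclusion radius, 0.5/1/2/4 A tolerances).
"""

import numpy as np

from graphmqa import compute_lddt, perturb_dihedrals, toy_reference

reference = toy_reference(30)
ensemble = perturb_dihedrals(reference, sigma=10.0, n_decoys=1, seed=42)
decoy = ensemble.decoys[0]
labels = compute_lddt(decoy, reference)

print(f"sequence          : {reference.sequence}")
print(f"global lDDT       : {labels.global_lddt:.4f}")
print("per-residue lDDT  :",
      " ".join(f"{v:.2f}" for v in labels.local_lddt))
worst = int(np.argmin(labels.local_lddt))
print(f"worst residue     : {worst + 1} ({reference.sequence[worst]}) "
      f"at lDDT {labels.local_lddt[worst]:.3f}")
print(f"pairs inside 15 A : {int(labels.threshold_mask.sum()) // 2}")
# A global lDDT near 1 means the decoy preserves almost all local geometry;
# the per-residue profile shows exactly where the perturbation distorted it.
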