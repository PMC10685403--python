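"""Assemble the network's inputs: feature bundle plus mock embeddings.

The feature bundle concatenates per-residue channels (position encoding,
Meiler descriptors, BLOSUM62 profile, secondary structure, dihedrals,
triangular location, contact order, a voxelized local environment) and
per-pair channels (Gaussian RBF distance expansions for the five backbone
atoms, frame-relative displacement, frame rotation quaternion, pair contact
order, relative-index encoding).  The deterministic mock provider supplies
language-model-shaped embeddings so the whole pipeline runs without any
model downloads.
"""

from graphmqa import MockEmbeddingProvider, featurize, toy_reference

s = toy_reference(30)
bundle = featurize(s, k=10)
emb = MockEmbeddingProvider(mode="single", seed=0).embed(s)

print(f"node features : {bundle.node_features.shape}")
print(f"edge features : {bundle.edge_features.shape}")
print(f"KNN topology  : {bundle.knn_indices.shape}")
print(f"layout hash   : {bundle.layout_hash}")
print("node channels :")
for name, (off, size) in bundle.layout["node_channels"].items():
    tag = "  (pose-sensitive)" if name in bundle.layout["pose_sensitive"] else ""
    print(f"  {name:<20} offset {off:>4} size {size:>4}{tag}")
print(f"sequence embedding  : {emb.seq_embedding.shape}")
print(f"structure embedding : {emb.struct_embedding.shape}")
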