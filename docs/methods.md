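# Methods

`graphmqa` predicts residue-level protein model quality on the lDDT scale
with a graph-coupled encoder–decoder operating on a five-atom backbone
representation (N, Cα, C, O, Cβ).  This note records the model, the label
definitions, the synthetic-data protocol, numerical choices and the design
decisions taken where more than one reasonable option existed.

## Quality labels

Ground truth is the local Distance Difference Test computed on Cα atoms.
For residue *i* against reference distances d_ref and model distances
d_mod:

    lDDT_i = mean over s ∈ {0.5, 1, 2, 4} Å of
             |{ j ≠ i : d_ref(i,j) < 15 Å and |d_mod(i,j) − d_ref(i,j)| < s }|
             / |{ j ≠ i : d_ref(i,j) < 15 Å }|

The inclusion radius is measured on the **reference** (the standard lDDT
convention), there is no sequence-separation exclusion beyond j ≠ i, and a
residue with no in-radius partner is reported as 1 with an `undefined`
flag.  The global score is the mean of the local scores.  Cα-only lDDT was
chosen over full-atom lDDT because the method targets residue-level
quality; side chains never enter the pipeline.

The same pairwise quantities, discretised, are the decoder's training
targets: a 5-class error bin per pair with half-open edges
[0, 0.5), [0.5, 1), [1, 2), [2, 4), [4, ∞) — a boundary value |Δd| = 0.5
falls deterministically in the second class — and a binary mask marking
pairs with d_ref < 15 Å.

## Input features

**Node channels** (per residue): a 16-dim sinusoidal encoding of the
sequence index; the 7 Meiler physicochemical descriptors; the residue's
20-dim BLOSUM62 row; a 3-state secondary-structure one-hot; sin/cos of
(φ, ψ, ω); the triangular-location descriptor (3 side lengths, 3 mean
vertex distances, sin/cos of 3 Euler angles); node contact order; and an
8×8×8 voxel occupancy grid of backbone atoms in a 16 Å cube, expressed in
the residue's local frame.

**Edge channels** (per residue pair): 16-center Gaussian RBF expansions
(centres uniform on [0, 20] Å, σ = centre spacing) of the five
backbone-atom distance maps (N–N, Cα–Cα, C–C, O–O, Cβ–Cβ); the
displacement s_ij = R_iᵀ(Cα_j − Cα_i) in residue i's frame; the quaternion
of R_iᵀR_j with non-negative scalar part; pair contact order
O_ij = |i−j| / d_ij; a 16-dim sinusoidal encoding of the sequence
separation clipped to ±32; and a physicochemical pair-energy channel that
is zero-filled by default (a provider hook accepts an external energy
function — computing such terms requires a dedicated force-field package).

Local frames come from Gram–Schmidt on (N, Cα, C).  Secondary structure
uses a dihedral-region rule (helix: φ ∈ [−100, −30], ψ ∈ [−80, −5];
strand: φ ∈ [−180, −80], ψ ∈ [80, 180] ∪ [−180, −170]; else coil) so the
package needs no external assignment binary; the interface accepts a
plug-in assigner.  The rule is discontinuous at region boundaries, so
fixtures avoid boundary dihedrals.

Triangular location picks, for residue i (point P1), the Cα farthest from
it (P2), then the Cα farthest from P2 excluding both (P3); ties break to
the lowest residue index.  e_x is the unit vector toward P3, e_y the
rejection of P2−P1 from e_x, and the Euler angles (intrinsic ZYX — the
convention had to be fixed here) describe the frame (e_x, e_y, e_x×e_y).
When P1, P2, P3 are collinear the rejection vanishes; e_y falls back to an
arbitrary unit vector orthogonal to e_x and the descriptor is flagged
degenerate.  Side lengths and mean distances are exactly pose-invariant;
the Euler angles rotate with the pose and are the only pose-sensitive
feature channels (the layout metadata marks them, and `featurize` can zero
them when strict end-to-end invariance is required).

Node contact order restricts the sum to neighbours within 15 Å,
consistent with its normaliser R_i (the count of such neighbours):
O_i = Σ_{j: d_ij ≤ 15, j≠i} |i−j| / (R_i·N), with O_i = 0 when R_i = 0.

**Embeddings.** The network additionally consumes language-model-shaped
representations: per-residue sequence embeddings (1280-dim single-sequence
mode; 768-dim MSA mode with a 144-dim per-pair row-attention tensor) and a
512-dim per-residue structural embedding.  Sequences longer than 1022
residues are split in half, embedded per segment and reassembled in order;
lengths ≥ 2044 are refused explicitly rather than silently truncated.
Providers are pluggable; the shipped `MockEmbeddingProvider` is a pure
function of (sequence, seed) with the structural embedding modulated by a
smooth function of the Cα distance matrix, making it pose-invariant but
conformation-sensitive.  The mock provider defines the test conditions;
it carries no evolutionary information, so results with it say nothing
about the accuracy achievable with real language-model embeddings — only
that the architecture can extract structural signal.

## Network

The encoder runs three coupled stages on a residue graph whose edges carry
the pair features above.

1. **Graph transformer** (full attention over all pairs): per head,
   C_ij = softmax_j ⟨q_i, k_j + m_ij⟩/√A_d with a head-specific edge
   projection m_ij; values are W_h h_j + m_ij; heads are concatenated and
   projected.  A scalar sigmoid gate C¹ = σ(Φ_s[h − h̄, h, h̄]) blends the
   updated embedding h̄ with the input h as C¹h + (1−C¹)h̄, followed by
   layer norm.
2. **Invariant point attention** in per-residue rigid frames
   (rotation R_i, translation t_i from the structure): attention logits
   sum a scalar dot product, an edge bias, and −γ_h/2 times the squared
   distances between learned 3-D points carried through the frames;
   outputs concatenate attended scalars, attended edge values, point
   outputs mapped back into the local frame, and their norms.  Each block
   emits a rigid update (local translation and a quaternion built as
   (1, b, c, d)/‖·‖) composed onto the frames, producing refined
   coordinates.  Scalar outputs are invariant and coordinates equivariant
   under global rigid motion by construction.
3. **E(3)-equivariant GNN** on the K-nearest-neighbour graph (K = 30 by
   default; toy graphs use the full neighbourhood since K ≥ N−1):
   messages φ_m(v_i, v_j, Fourier(‖x_i − x_j‖), ε_ij) with sin/cos
   distance features at geometric frequencies; coordinates update as
   x_i + β Σ_j (x_i − x_j)·w(m_ij) with β = 1/(N−1); nodes update from
   the aggregated messages with a residual and layer norm.

The decoder tiles the encoder node representation and a **fresh**
projection of the raw features (separate parameters from the encoder's
input projections) into an N×N pair map alongside the encoder edge
representation, then runs a residual trunk of inverted-bottleneck blocks
— channel norm, 1×1 expansion (4×), GELU, dilated 3×3 convolution, GELU,
1×1 projection — with dilations cycling 1, 4, 9, 16.  Two branch blocks
emit the heads: a 5-class softmax over distance-error bins and a sigmoid
threshold probability.  Both heads are symmetrised by averaging logits at
(i, j) and (j, i).

**Scoring.** With cumulative bin mass M_s(i,j) = Σ_{b ≤ s} P_e(i,j,b) and
threshold probability t_ij, the predicted local score is

    predLDDT_i = Σ_j Σ_{s ∈ T} M_s(i,j) · t_ij / (|T| · Σ_j t_ij),   T = {0.5, 1, 2, 4}.

The 1/|T| normaliser makes a perfect prediction score exactly 1 (without
it the numerator counts four indicators per pair while the denominator
counts each pair once, giving a [0, 4] range); with it, feeding one-hot
ground-truth bins and the exact mask through this formula reproduces the
label lDDT to machine precision — an identity the test-suite checks
against the independent label code path.  Residues whose threshold mass
is zero are reported as 0 with a flag.  The global score is the mean of
the local scores.

GELU uses the standard tanh approximation.  All arithmetic is float64 on
a tape-based reverse-mode autodiff core written for this package; its
gradients are pinned by central-finite-difference checks (primitive-level
and end-to-end through the full network and loss, 1e-3 relative).

## Training

Loss = L_geometric + L_error + L_threshold + L_lddt, all weights 1 by
default and exposed in the config (no principled relative weighting is
known for this setup; unit weights keep every head active).

* L_geometric: MSE between the encoder's refined Cα coordinates and the
  reference after optimal superposition, plus a mean L1 on off-diagonal
  pairwise distances.  The Kabsch alignment is computed outside the
  gradient graph so the arbitrary global pose of the prediction carries
  no gradient.
* L_error: categorical cross-entropy on the error head, masked to pairs
  inside the reference 15 Å radius.
* L_threshold: binary cross-entropy on the threshold head over all i ≠ j
  pairs, computed in the numerically stable softplus form.
* L_lddt: MSE between predicted and true per-residue lDDT.

Optimization is AdamW, learning rate 1e-3 with a multiplicative 0.99
decay per epoch ("1% decay" read as a per-epoch factor), weight decay
0.01, batch size one model.  4% of the models (at least one) are held out
for validation; per-epoch validation Pearson is tracked and the five best
parameter sets retained, the best being loaded at the end.

## Synthetic data

References are idealized backbones grown from dihedrals by sequential
placement with ideal bond geometry (N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å; angles 111.0°/116.6°/121.7°; carbonyl O at 1.231 Å/120.8°;
Cβ by ideal tetrahedral construction at 1.521 Å).  Decoys add Gaussian
noise (sd = σ degrees) to φ/ψ of a random 30% of residues and rebuild the
chain.  The 30% fraction spreads the damage: perturbing everything makes
every decoy uniformly bad, perturbing one residue gives little per-residue
contrast.  No relaxation follows the perturbation — at these σ values the
occasional clash is irrelevant for distance-based labels, and relaxation
would require an external force field.  A greedy diversity filter keeps a
decoy only if its global lDDT against every kept decoy is ≤ 1 − gap.

What the generator emulates: a graded ladder of structural damage with
known per-residue labels, the essential supervision signal for this model
class.  What it does not emulate: real decoy ensembles contain
template-derived and deep-learning-refined models with correlated,
non-local error patterns, physically relaxed geometry and diverse
sequences.  Passing the learning benchmark therefore demonstrates that
the architecture, features, labels, loss and optimization are wired
correctly and can extract structural signal — not that the trained toy
model generalises to real protein models.

Because `sigma = 0` rebuilds the reference's own dihedrals with ideal
covalent geometry, the zero-perturbation ensemble scores exactly 1 only
for references that are themselves idealized (as all synthetic references
are); an experimental reference would be idealized by the rebuild.

## Problem sizes and benchmarks

The shipped configurations are deliberately two-scaled: the default
network (d_node 128, 8 heads, 3 transformer layers, 2 IPA blocks, 2 EGNN
layers, 8 decoder blocks of 64 channels) is the reference architecture;
`NetworkConfig.toy()` (d_node 24, 4 heads, 1 IPA, 1 EGNN, 3 decoder
blocks of 8 channels) is the configuration used by the training
demonstrations and benchmarks, sized so a full benchmark trains in
minutes on one CPU core.

The learning benchmark trains on 200 decoys of a 30-residue toy protein
(σ ∈ {2, 5, 10, 20}°, 50 each, seed 0) for 40 epochs and requires (i)
strictly decreasing epoch-mean training loss over the first 10 epochs and
(ii) held-out per-residue Pearson > 0.5.  A negative control trains on
the same data with labels reassigned across decoys and permuted across
residues; with the structure–quality link severed there is nothing to
converge to, so the control runs fewer epochs (8–12) and must stay below
|r| < 0.2.  The acceptance script repeats the demonstration at a reduced
size (120 decoys, 18 epochs) chosen to keep the whole script in single-
digit minutes while leaving the conclusion unchanged.

## Numerical choices and edge cases

* Farthest-point and nearest-neighbour ties break to the lowest index;
  KNN lists sort by (distance, index).
* Quaternions are sign-fixed to a non-negative scalar part.
* Coincident Cα pairs are skipped (with a warning) in pair contact order;
  an isolated residue has node contact order 0.
* Residues missing N, Cα or C are dropped on reading with a warning;
  missing O is rebuilt from the peptide plane, missing Cβ from ideal
  geometry (flagged).  Consecutive Cα–Cα distances outside (2.0, 4.5) Å
  warn but do not fail.
* Altlocs resolve to highest occupancy; insertion codes order
  lexicographically after the residue number; HETATM records are ignored;
  multi-model files read the first model unless told otherwise.
* Multimers are handled as a single concatenated graph with chain
  identity preserved in the metadata; no interface-specific scoring is
  implemented.
* The ±π wrap of trans ω angles means raw dihedral comparisons must use
  sin/cos; all consumers do.

## Known limitations

* The mock embedding provider carries no evolutionary signal; accuracy
  numbers obtained with it do not transfer to real embeddings.
* Cα-only lDDT ignores side-chain and stereochemical quality.
* The dihedral-region secondary-structure rule is cruder than
  hydrogen-bond-based assignment, especially for irregular strands.
* The decoder sees the full N×N map; memory grows quadratically with
  length, which is acceptable at desk scale but would need cropping for
  long chains.
* Training at the default architecture size on large decoy sets is
  outside the intended scope of the pure-numpy engine.
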