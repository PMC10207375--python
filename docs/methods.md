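# Methods

## The scoring model

The scoring function is an E(n)-equivariant graph network over the atoms of
a bound protein–ligand complex. Inputs are positions (n × 3, Å), node
features (n × 12: a one-hot over the element vocabulary {C, N, O, S, P, F,
Cl, Br, I, B, other} plus one ligand/receptor bit), directed edge indices,
and a 3-wide one-hot edge type (ligand–ligand, ligand–protein,
protein–protein). Edges are built on the fly from a 10 Å cutoff for
ligand–protein pairs and a 2 Å cutoff for intramolecular pairs (closed
boundary), so intramolecular connectivity approximates covalent structure
while intermolecular connectivity is expansive. The binding pocket is the
set of protein atoms within 6 Å (closed) of any ligand atom; everything
farther is discarded before featurization.

Each of the (default 48, desk profile 4) layers computes an edge message
from the two endpoint embeddings, the squared distance, and the edge type;
a one-hidden-layer attention MLP squashes each message — together with the
scaled squared distance, so the gate can resolve geometry directly rather
than only through the bounded message — to e_ij ∈ [0, 1]; node i aggregates
the plain attention-weighted sum of incident messages (no degree
normalization); the feature update is residual. Positions are
updated along relative-position vectors with a scalar per-edge coefficient
(tanh-bounded, scaled by 0.1 Å — a norm-bounded clamp that preserves
rotation equivariance, unlike per-component clipping). The prediction pools
node features only (global average) and applies the head: sigmoid for pose
classification, linear + ReLU for affinity after head replacement. Scalars
are therefore invariant under the full Euclidean group including
reflections, and under atom relabeling; the test suite asserts this to
1e-4 over random transforms.

Deliberate deviations from the reference equivariant formulation, all in
service of attribution or numerical sanity:

* The position update is weighted by the attention score as well. This
  makes "force e_ij = 0" *identical* to deleting the edge from the graph
  (asserted to 1e-5 on random graphs), which is the formal bridge between
  edge-attention attribution and bond masking. Without it, a masked edge
  would still move coordinates.
* Edge messages are tanh-bounded. Attention multiplies messages, so an
  unbounded network can neutralize any attention sparsity pressure by
  inflating message norms, leaving the exported weights uninformative; with
  bounded messages the attention score is the only per-edge gain control.
* The attention MLP input is (m_ij, ‖x_i − x_j‖²/100). A tanh-bounded
  message compresses fine distance differences; feeding the gate the
  distance directly lets it learn a crisp, smoothly graded geometric
  threshold, which is what makes the exported scores rank contacts cleanly.
* Squared distances are divided by the ligand–protein cutoff squared
  (100 Å²) before entering the edge MLP, and the final layer of every
  residual node-update MLP is zero-initialized, so layers start as identity
  maps and activations stay O(1) at any depth. Without these, a 10 Å edge
  contributes d² = 100 to a unit-scale MLP input and the residual stack
  saturates the attention and the output sigmoid at initialization.

The network and its training run on a small reverse-mode automatic
differentiation core over numpy arrays (`eqscore.autodiff`), written for
exactly the operations the model needs; gradients are verified against
central finite differences in the test suite. All arithmetic is float64.

## Training

Stage one is pose classification (binder vs decoy) under binary
cross-entropy on the logit; stage two replaces the output layer with a
freshly initialized linear + ReLU head (bias 1.0, keeping the unit alive —
a zero pre-activation would have no gradient through the ReLU) and
finetunes under squared error on nonnegative affinity labels. The optimizer
is Adam (lr 1e-3, batch 16) with group-aware validation splits: all
examples sharing a `group_id` (binder/decoy variants of one system) land on
the same side, mirroring the leakage concern the dataset filters address.
Training is bit-reproducible from the seeds in `TrainConfig`.

Pose training runs in two phases. The first half of the epoch budget
minimizes the plain task loss with early stopping on validation loss. The
second half adds an L1 sparsity penalty on the attention scores (weight
0.1, averaged over edges and layers) and runs to completion. Applying the
penalty from the start prevents the task from being learned at all (the
gates close before messages carry signal); applying it after the task is
learned lets the task loss hold the decision boundary while the attention
of unneeded edges decays toward zero. Two companions make the penalty
meaningful: tanh-bounded messages (above) and decoupled weight decay
(0.01 on weight matrices), which anchors the overall activation scale so
the penalty cannot be absorbed by downstream amplification. An optional
binarization term e(1 − e) pushing scores toward saturation is exposed in
`TrainConfig` but off by default — it also pushes useful sub-0.5 scores
down, which measurably degrades the attribution readout. The penalty and
decay weights were chosen as the smallest sweep values that make the
attention of planted contacts separate cleanly from the rest on the
synthetic suite; all are exposed in `TrainConfig` and can be set to zero.

## Attribution

Three procedures, all returning per-atom and/or per-edge scores:

* **Atom masking** — score(i) = f(X) − f(X \ {i}); the atom and its
  incident edges are deleted, nothing is rebuilt. An atom whose removal
  would leave no ligand atoms is skipped with a warning.
* **Bond masking** — per undirected eligible edge (both directions removed
  together), score = f(G) − f(G − e). Eligibility defaults to
  intermolecular edges with endpoint distance < 4 Å.
* **Edge attention** — the final layer's e_ij for ligand–protein edges;
  direction pairs are averaged (not summed); a protein atom's score is the
  maximum over its incident intermolecular edges. Edge keys are oriented
  (ligand_atom_id, protein_atom_id).

The diagnostic `distance_rank_correlation` takes the k highest-scoring
protein atoms and computes Spearman's ρ between their scores and the
negated distance to the nearest *polar* ligand atom (N/O or any atom with a
donor/acceptor role), with average ranks for ties, so ρ > 0 means
higher-scored protein atoms sit closer to plausible hydrogen-bonding
partners. The nearest-polar convention is the default; a flag switches to
nearest-any-ligand-atom. Layer choice for the attention readout is the
final layer (recomputed per layer during the forward pass).

## Hotspot maps

Attribution on one structure scores the pocket's protein atoms; repeating
over a fragment screen and averaging per protein atom — matched across
structures by (chain, residue index, atom name), averaged over the
structures where the atom received a score, not zero-filled — yields a
ranked hotspot map. Pharmacophore type comes from the atom's
hydrogen-bonding role; ambiguous atoms ("both"/"none") are typed by the
complementary roles of the ligand atoms their scored edges point to, ties
defaulting to donor. Per-structure scores are used raw; a flag enables
per-structure min–max normalization.

Two companions: a geometric baseline that counts, per protein atom, the
structures in which a complementary-role polar ligand atom lies within
3.5 Å, keeping atoms highlighted in strictly more than 5 structures; and a
stability analysis that recomputes the top-k hotspot set on random subsets
of the screen (default 40 repeats) and reports per-atom inclusion
frequencies plus the mean Jaccard overlap with the full-data top-k.

## Leakage filters

A training ligand is removed when its Tanimoto similarity (2048-bit Morgan
fingerprints, radius 2) to *any* test ligand exceeds 0.8 (strict); a
training protein when its sequence identity to any test protein exceeds 0.8
(strict). Identity is matches / alignment length from one global alignment
(match 1, mismatch 0, affine gaps −2.51/−0.53, non-commensurate with the
match score so that co-optimal alignments cannot differ in match or gap
counts and the identity is well-defined); a flag switches the denominator
to the shorter sequence; multi-chain entries take the maximum over chain
pairs. Unparseable items are removed with reason `parse_failure`. Test sets
always pass through untouched, and size-matched uniform random subsets of
the unfiltered training set are provided as controls that may still contain
test-similar items.

## Fragment-elaboration statistics

Ligand efficiency is docking score / heavy-atom count. For one
(fragment, hotspot) pool — elaborations plus the ground-truth molecule the
fragment was cut from — LEs are standardized to zero mean and unit
variance (population variance by default; a flag selects sample variance;
zero-variance pools standardize to all zeros with a warning, making
ΔSLE = 0 rather than an error), elaborations are sorted descending, and
ΔSLE_α is the mean of the top α = 20 minus the ground truth's standardized
value. Per hotspot, ΔSLE_α is averaged over fragments with at least one
elaboration; hotspots with none report n = 0 and a null mean. The
quasi-active distance thresholds (2 Å for pocket-point hotspots, 3 Å for
protein-atom hotspots) are recorded as metadata; the docking and generative
steps that apply them are outside this package. Fragment enumeration cuts
acyclic single bonds whose endpoints do not lie inside a functional-group
match (amide, ester, sulfonamide, nitro — configurable), emitting both
sides of each cut with a dummy atom at the exit point.

## Synthetic data

The generator emulates the statistical structure the analyses assume:
binding driven by a few polar contacts. Defaults: 12 ligand atoms in a
compact cluster (5 Å ball, ≥3 Å separation), 24 pocket atoms, 4 planted
donor–acceptor contacts at 2.9 ± 0.1 Å, every other ligand–protein pair
≥4.5 Å, nonpolar shell atoms 4.6–5.8 Å out. Binders keep the planted
geometry; decoys rigidly rotate/translate the ligand (3 Å) until fewer than
`label_rule_k` = 3 contacts remain intact (intact = pair within 3.5 Å), so
labels are recomputable from coordinates alone and a distance rule achieves
100% accuracy — the task is solvable by construction. Affinity labels are
the planted-contact count (varied 0–4 per example) plus Gaussian noise
(σ = 0.1), clipped at zero. The fragment screen shares one reference pocket
across structures with 5 contact sites; the dominant site is occupied in
every structure, the others with probabilities 0.8/0.6/0.4/0.3; an
unoccupied site contributes no ligand atom, and every non-contact
ligand–protein pair respects the same ≥4.5 Å floor as the single-complex
generator, so screen structures stay inside the training geometry
distribution. Docking-score tables draw per-molecule ligand efficiencies as
N(effect × quality, 1) against N(0, 1) ground truths, with hotspot
qualities equally spaced on [0, 1] and labels shuffled; defaults (5
hotspots × 16 fragments × 25 molecules, effect 2.5 pooled standard
deviations) were sized so the per-hotspot mean has a standard error well
below the quality gap.

What the generator does *not* emulate: real chemistry (no covalent ligand
topology beyond the 2 Å rule, no torsional decoys — rigid-body
perturbations only), crystallographic noise, protein flexibility, or the
composition biases of real screens. Passing tests therefore demonstrate
that the machinery recovers planted signal under its own assumptions, not
performance on experimental data.

## Problem sizes and numerical choices

The desk profile (4 layers, width 32, ~200-example datasets, 100-structure
screens) keeps every experiment within minutes on one CPU core; the
48-layer profile is available through `ModelConfig`. Distances use closed
boundaries everywhere a cutoff appears. Ties in rankings break by atom id
for determinism. Spearman ρ uses average ranks. Seeds enter every random
path explicitly; training, generation, and subsampling are bit-reproducible
given the same seeds.

## Known limitations

* Attention interpretability is a trained property, not a structural
  guarantee: with the sparsity phase disabled, the network solves the
  synthetic task with near-uniform attention and the readout carries little
  signal.
* Hotspot *ranking among sites of similar contact frequency* is
  noise-limited: the attention magnitude a trained model assigns to a
  contact varies severalfold with the site's local geometry, so
  mean-attention hotspot maps resolve large occupancy differences reliably
  but can permute sites whose frequencies differ by less than that noise.
  The stability subsampling (Jaccard against the full-screen top-k) is the
  robust readout; single-rank distinctions near the top should not be
  over-interpreted.
* The hotspot pipeline assumes one rigid reference protein per target;
  there is no superposition of non-identical structures.
* The hydrogen-bond role table is a fixed approximation (no protonation
  states); ligand N/O atoms are treated as ambivalent donors/acceptors.
* The affinity head's ReLU clips at zero, so the model cannot express
  negative −log-affinities (which do not occur in the intended label
  range).
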