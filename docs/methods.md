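# Methods

## Overview

`kgmedrec` couples two supervised tasks over a shared typed medical
knowledge graph (KG): (i) translation-distance embedding of the graph
(TransD) and (ii) binary click/interaction prediction, joined at the lowest
layer by a cross-compression unit and by a shared multimodal entity
encoder. This note records the modeling assumptions, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would need to know.

## TransD embedding

Each entity and relation carries a meaning vector and a projection vector;
mapping matrices `M_re = r_p e_pᵀ + I` project entities into relation space
and triples are scored by the squared L2 translation distance. Projection
is always computed in vector form (`trunc_pad(e) + r_p (e_p·e)`), which is
algebraically identical to the matrix product; the identity is enforced by
an oracle test over random rectangular instances. `I` is interpreted as the
rectangular principal-diagonal identity so entity dimension n and relation
dimension m may differ; both default to 32, which is ample for graphs of a
few hundred entities.

Defaults: margin γ = 1.0, Adam at learning rate 0.01 for 150 epochs,
minibatch 128. After every step, entity and relation *meaning* vectors are
projected back onto the unit ball (norm ≤ 1); without this constraint the
margin objective can be satisfied by inflating scale rather than arranging
geometry. Projection vectors are unconstrained.

**Negative sampling.** The single-triple `corrupt` operation replaces head
or tail (fair coin) with a uniformly drawn entity of the same type and
rejects observed triples, with a bounded retry budget. Training, however,
mixes typed and untyped corruption (`type_preserve_prob = 0.5`): with
purely type-preserving negatives the scores of wrong-type entities are
never trained, and on the default graph every link-prediction miss was
caused by wrong-type entities outranking the true tail. The even mixture
trains both within-type discrimination and cross-type separation.

**Link prediction.** Candidates are ranked by ascending distance, ties
broken stably by candidate order. The filtered protocol removes other
known-true tails of the same (head, relation) from the candidate list.
hits@10 and mean rank are reported per query set.

## Text pipeline

Documents are lower-cased and whitespace-tokenized; one line is one
sentence. The vocabulary keeps tokens with frequency ≥ min_count (default
1), ordered by frequency then lexicographically so indices are
deterministic. The skip-gram objective is the exact full softmax (the
synthetic vocabularies are small, ~60 types, so neither negative sampling
nor hierarchical softmax is needed); window C = 2; embedding dimension 16.

Document vectors are the final hidden state of a single-layer GRU (hidden
size = word dimension by default) read over the token vectors. The GRU can
optionally be pretrained with a Skip-Thought objective — two GRU decoders,
teacher-forced on frozen word vectors with a shared softmax output layer,
reconstruct the previous and next sentence — but the encoder is used
untrained by default: with class-disjoint topic vocabularies the word
vectors alone carry the topical signal and a random orthogonal-ish
recurrent pooling preserves it. A mean-pooling mode is available and
flagged in the output metadata.

## Visual pipeline

The image encoder is a deliberately small residual CNN for 32×32 grayscale
inputs: stem 3×3 conv (8 channels) → batch-norm → ReLU → 2×2 max-pool, two
stages of [projection conv block + identity block] at 8 and 16 channels
(stride 2 in the second stage), global average pooling, and a dense map to
32 features. Batch statistics are used in training mode and frozen running
statistics in evaluation mode, so evaluation encoding is exactly
deterministic; freshly initialized running statistics are mean 0 /
variance 1, which makes a zero residual branch output exactly zero and
preserves the zero-residual identity property through the full depth.
Gradients flow through an additive identity path; a finite-difference check
(relative error < 1e-3) is part of the acceptance suite. The encoder is
used as a fixed random feature extractor in the recommendation experiments;
a linear probe on its features separates the synthetic blob classes well
above chance, which is all the downstream model needs.

## Fusion encoder

An entity's modality vectors (structural 32, text 16, image 32) are
concatenated and passed through one dense layer with tanh to the shared
dimension d = 16. The layer is implemented blockwise (one weight block per
modality), which is algebraically the same as concatenation + one matrix
and makes the base / base+text / base+image / full ablation purely a
matter of which inputs are supplied. Absent modalities contribute a
learned per-modality default vector. The structural input is the
pretrained TransD meaning vector, kept frozen; fusion weights train
jointly with the rest of the model (a freeze flag exists). The text and
image weight blocks are zero-initialized, residual-style: every
configuration starts functionally identical to the structural-only model
and the modality paths grow only where gradients support them, so adding
an uninformative modality cannot perturb the base solution at
initialization.

## Multitask recommender

Dimensions: shared low-level d = 16; user MLP two ReLU layers d→d;
combining MLP on [u, v, u⊙v] (3d→d→1); relation and tail MLPs d→d and
2d→d. The elementwise product term gives the head a direct
inner-product-style interaction; scalar per-user and per-item bias terms
absorb activity and popularity so the MLP only has to model interactions.
One cross-compression layer is applied at the lowest level only; the item
embedding table spans all KG entities so KG heads (diseases, which never
occur as recommendation items) have an item stream for the shared cross
unit.

The joint loss is `L_RS + L_KG + L_REG` with L_RS the summed binary
cross-entropy (computed from logits via log-sum-exp for stability), L_KG =
−λ₁(Σ score(pos) − Σ score(neg)) with score = σ(pred_tail·tail), and
L_REG = λ₂‖W‖². Defaults λ₁ = 0.5, λ₂ = 1e-2, Adam at 0.02, 240 epochs,
batch 256, alternation 3 recommendation steps per KG step. The L2 term is
applied as per-step weight decay on exactly the parameters that received a
gradient in that step, so a KG step provably leaves the user MLP untouched
and a recommendation step leaves the relation MLP untouched (asserted in
tests). The margin-ranking loss remains the standalone KG-pretraining
objective; the joint loop uses the sigmoid similarity score, reconciling
the distance semantics (lower = better) of the embedding task with the
score semantics (higher = better) of the joint objective.

## Synthetic world

The generator emulates, with known ground truth, the regime KG-enhanced
recommenders are built for: sparse interactions over a large item pool,
an *incomplete* structural knowledge base, and side channels that carry
part of what the graph is missing.

* **Graph.** Six entity types; five relations (has_symptom,
  treated_by_drug, belongs_to_department, recommended_food,
  requires_examination). Default link-prediction graph: ~60 entities,
  density 0.65 (~410 triples). Default recommendation world: ~545
  entities with 280 item-eligible entities (drugs, foods, examinations),
  density 0.08. Disease→item links are class-structured: entities carry a
  latent class (index mod 4) and 80 % of a disease's expected item links
  fall in its own class (therapeutic families); expected per-head degree
  is preserved exactly when the in-class probability saturates. Every
  head keeps at least one tail per relation.
* **Incompleteness.** 30 % of diseases are "cold": their item links exist
  in the ground-truth graph that drives labels but are removed from the
  observed triples (items keep at least one anchor link so referential
  integrity holds). This implements the premise that structural knowledge
  is not comprehensive.
* **Interactions.** 200 users × 30 distinct items each. Label probability
  is `(1−noise)·σ(u·q_i + kg_weight·(adj_i − 0.2)) + noise/2`, with u, q
  latent Gaussian factors, adj the ground-truth adjacency of the item to
  the user's 2 preferred diseases, kg_weight = 10 and noise = 0.1 by
  default. The centering term makes strong KG dependence suppress
  non-adjacent clicks as well as boost adjacent ones — without it half of
  all positives are coin flips that no learner can rank; at kg_weight = 0
  the labels are exactly KG-independent with mean rate 1/2.
* **Text / images.** The vocabulary is partitioned into class blocks;
  each disease and (in the world default) each item draws its document
  from its class block with entity-specific Dirichlet weights. Images
  contain 2c+1 Gaussian blobs for class c plus uniform noise, values
  clipped to [0, 1]. Thus the modalities expose the latent class — the
  information the observed graph hides for cold diseases and sparsely
  linked items.
* **Determinism.** One global seed, split per generator through
  `numpy.random.SeedSequence` spawn keys; regeneration is bit-identical.

What the world does **not** emulate: real clinical ontologies, free-text
language, radiology image statistics, non-stationary user behavior, or
popularity skew beyond what the class structure induces. Passing the
ablation here shows the architecture can exploit multimodal side channels
when they carry graph-missing information; it does not certify effect
sizes on real clinical data.

## Evaluation protocol

Interactions are split 6:2:2 train/validation/test, stratified per user
and seed-stable. Each user's held-out test positives are ranked against
every item the user did not interact with in train/validation (full
ranking over the 280-item pool); recall@K (default K = 10) is per-user
averaged, users without held-out positives excluded. AUC is the standard
positive-over-negative probability with ties counted half. The ablation
harness trains all configurations on identical splits and initialization
per seed — configurations share every random stream, so differences are
attributable to the modality inputs — and reports per-seed values and
medians over 5 seeds. Experiment sizes (5 seeds, 240 epochs, ~545-entity
world) were chosen so a full ablation completes in minutes on one CPU
while the modality effect clears the seed-to-seed spread.

## Numerical core

All trainable components run on a minimal reverse-mode autodiff engine
over float64 NumPy arrays (broadcast arithmetic, matmul, the standard
nonlinearities, reductions with log-sum-exp, gather/scatter for embedding
tables, im2col-based 2-D convolution and max pooling with tie-splitting
gradients). Every operation is validated against central finite
differences. SGD and Adam are provided; all training loops are
bit-deterministic given a seed.

## Known limitations

* The GRU sentence encoder is used untrained by default; Skip-Thought
  pretraining is implemented but adds little on class-blocked synthetic
  text.
* The image channel is weaker than text in the ablation: blob count is a
  coarser class code than a topic-blocked document, and a random-weight
  encoder extracts it imperfectly.
* Absolute recall values on the synthetic world are small by design
  (few held-out positives, large candidate pool); orderings and lifts,
  not absolute values, are the meaningful outputs.
* The cross unit is shared between the item and KG-head streams; with a
  single cross layer this is the simplest faithful wiring, but deeper
  sharing patterns were not explored.
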