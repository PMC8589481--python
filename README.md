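# kgmedrec

A research toolkit for **multitask, knowledge-graph-enhanced healthcare
recommendation**: a TransD knowledge-graph embedding task and a
click-prediction task are trained jointly, coupled through a
cross-compression unit, with each knowledge-graph entity encoded from up to
three modalities — its structural embedding, a sentence vector of its
symptom/indication text, and a residual-CNN feature vector of its image.

It is aimed at researchers studying how structured medical knowledge
(disease–symptom–drug–food–department–examination graphs) and multimodal
side information mitigate sparsity and cold-start in clinical
recommendation. Because real clinical logs cannot be shipped, the package
includes a first-class synthetic-data module that generates a typed medical
knowledge graph, KG-driven user–item interactions, symptom text and toy
medical images with known ground truth, so every claim is testable end to
end.

## The model

**Structural knowledge — TransD.** Every entity *e* and relation *r* carries
a meaning vector and a projection vector. The relation- and entity-specific
mapping matrices

```
M_rh = r_p h_pᵀ + I        M_rt = r_p t_pᵀ + I
h⊥ = M_rh h                t⊥ = M_rt t
```

project entities into relation space, and a triple (h, r, t) is scored by
the squared translation distance `f_r(h,t) = ‖h⊥ + r − t⊥‖₂²` (lower =
more plausible). The projection is computed without materializing M
(`M e = trunc_pad(e) + r_p (e_p·e)`). Training minimizes the margin-ranking
loss `Σ max(0, f_r(h,t) + γ − f_r(h′,t′))` over observed triples and
corrupted negatives.

**Textual knowledge.** Skip-gram word vectors with the exact full-softmax
objective `p(w_j | w_I) = exp(u_j)/Σ_{j'} exp(u_{j'})`, pooled into a
document vector by a single-layer GRU encoder (Skip-Thought style, with an
optional previous/next-sentence pretraining mode and a mean-pooling
fallback).

**Visual knowledge.** A small residual CNN: units
`x_{l+1} = f(h(x_l) + F(x_l, W_l))` with identity or strided-1×1-projection
shortcuts, stem conv → batch-norm → ReLU → max-pool → conv/identity block
stages → global average pooling.

**Fusion.** Per entity, the available modality vectors are concatenated
(learned defaults fill absent ones) and passed through one dense layer with
tanh, giving the entity vector used both as the KG tail representation and
as the entity-side input of the cross-compression unit.

**Multitask coupling.** For an item v with entity vector e, each
cross-compression layer forms C = v eᵀ and compresses back:
`v′ = C w^{VV} + Cᵀ w^{EV} + b^V`, `e′ = C w^{VE} + Cᵀ w^{EE} + b^E`.
The click head is user-MLP × crossed-item-vector → combining MLP → sigmoid;
the KG head predicts a tail vector from (crossed head, relation-MLP) and
scores it as `f = σ(pred·tail)`. The joint objective

```
L = L_RS + L_KG + L_REG
  = Σ BCE(ŷ_uv, y_uv) − λ₁ (Σ_pos score − Σ_neg score) + λ₂‖W‖₂²
```

is optimized with an alternating schedule (default 3 recommendation steps
per KG step).

All gradient-based training runs on the package's own reverse-mode
autodiff core over NumPy (`kgmedrec.autodiff`) and is bit-deterministic
per seed.

## Worked example

```python
from kgmedrec.experiments import link_prediction_lift, modality_ablation
from kgmedrec.evaluation import format_table

lift = link_prediction_lift(seed=0)
print(lift["hits_trained"], lift["hits_random"], round(lift["lift"], 2))
# 1.0 0.14841849148418493 6.74

print(format_table(modality_ablation(seed=0, n_seeds=5)))
# Model       Recall@10
# base        0.0410
# base+text   0.0637
# base+image  0.0505
# full        0.0524
```

The first block trains TransD on the default ~60-entity medical KG
(411 triples) and ranks every test triple's true tail against all entities
in the filtered setting: training lifts hits@10 from the near-uniform 0.148
of randomly initialized embeddings to 1.0 — a 6.7× lift.

The second block runs the modality ablation on the standard synthetic
world (200 users × 30 interactions, 280 recommendable items, strong
KG-dependence, 30 % of diseases "cold" — their item links hidden from the
observed graph). Median held-out recall@10 over 5 seeds: every
modality-augmented configuration matches or beats the structural-only
base, with text the strongest single addition — the side channels carry
exactly the class information the incomplete graph is missing. Absolute
recalls are small because each user's few held-out positives are ranked
against the full 280-item pool.

A CLI wraps the same pipeline for shell use:

```bash
kgmedrec generate --seed 1 --out world/
kgmedrec train-kg --triples world/triples.tsv --out kg/
kgmedrec train-text --documents world/documents.tsv --out txt/
kgmedrec train-image --images world/images --out img/
kgmedrec evaluate --seed 1 --k 10 --out eval/
kgmedrec ablate --seed 1 --n-seeds 5 --out ablation/
```

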