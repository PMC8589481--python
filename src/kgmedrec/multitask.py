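"""Coupled recommendation + knowledge-graph-embedding model.

Two tasks share information at the lowest layer through a
*cross-compression unit*.  For an item v with entity vector e (both in
R^d) the unit forms the outer-product interaction matrix C = v e^T and
compresses it back into updated streams:

    v' = C w_vv + C^T w_ev + b_v
    e' = C w_ve + C^T w_ee + b_e

Since C w = v (e . w) and C^T w = e (v . w), the unit never materializes C.

* Recommendation head: user embedding -> user MLP; item embedding crossed
  with its fused entity vector; both fed to a combining MLP -> sigmoid
  click probability.
* KG head: head entity (after the same cross unit) concatenated with the
  relation MLP output -> tail MLP -> predicted tail vector; the similarity
  to an actual tail is f = sigmoid(inner product).

The joint objective is

    L = L_RS + L_KG + L_REG
      = sum BCE(y_hat, y)  -  lambda1 (sum score(pos) - sum score(neg))
        + lambda2 ||W||^2

optimized with an alternating schedule: `t_rs` recommendation minibatch
steps followed by one KG step.  The L2 term is applied as weight decay on
exactly the parameters that received a gradient in the step, so a KG step
never touches recommendation-only parameters and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, Adam, concat
from .errors import DivergenceError, HarnessError, VocabularyError
from .fusion import FusionConfig, FusionEncoder
from .kg_embedding import Triple

__all__ = [
    "InteractionRecord", "CrossUnitParams", "JointLossReport", "MTKRConfig",
    "MultitaskModel", "cross_compress", "train_joint",
]


@dataclass(frozen=True)
class InteractionRecord:
    user: str
    item: str
    label: int


@dataclass
class CrossUnitParams:
    """One cross-compression layer: four weight vectors + two biases in R^d."""

    w_vv: Tensor
    w_ev: Tensor
    w_ve: Tensor
    w_ee: Tensor
    b_v: Tensor
    b_e: Tensor

    @staticmethod
    def init_random(d: int, rng: np.random.Generator) -> "CrossUnitParams":
        s = 1.0 / np.sqrt(d)

        def vec():
            return Tensor.param(rng.uniform(-s, s, d))

        return CrossUnitParams(vec(), vec(), vec(), vec(),
                               Tensor.param(np.zeros(d)), Tensor.param(np.zeros(d)))

    def tensors(self) -> list[Tensor]:
        return [self.w_vv, self.w_ev, self.w_ve, self.w_ee, self.b_v, self.b_e]


def cross_compress(v: np.ndarray, e: np.ndarray, params: CrossUnitParams,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Reference (vector) form of one cross-compression layer on R^d inputs."""
    v = np.asarray(v, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    if v.shape != e.shape or v.ndim != 1:
        raise ValueError(f"item/entity streams must share a 1-D shape: {v.shape} vs {e.shape}")
    v_next = v * (e @ params.w_vv.data) + e * (v @ params.w_ev.data) + params.b_v.data
    e_next = v * (e @ params.w_ve.data) + e * (v @ params.w_ee.data) + params.b_e.data
    return v_next, e_next


@dataclass
class JointLossReport:
    """Decomposed joint objective; total is always the sum of the parts."""

    l_rs: float
    l_kg: float
    l_reg: float
    lambda1: float
    lambda2: float

    @property
    def total(self) -> float:
        return self.l_rs + self.l_kg + self.l_reg


@dataclass
class MTKRConfig:
    dim: int = 16                 # shared low-level dimension d
    dim_struct: int = 32          # matches the TransD entity dimension
    dim_text: int = 16
    dim_image: int = 32
    n_cross_layers: int = 1       # cross-compression only at the low level
    use_text: bool = True
    use_image: bool = True
    lambda1: float = 0.5
    lambda2: float = 1e-2
    lr: float = 0.02
    epochs: int = 240
    batch_size: int = 256
    kg_batch_size: int = 128
    t_rs: int = 3                 # RS steps per KG step
    seed: int = 0


class MultitaskModel:
    """Parameter container + differentiable forward passes for both tasks."""

    def __init__(self, user_ids: list[str], triples: list[Triple],
                 config: MTKRConfig,
                 struct_vectors: dict[str, np.ndarray] | None = None,
                 text_vectors: dict[str, np.ndarray] | None = None,
                 image_vectors: dict[str, np.ndarray] | None = None):
        self.config = config
        d = config.dim
        self.user_ids = list(user_ids)
        self.entity_ids = sorted({t.head for t in triples} | {t.tail for t in triples})
        self.relation_ids = sorted({t.relation for t in triples})
        self.user_index = {u: i for i, u in enumerate(self.user_ids)}
        self.entity_index = {e: i for i, e in enumerate(self.entity_ids)}
        self.relation_index = {r: i for i, r in enumerate(self.relation_ids)}

        rng = np.random.default_rng(config.seed)
        s = 1.0 / np.sqrt(d)

        def mat(shape):
            return Tensor.param(rng.uniform(-s, s, shape))

        n_u, n_e, n_r = len(self.user_ids), len(self.entity_ids), len(self.relation_ids)
        self.user_emb = mat((n_u, d))
        self.item_emb = mat((n_e, d))     # item-stream vector for every entity
        self.rel_emb = mat((n_r, d))
        # scalar bias terms: the usual shortcut for per-user activity and
        # per-item popularity, so the MLP only has to model interactions
        self.user_bias = Tensor.param(np.zeros(n_u))
        self.item_bias = Tensor.param(np.zeros(n_e))
        # structural modality: pretrained translation-embedding vectors when
        # given (frozen features, like text/image); a free table otherwise
        if struct_vectors is not None:
            struct = np.zeros((n_e, config.dim_struct))
            for eid, vec in struct_vectors.items():
                if eid not in self.entity_index:
                    raise VocabularyError(f"structural vector for unknown entity {eid!r}")
                struct[self.entity_index[eid]] = vec
            self.struct_emb = Tensor(struct)
        else:
            self.struct_emb = mat((n_e, config.dim_struct))

        self.fusion = FusionEncoder(FusionConfig(
            dim_struct=config.dim_struct, dim_text=config.dim_text,
            dim_image=config.dim_image, dim_out=d, seed=config.seed + 1))
        self.cross_layers = [CrossUnitParams.init_random(d, rng)
                             for _ in range(config.n_cross_layers)]

        # user MLP: two d->d ReLU layers
        self.user_w1, self.user_b1 = mat((d, d)), Tensor.param(np.zeros(d))
        self.user_w2, self.user_b2 = mat((d, d)), Tensor.param(np.zeros(d))
        # combining MLP on [u, v, u*v]: 3d -> d -> 1 (the elementwise product
        # lets the head express inner-product-style user-item interactions)
        self.comb_w1, self.comb_b1 = mat((3 * d, d)), Tensor.param(np.zeros(d))
        self.comb_w2, self.comb_b2 = mat((d, 1)), Tensor.param(np.zeros(1))
        # relation MLP d->d and tail MLP 2d->d
        self.rel_w, self.rel_b = mat((d, d)), Tensor.param(np.zeros(d))
        self.tail_w, self.tail_b = mat((2 * d, d)), Tensor.param(np.zeros(d))

        self._set_modalities(text_vectors, image_vectors)

    def _set_modalities(self, text_vectors, image_vectors) -> None:
        cfg = self.config
        n_e = len(self.entity_ids)

        def table(vectors, dim, name):
            if vectors is None:
                return None, None
            mat = np.zeros((n_e, dim))
            mask = np.zeros(n_e)
            for eid, vec in vectors.items():
                if eid not in self.entity_index:
                    raise VocabularyError(f"{name} vector for unknown entity {eid!r}")
                mat[self.entity_index[eid]] = vec
                mask[self.entity_index[eid]] = 1.0
            return mat, mask

        self.text_mat, self.text_mask = table(
            text_vectors if cfg.use_text else None, cfg.dim_text, "text")
        self.image_mat, self.image_mask = table(
            image_vectors if cfg.use_image else None, cfg.dim_image, "image")

    # -- persistence ----------------------------------------------------------
    def named_params(self) -> dict[str, Tensor]:
        out = {"user_emb": self.user_emb, "item_emb": self.item_emb,
               "rel_emb": self.rel_emb, "user_bias": self.user_bias,
               "item_bias": self.item_bias, "struct_emb": self.struct_emb,
               "user_w1": self.user_w1, "user_b1": self.user_b1,
               "user_w2": self.user_w2, "user_b2": self.user_b2,
               "comb_w1": self.comb_w1, "comb_b1": self.comb_b1,
               "comb_w2": self.comb_w2, "comb_b2": self.comb_b2,
               "rel_w": self.rel_w, "rel_b": self.rel_b,
               "tail_w": self.tail_w, "tail_b": self.tail_b}
        for i, t in enumerate(self.fusion.params()):
            out[f"fusion_{i}"] = t
        for li, layer in enumerate(self.cross_layers):
            for ti, t in enumerate(layer.tensors()):
                out[f"cross_{li}_{ti}"] = t
        return out

    def save(self, path) -> None:
        """Versioned binary checkpoint (NumPy .npz with a JSON header)."""
        import json

        header = json.dumps({"format": "kgmedrec-checkpoint", "version": 1,
                             "user_ids": self.user_ids,
                             "entity_ids": self.entity_ids,
                             "relation_ids": self.relation_ids})
        arrays = {k: t.data for k, t in self.named_params().items()}
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    def load_arrays(self, path) -> None:
        with np.load(path) as data:
            for k, t in self.named_params().items():
                t.data = data[k]

    # -- parameter groups -----------------------------------------------------
    def params(self) -> list[Tensor]:
        out = [self.user_emb, self.item_emb, self.rel_emb,
               self.user_bias, self.item_bias,
               self.user_w1, self.user_b1, self.user_w2, self.user_b2,
               self.comb_w1, self.comb_b1, self.comb_w2, self.comb_b2,
               self.rel_w, self.rel_b, self.tail_w, self.tail_b]
        out += self.fusion.params()
        for layer in self.cross_layers:
            out += layer.tensors()
        if self.struct_emb.requires_grad:
            out.append(self.struct_emb)
        return out

    def user_mlp_params(self) -> list[Tensor]:
        return [self.user_w1, self.user_b1, self.user_w2, self.user_b2]

    def relation_mlp_params(self) -> list[Tensor]:
        return [self.rel_w, self.rel_b]

    # -- differentiable forward passes ---------------------------------------
    def entity_table(self) -> Tensor:
        """Fused entity vectors (n_entities, d) — the multimodal encoder."""
        return self.fusion.forward_table(
            self.struct_emb, self.text_mat, self.text_mask,
            self.image_mat, self.image_mask)

    def _cross(self, v: Tensor, e: Tensor) -> tuple[Tensor, Tensor]:
        for layer in self.cross_layers:
            ev = (e * layer.w_vv).sum(axis=-1, keepdims=True)
            ve = (v * layer.w_ev).sum(axis=-1, keepdims=True)
            v_next = v * ev + e * ve + layer.b_v
            ev2 = (e * layer.w_ve).sum(axis=-1, keepdims=True)
            ve2 = (v * layer.w_ee).sum(axis=-1, keepdims=True)
            e_next = v * ev2 + e * ve2 + layer.b_e
            v, e = v_next, e_next
        return v, e

    def rs_logits(self, users: np.ndarray, items: np.ndarray,
                  entities: Tensor | None = None) -> Tensor:
        """Click logits for index arrays (differentiable)."""
        entities = self.entity_table() if entities is None else entities
        u = (self.user_emb.gather(users) @ self.user_w1 + self.user_b1).relu()
        u = (u @ self.user_w2 + self.user_b2).relu()
        v, _ = self._cross(self.item_emb.gather(items), entities.gather(items))
        h = concat([u, v, u * v], axis=-1)
        h = (h @ self.comb_w1 + self.comb_b1).relu()
        out = (h @ self.comb_w2 + self.comb_b2).reshape(-1)
        return out + self.user_bias.gather(users) + self.item_bias.gather(items)

    def kg_scores(self, heads: np.ndarray, rels: np.ndarray, tails: np.ndarray,
                  entities: Tensor | None = None) -> Tensor:
        """Triple similarity scores f = sigmoid(pred_tail . actual_tail)."""
        entities = self.entity_table() if entities is None else entities
        _, e_h = self._cross(self.item_emb.gather(heads), entities.gather(heads))
        r = (self.rel_emb.gather(rels) @ self.rel_w + self.rel_b).relu()
        pred = (concat([e_h, r], axis=-1) @ self.tail_w + self.tail_b).tanh()
        return (pred * entities.gather(tails)).sum(axis=-1).sigmoid()

    # -- public prediction API -------------------------------------------------
    def _uidx(self, user_id: str) -> int:
        try:
            return self.user_index[user_id]
        except KeyError:
            raise VocabularyError(f"unknown user {user_id!r}")

    def _eidx(self, entity_id: str) -> int:
        try:
            return self.entity_index[entity_id]
        except KeyError:
            raise VocabularyError(f"unknown entity {entity_id!r}")

    def predict_click(self, user_id: str, item_id: str) -> float:
        """Click probability in (0, 1) for one (user, item) pair."""
        return float(self.predict_click_batch([user_id], [item_id])[0])

    def predict_click_batch(self, user_ids, item_ids) -> np.ndarray:
        users = np.array([self._uidx(u) for u in user_ids])
        items = np.array([self._eidx(i) for i in item_ids])
        logits = self.rs_logits(users, items)
        from scipy.special import expit

        return expit(logits.data)

    def predict_tail(self, head_id: str, relation_id: str) -> np.ndarray:
        """Predicted tail vector for a (head, relation) query."""
        if relation_id not in self.relation_index:
            raise VocabularyError(f"unknown relation {relation_id!r}")
        h = np.array([self._eidx(head_id)])
        r = np.array([self.relation_index[relation_id]])
        entities = self.entity_table()
        _, e_h = self._cross(self.item_emb.gather(h), entities.gather(h))
        r_vec = (self.rel_emb.gather(r) @ self.rel_w + self.rel_b).relu()
        pred = (concat([e_h, r_vec], axis=-1) @ self.tail_w + self.tail_b).tanh()
        return pred.data[0]

    def tail_vector(self, entity_id: str) -> np.ndarray:
        return self.entity_table().data[self._eidx(entity_id)]


def tail_similarity(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Similarity f between predicted and actual tail: sigmoid inner product."""
    from scipy.special import expit

    return float(expit(float(np.dot(predicted, actual))))


# ---------------------------------------------------------------------------
# joint objective
# ---------------------------------------------------------------------------

def _bce(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable sum of binary cross-entropies from logits."""
    y = Tensor(np.asarray(labels, dtype=np.float64))
    # log(1 + e^z) - y z, via logsumexp([0, z]) for stability
    z = logits.reshape(-1, 1)
    zero = z * 0.0
    lse = concat([zero, z], axis=-1).logsumexp(axis=-1)
    return (lse - y * logits).sum()


def _reg_value(model: MultitaskModel) -> float:
    return float(sum(np.sum(p.data ** 2) for p in model.params()))


def joint_loss(batch_rs: list[InteractionRecord],
               batch_kg_pos: list[Triple], batch_kg_neg: list[Triple],
               model: MultitaskModel, lambda1: float, lambda2: float,
               ) -> JointLossReport:
    """Decomposed L = L_RS + L_KG + L_REG on explicit batches."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("lambda1 and lambda2 must be nonnegative")
    if not batch_rs or not batch_kg_pos or not batch_kg_neg:
        raise ValueError("joint_loss requires nonempty batches")
    entities = model.entity_table()
    users = np.array([model._uidx(r.user) for r in batch_rs])
    items = np.array([model._eidx(r.item) for r in batch_rs])
    labels = np.array([r.label for r in batch_rs], dtype=np.float64)
    logits = model.rs_logits(users, items, entities)
    if not np.isfinite(logits.data).all():
        raise FloatingPointError("click probabilities left the open interval (0,1)")
    l_rs = float(_bce(logits, labels).data)

    def batch_scores(triples):
        h = np.array([model._eidx(t.head) for t in triples])
        r = np.array([model.relation_index[t.relation] for t in triples])
        t_ = np.array([model._eidx(t.tail) for t in triples])
        return model.kg_scores(h, r, t_, entities)

    pos = float(batch_scores(batch_kg_pos).sum(axis=None).data) if batch_kg_pos else 0.0
    neg = float(batch_scores(batch_kg_neg).sum(axis=None).data) if batch_kg_neg else 0.0
    l_kg = -lambda1 * (pos - neg)
    l_reg = lambda2 * _reg_value(model)
    return JointLossReport(l_rs=l_rs, l_kg=l_kg, l_reg=l_reg,
                           lambda1=lambda1, lambda2=lambda2)


# ---------------------------------------------------------------------------
# alternating training
# ---------------------------------------------------------------------------

def train_joint(user_ids: list[str], interactions: list[InteractionRecord],
                triples: list[Triple], config: MTKRConfig | None = None,
                struct_vectors: dict[str, np.ndarray] | None = None,
                text_vectors: dict[str, np.ndarray] | None = None,
                image_vectors: dict[str, np.ndarray] | None = None,
                entity_type: dict[str, str] | None = None,
                ) -> tuple[MultitaskModel, list[JointLossReport]]:
    """Alternating training: `t_rs` recommendation steps, then one KG step.

    Items must be KG entities (the coupling is undefined otherwise).
    Returns the model and one JointLossReport per epoch, evaluated on the
    full training data with fresh negatives per epoch.
    """
    config = config or MTKRConfig()
    model = MultitaskModel(user_ids, triples, config, struct_vectors,
                           text_vectors, image_vectors)
    missing = {r.item for r in interactions} - set(model.entity_ids)
    if missing:
        raise HarnessError(
            f"{len(missing)} interaction items are not KG entities "
            f"(e.g. {sorted(missing)[:3]}); item/entity overlap is required")

    rng = np.random.default_rng(config.seed + 7)
    users = np.array([model.user_index[r.user] for r in interactions])
    items = np.array([model.entity_index[r.item] for r in interactions])
    labels = np.array([r.label for r in interactions], dtype=np.float64)
    h_idx = np.array([model.entity_index[t.head] for t in triples])
    r_idx = np.array([model.relation_index[t.relation] for t in triples])
    t_idx = np.array([model.entity_index[t.tail] for t in triples])
    observed = set(zip(h_idx.tolist(), r_idx.tolist(), t_idx.tolist()))

    etype = entity_type or {}
    pools: dict[str, list[int]] = {}
    for i, e in enumerate(model.entity_ids):
        pools.setdefault(etype.get(e, ""), []).append(i)
    pool_of = [np.array(pools[etype.get(e, "")]) for e in model.entity_ids]

    def corrupt_tails(heads, rels, tails):
        out = tails.copy()
        for i, t in enumerate(tails):
            pool = pool_of[int(t)]
            for _ in range(100):
                repl = int(pool[int(rng.integers(len(pool)))])
                if (int(heads[i]), int(rels[i]), repl) not in observed:
                    out[i] = repl
                    break
        return out

    opt = Adam(model.params(), lr=config.lr)

    def step(loss: Tensor):
        opt.zero_grad()
        loss.backward()
        opt.step()
        if config.lambda2 > 0:
            for p in opt.params:
                if p.grad is not None:
                    p.data *= 1.0 - 2.0 * config.lr * config.lambda2

    n_rs, n_kg = len(interactions), len(triples)
    trace: list[JointLossReport] = []
    kg_cursor = 0
    kg_order = rng.permutation(n_kg)
    for epoch in range(config.epochs):
        order = rng.permutation(n_rs)
        rs_steps = 0
        for start in range(0, n_rs, config.batch_size):
            sel = order[start:start + config.batch_size]
            logits = model.rs_logits(users[sel], items[sel])
            loss = _bce(logits, labels[sel]) * (1.0 / sel.size)
            step(loss)
            rs_steps += 1
            if rs_steps % config.t_rs == 0:
                # one KG step: push positive scores up, corrupted ones down
                take = min(config.kg_batch_size, n_kg)
                if kg_cursor + take > n_kg:
                    kg_order = rng.permutation(n_kg)
                    kg_cursor = 0
                ksel = kg_order[kg_cursor:kg_cursor + take]
                kg_cursor += take
                t_neg = corrupt_tails(h_idx[ksel], r_idx[ksel], t_idx[ksel])
                pos = model.kg_scores(h_idx[ksel], r_idx[ksel], t_idx[ksel])
                neg = model.kg_scores(h_idx[ksel], r_idx[ksel], t_neg)
                kg_loss = (neg.mean() - pos.mean()) * config.lambda1
                step(kg_loss)

        # epoch-level bookkeeping on the full training data
        t_neg_full = corrupt_tails(h_idx, r_idx, t_idx)
        neg_triples = [Triple(model.entity_ids[h], model.relation_ids[r],
                              model.entity_ids[t])
                       for h, r, t in zip(h_idx, r_idx, t_neg_full)]
        report = joint_loss(interactions, triples, neg_triples, model,
                            config.lambda1, config.lambda2)
        if not np.isfinite(report.total):
            raise DivergenceError(epoch, report.total)
        trace.append(report)
    return model, trace
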