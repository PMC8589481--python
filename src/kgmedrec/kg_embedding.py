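"""TransD translation-distance embedding of a knowledge graph.

Each entity *e* and relation *r* carries two vectors: a meaning vector
(``e``, ``r``) and a projection vector (``e_p``, ``r_p``).  A relation- and
entity-specific mapping matrix

    M_re = r_p e_p^T + I

projects entity meaning vectors into the relation space before scoring a
triple (h, r, t) by the squared translation distance

    f_r(h, t) = || h_perp + r - t_perp ||_2^2         (lower = more plausible)

where ``h_perp = M_rh h`` and ``t_perp = M_rt t``.  ``I`` is the (possibly
rectangular) principal-diagonal identity, so entity dimension ``n`` and
relation dimension ``m`` may differ.  Crucially the projection never needs
the matrix: ``M_re e = trunc_pad(e) + r_p (e_p . e)``, which is what makes
this family cheap on large graphs.

Training minimises the margin-ranking loss over observed triples S and
corrupted triples S': sum max(0, f_r(h,t) + gamma - f_r(h',t')).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, Adam
from .errors import DivergenceError, SamplingError, VocabularyError

__all__ = [
    "Triple", "TransDConfig", "TransDParams",
    "mapping_matrix", "project", "score_triple", "margin_loss",
    "corrupt", "train_transd", "link_predict", "link_prediction_metrics",
]


@dataclass(frozen=True)
class Triple:
    """One (head, relation, tail) fact."""

    head: str
    relation: str
    tail: str


@dataclass
class TransDConfig:
    dim_entity: int = 32       # n
    dim_relation: int = 32     # m
    margin: float = 1.0        # gamma of the ranking loss
    lr: float = 0.01
    epochs: int = 150
    batch_size: int = 128
    # probability that a corrupted entity is drawn from the same type pool;
    # the rest use the full entity pool so cross-type geometry is trained too
    type_preserve_prob: float = 0.5
    seed: int = 0


@dataclass
class TransDParams:
    """Dual (meaning + projection) vectors for every entity and relation."""

    entity_ids: list[str]
    relation_ids: list[str]
    entity_vec: np.ndarray       # (n_entities, n) meaning
    entity_proj: np.ndarray      # (n_entities, n) projection
    relation_vec: np.ndarray     # (n_relations, m) meaning
    relation_proj: np.ndarray    # (n_relations, m) projection
    margin: float = 1.0
    entity_type: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._eidx = {e: i for i, e in enumerate(self.entity_ids)}
        self._ridx = {r: i for i, r in enumerate(self.relation_ids)}

    @property
    def dim_entity(self) -> int:
        return self.entity_vec.shape[1]

    @property
    def dim_relation(self) -> int:
        return self.relation_vec.shape[1]

    def entity_index(self, eid: str) -> int:
        try:
            return self._eidx[eid]
        except KeyError:
            raise VocabularyError(f"unknown entity {eid!r}")

    def relation_index(self, rid: str) -> int:
        try:
            return self._ridx[rid]
        except KeyError:
            raise VocabularyError(f"unknown relation {rid!r}")

    @staticmethod
    def init_random(triples: list[Triple], config: TransDConfig,
                    entity_type: dict[str, str] | None = None) -> "TransDParams":
        """Uniform Xavier-style init over the vocabulary of `triples`."""
        entities = sorted({t.head for t in triples} | {t.tail for t in triples})
        relations = sorted({t.relation for t in triples})
        rng = np.random.default_rng(config.seed)
        n, m = config.dim_entity, config.dim_relation
        bnd_e, bnd_r = 6.0 ** 0.5 / n ** 0.5, 6.0 ** 0.5 / m ** 0.5
        return TransDParams(
            entity_ids=entities,
            relation_ids=relations,
            entity_vec=rng.uniform(-bnd_e, bnd_e, (len(entities), n)),
            entity_proj=rng.uniform(-bnd_e, bnd_e, (len(entities), n)),
            relation_vec=rng.uniform(-bnd_r, bnd_r, (len(relations), m)),
            relation_proj=rng.uniform(-bnd_r, bnd_r, (len(relations), m)),
            margin=config.margin,
            entity_type=dict(entity_type or {}),
        )


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def _rect_eye(m: int, n: int) -> np.ndarray:
    return np.eye(m, n)


def mapping_matrix(rel_proj: np.ndarray, ent_proj: np.ndarray) -> np.ndarray:
    """Dynamic mapping matrix M = r_p e_p^T + I  (shape m x n)."""
    rel_proj = np.asarray(rel_proj, dtype=np.float64)
    ent_proj = np.asarray(ent_proj, dtype=np.float64)
    if rel_proj.ndim != 1 or ent_proj.ndim != 1:
        raise ValueError("projection vectors must be 1-D")
    return np.outer(rel_proj, ent_proj) + _rect_eye(rel_proj.size, ent_proj.size)


def _trunc_pad(vec: np.ndarray, m: int) -> np.ndarray:
    """Action of the rectangular identity: truncate or zero-pad to length m."""
    n = vec.shape[-1]
    if m == n:
        return vec
    if m < n:
        return vec[..., :m]
    pad = [(0, 0)] * (vec.ndim - 1) + [(0, m - n)]
    return np.pad(vec, pad)


def project(entity_vec: np.ndarray, entity_proj: np.ndarray,
            rel_proj: np.ndarray) -> np.ndarray:
    """Project an entity into relation space without building the matrix.

    Equals ``mapping_matrix(rel_proj, entity_proj) @ entity_vec`` exactly,
    via the identity M e = trunc_pad(e) + r_p (e_p . e).
    """
    entity_vec = np.asarray(entity_vec, dtype=np.float64)
    entity_proj = np.asarray(entity_proj, dtype=np.float64)
    rel_proj = np.asarray(rel_proj, dtype=np.float64)
    if entity_vec.shape != entity_proj.shape:
        raise ValueError(
            f"entity vector/projection shapes differ: {entity_vec.shape} vs {entity_proj.shape}")
    return _trunc_pad(entity_vec, rel_proj.size) + rel_proj * float(entity_proj @ entity_vec)


def score_triple(h_perp: np.ndarray, r: np.ndarray, t_perp: np.ndarray) -> float:
    """Squared-L2 translation distance; 0 iff h_perp + r == t_perp."""
    d = np.asarray(h_perp) + np.asarray(r) - np.asarray(t_perp)
    return float(d @ d)


def _score_batch(params: TransDParams, triples: list[Triple]) -> np.ndarray:
    h = np.array([params.entity_index(t.head) for t in triples])
    r = np.array([params.relation_index(t.relation) for t in triples])
    t = np.array([params.entity_index(t.tail) for t in triples])
    return _score_idx(params, h, r, t)


def _score_idx(params: TransDParams, h: np.ndarray, r: np.ndarray,
               t: np.ndarray) -> np.ndarray:
    m = params.dim_relation
    hv, hp = params.entity_vec[h], params.entity_proj[h]
    tv, tp = params.entity_vec[t], params.entity_proj[t]
    rv, rp = params.relation_vec[r], params.relation_proj[r]
    h_perp = _trunc_pad(hv, m) + rp * np.sum(hp * hv, axis=-1, keepdims=True)
    t_perp = _trunc_pad(tv, m) + rp * np.sum(tp * tv, axis=-1, keepdims=True)
    d = h_perp + rv - t_perp
    return np.sum(d * d, axis=-1)


def margin_loss(positives: list[Triple], negatives: list[Triple],
                params: TransDParams) -> float:
    """Sum of hinge terms max(0, f(pos) + gamma - f(neg)) over matched pairs."""
    if not positives or not negatives:
        raise ValueError("margin_loss requires nonempty matched batches")
    if len(positives) != len(negatives):
        raise ValueError("positives and negatives must be matched pairwise")
    fp = _score_batch(params, positives)
    fn = _score_batch(params, negatives)
    return float(np.maximum(0.0, fp + params.margin - fn).sum())


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def corrupt(triple: Triple, entity_vocab: list[str], rng: np.random.Generator,
            observed: set[Triple] | None = None,
            entity_type: dict[str, str] | None = None,
            max_attempts: int = 100) -> Triple:
    """Corrupt head OR tail (fair coin) with a random same-type entity.

    The corruption is resampled (up to `max_attempts`) until it is not in
    `observed`; with no type map all entities form one pool.
    """
    observed = observed or set()
    etype = entity_type or {}
    for _ in range(max_attempts):
        corrupt_head = rng.random() < 0.5
        slot = triple.head if corrupt_head else triple.tail
        pool = [e for e in entity_vocab
                if e != slot and etype.get(e) == etype.get(slot)]
        if not pool:
            continue
        repl = pool[int(rng.integers(len(pool)))]
        cand = (Triple(repl, triple.relation, triple.tail) if corrupt_head
                else Triple(triple.head, triple.relation, repl))
        if cand not in observed:
            return cand
    raise SamplingError(f"no valid corruption for {triple} after {max_attempts} attempts")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_transd(triples: list[Triple], config: TransDConfig | None = None,
                 entity_type: dict[str, str] | None = None,
                 ) -> tuple[TransDParams, list[float]]:
    """Minibatch margin-ranking training; returns params and per-epoch mean loss.

    Meaning vectors are renormalized onto the unit ball after every step.
    Negative triples preserve entity type when a type map is given.
    """
    if not triples:
        raise ValueError("cannot train on an empty triple list")
    config = config or TransDConfig()
    params = TransDParams.init_random(triples, config, entity_type)
    rng = np.random.default_rng(config.seed + 1)

    n_e = len(params.entity_ids)
    h_idx = np.array([params.entity_index(t.head) for t in triples])
    r_idx = np.array([params.relation_index(t.relation) for t in triples])
    t_idx = np.array([params.entity_index(t.tail) for t in triples])
    observed = {(int(h), int(r), int(t)) for h, r, t in zip(h_idx, r_idx, t_idx)}

    # per-entity candidate pools for type-preserving corruption
    etype = entity_type or {}
    by_type: dict[str, np.ndarray] = {}
    for ty in {etype.get(e) for e in params.entity_ids}:
        by_type[ty] = np.array([i for i, e in enumerate(params.entity_ids)
                                if etype.get(e) == ty])
    pool_of = np.array([0] * n_e, dtype=object)
    for i, e in enumerate(params.entity_ids):
        pool_of[i] = by_type[etype.get(e)]
    all_pool = np.arange(n_e)

    E = Tensor.param(params.entity_vec, "E")
    Ep = Tensor.param(params.entity_proj, "Ep")
    R = Tensor.param(params.relation_vec, "R")
    Rp = Tensor.param(params.relation_proj, "Rp")
    eye = Tensor(_rect_eye(config.dim_entity, config.dim_relation))  # (n, m)
    opt = Adam([E, Ep, R, Rp], lr=config.lr)

    def proj(idx_e, rp):
        v, p = E.gather(idx_e), Ep.gather(idx_e)
        return v @ eye + rp * (v * p).sum(axis=-1, keepdims=True)

    def scores(bh, br, bt):
        rv, rp = R.gather(br), Rp.gather(br)
        d = proj(bh, rp) + rv - proj(bt, rp)
        return (d * d).sum(axis=-1)

    n = len(triples)
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_pairs = 0.0, 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            bh, br, bt = h_idx[sel], r_idx[sel], t_idx[sel]
            # corrupt one end per positive, type-preserving, avoiding observed
            ch, ct = bh.copy(), bt.copy()
            pick_head = rng.random(sel.size) < 0.5
            keep_type = rng.random(sel.size) < config.type_preserve_prob
            for i in range(sel.size):
                pool = (pool_of[bh[i] if pick_head[i] else bt[i]]
                        if keep_type[i] else all_pool)
                for _ in range(100):
                    repl = int(pool[int(rng.integers(len(pool)))])
                    cand = ((repl, int(br[i]), int(bt[i])) if pick_head[i]
                            else (int(bh[i]), int(br[i]), repl))
                    if cand not in observed:
                        if pick_head[i]:
                            ch[i] = repl
                        else:
                            ct[i] = repl
                        break
            opt.zero_grad()
            hinge = (scores(bh, br, bt) + config.margin - scores(ch, br, ct)).relu()
            loss = hinge.mean()
            loss.backward()
            opt.step()
            # norm constraint: meaning vectors stay inside the unit ball
            for mat in (E, R):
                norms = np.linalg.norm(mat.data, axis=1, keepdims=True)
                np.divide(mat.data, norms, out=mat.data, where=norms > 1.0)
            epoch_loss += float(hinge.data.sum())
            n_pairs += sel.size
        mean_loss = epoch_loss / n_pairs
        if not np.isfinite(mean_loss):
            raise DivergenceError(epoch, mean_loss)
        trace.append(mean_loss)

    params.entity_vec, params.entity_proj = E.data, Ep.data
    params.relation_vec, params.relation_proj = R.data, Rp.data
    return params, trace


# ---------------------------------------------------------------------------
# link prediction
# ---------------------------------------------------------------------------

def link_predict(params: TransDParams, query: tuple[str, str],
                 candidates: list[str]) -> list[tuple[str, float]]:
    """Rank candidate tails for (head, relation) by ascending distance."""
    head, relation = query
    h = np.full(len(candidates), params.entity_index(head))
    r = np.full(len(candidates), params.relation_index(relation))
    t = np.array([params.entity_index(c) for c in candidates])
    s = _score_idx(params, h, r, t)
    order = np.argsort(s, kind="stable")
    return [(candidates[i], float(s[i])) for i in order]


def link_prediction_metrics(params: TransDParams, test_triples: list[Triple],
                            candidates: list[str], k: int = 10,
                            known: set[Triple] | None = None,
                            ) -> dict[str, float]:
    """hits@k and mean rank of the true tail over the candidate list.

    In the filtered setting (`known` given) other known-true tails for the
    same (head, relation) are removed from the candidate list before ranking.
    """
    known = known or set()
    hits, ranks = 0, []
    for triple in test_triples:
        cands = [c for c in candidates
                 if c == triple.tail
                 or Triple(triple.head, triple.relation, c) not in known]
        ranked = link_predict(params, (triple.head, triple.relation), cands)
        rank = 1 + next(i for i, (c, _) in enumerate(ranked) if c == triple.tail)
        ranks.append(rank)
        hits += rank <= k
    return {"hits_at_k": hits / len(test_triples),
            "mean_rank": float(np.mean(ranks)),
            "k": k, "n_queries": len(test_triples)}


def save_params(params: TransDParams, out_dir, epochs: int | None = None) -> None:
    """Write meaning/projection vectors as TSV plus a JSON header."""
    from pathlib import Path

    from .io import write_vectors

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = {"dim_entity": params.dim_entity, "dim_relation": params.dim_relation,
              "margin": params.margin, "epochs": epochs}
    write_vectors(out / "entity_vec.tsv",
                  {e: params.entity_vec[i] for i, e in enumerate(params.entity_ids)},
                  header)
    write_vectors(out / "entity_proj.tsv",
                  {e: params.entity_proj[i] for i, e in enumerate(params.entity_ids)})
    write_vectors(out / "relation_vec.tsv",
                  {r: params.relation_vec[i] for i, r in enumerate(params.relation_ids)})
    write_vectors(out / "relation_proj.tsv",
                  {r: params.relation_proj[i] for i, r in enumerate(params.relation_ids)})
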