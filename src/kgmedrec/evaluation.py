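"""Metrics and the ablation harness for the recommendation experiments.

Protocol (stated in every report so numbers are interpretable): the
interactions are split 6:2:2 train/validation/test, stratified by user.
For each user the held-out *positive* test items are ranked against every
item the user did not interact with in train/validation (full ranking);
recall@K is the per-user-averaged fraction of held-out positives retrieved
in the top K.  AUC is the usual probability that a random positive
outscores a random negative, ties counted half.

The ablation harness trains the same model under four modality
configurations — base (structural only), base+text, base+image, full — on
identical splits per seed, and reports per-seed metrics plus medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import HarnessError
from .multitask import InteractionRecord, MTKRConfig, MultitaskModel, train_joint
from .synthetic import SyntheticWorld, entity_type_map
from .text_embedding import TextConfig, train_skipgram, GRUEncoder, encode_documents
from .visual_embedding import ImageEncoder, ResNetConfig, encode_images

__all__ = [
    "recall_at_k", "auc", "split_interactions", "EvalReport",
    "prepare_modalities", "evaluate_model", "run_ablation", "ablation_configs",
]


def recall_at_k(ranked_items: dict[str, list[str]],
                relevant_items: dict[str, set[str]], k: int) -> float:
    """Mean over users of |top-K intersect relevant| / |relevant|.

    Users without relevant items are excluded; rankings must be
    duplicate-free.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = []
    for user, ranking in ranked_items.items():
        if len(set(ranking)) != len(ranking):
            raise ValueError(f"ranking for {user!r} contains duplicates")
        relevant = relevant_items.get(user, set())
        if not relevant:
            continue
        top = set(ranking[:k])
        scores.append(len(top & relevant) / len(relevant))
    if not scores:
        raise ValueError("no user has any relevant items")
    return float(np.mean(scores))


def auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def split_interactions(records: list[InteractionRecord],
                       ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                       seed: int = 0):
    """Disjoint, seed-stable 6:2:2 split stratified by user."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    by_user: dict[str, list[InteractionRecord]] = {}
    for r in records:
        by_user.setdefault(r.user, []).append(r)
    train, valid, test = [], [], []
    for user in sorted(by_user):
        recs = by_user[user]
        order = rng.permutation(len(recs))
        n = len(recs)
        n_tr = int(round(ratios[0] * n))
        n_va = int(round(ratios[1] * n))
        for pos, j in enumerate(order):
            (train if pos < n_tr else valid if pos < n_tr + n_va else test
             ).append(recs[j])
    return train, valid, test


@dataclass
class EvalReport:
    """Metrics for one trained configuration."""

    config_name: str
    recall_at_k: dict[int, float]
    auc: float
    seed: int
    protocol: str = ("full ranking of held-out positives against "
                     "non-interacted items; recall per-user-averaged")
    extras: dict = field(default_factory=dict)


def prepare_modalities(world: SyntheticWorld, config: MTKRConfig,
                       text_epochs: int = 5, transd_epochs: int = 100):
    """Pretrain the three per-entity feature tables once per world.

    Structural vectors come from TransD on the world's triples (entity
    meaning vectors); word vectors from skip-gram on the symptom documents,
    pooled by the GRU sentence encoder; image vectors from the residual
    encoder in evaluation mode.  Returns (struct, text, image) dicts.
    """
    from .kg_embedding import TransDConfig, train_transd

    kcfg = TransDConfig(dim_entity=config.dim_struct,
                        dim_relation=config.dim_struct,
                        epochs=transd_epochs, seed=world.seed)
    params, _ = train_transd(world.triples, kcfg,
                             entity_type=entity_type_map(world.schema))
    struct_vectors = {e: params.entity_vec[i]
                      for i, e in enumerate(params.entity_ids)}
    tcfg = TextConfig(dim=config.dim_text, hidden=config.dim_text,
                      epochs=text_epochs, seed=world.seed)
    word_model, _ = train_skipgram(list(world.documents.values()), tcfg)
    gru = GRUEncoder.init_random(tcfg.dim, tcfg.hidden, seed=world.seed + 11)
    text_vectors, _ = encode_documents(world.documents, word_model, gru, mode="gru")
    enc = ImageEncoder(ResNetConfig(feature_dim=config.dim_image,
                                    seed=world.seed + 12))
    image_vectors, _ = encode_images(world.images, enc)
    return struct_vectors, text_vectors, image_vectors


def evaluate_model(model: MultitaskModel, train_records, valid_records,
                   test_records, item_ids: list[str], ks=(10,)) -> EvalReport:
    """Recall@K over held-out positives and AUC over test labels."""
    seen: dict[str, set[str]] = {}
    for r in list(train_records) + list(valid_records):
        seen.setdefault(r.user, set()).add(r.item)
    relevant: dict[str, set[str]] = {}
    for r in test_records:
        if r.label == 1:
            relevant.setdefault(r.user, set()).add(r.item)

    ranked: dict[str, list[str]] = {}
    for user in sorted(relevant):
        candidates = [i for i in item_ids if i not in seen.get(user, ())]
        probs = model.predict_click_batch([user] * len(candidates), candidates)
        order = np.argsort(-probs, kind="stable")
        ranked[user] = [candidates[i] for i in order]

    recalls = {k: recall_at_k(ranked, relevant, k) for k in ks}
    test_scores = model.predict_click_batch([r.user for r in test_records],
                                            [r.item for r in test_records])
    test_auc = auc(test_scores, [r.label for r in test_records])
    return EvalReport(config_name="", recall_at_k=recalls, auc=test_auc, seed=-1)


def ablation_configs(base: MTKRConfig) -> dict[str, MTKRConfig]:
    """The four modality configurations, differing only in inputs."""
    from dataclasses import replace

    return {
        "base": replace(base, use_text=False, use_image=False),
        "base+text": replace(base, use_text=True, use_image=False),
        "base+image": replace(base, use_text=False, use_image=True),
        "full": replace(base, use_text=True, use_image=True),
    }


def run_ablation(world: SyntheticWorld, configs: dict[str, MTKRConfig],
                 seeds: list[int], ks=(10,)) -> dict:
    """Train every configuration on identical per-seed splits; report medians.

    Returns {"per_seed": {name: [EvalReport...]}, "median_recall": {name: v},
    "table": [(name, median_recall), ...]} with one table row per config.
    """
    if len(configs) < 1:
        raise HarnessError("ablation needs at least one configuration")
    dims = {(c.dim, c.dim_struct, c.dim_text, c.dim_image) for c in configs.values()}
    if len(dims) != 1:
        raise HarnessError("configurations disagree on dimensions; "
                           "splits/modalities would not be comparable")
    etype = entity_type_map(world.schema)
    per_seed: dict[str, list[EvalReport]] = {name: [] for name in configs}
    k0 = ks[0]
    # modality features depend only on the world, not the config seed
    struct_vec, text_vec, img_vec = prepare_modalities(
        world, next(iter(configs.values())))
    for seed in seeds:
        train, valid, test = split_interactions(world.interactions, seed=seed)
        for name, cfg in configs.items():
            from dataclasses import replace

            cfg_s = replace(cfg, seed=seed)
            model, _ = train_joint(
                world.user_ids, train, world.triples, cfg_s,
                struct_vectors=struct_vec,
                text_vectors=text_vec if cfg_s.use_text else None,
                image_vectors=img_vec if cfg_s.use_image else None,
                entity_type=etype)
            report = evaluate_model(model, train, valid, test,
                                    world.item_ids, ks=ks)
            report.config_name = name
            report.seed = seed
            per_seed[name].append(report)
    medians = {name: float(np.median([r.recall_at_k[k0] for r in reports]))
               for name, reports in per_seed.items()}
    table = [(name, medians[name]) for name in configs]
    return {"per_seed": per_seed, "median_recall": medians, "table": table,
            "k": k0, "seeds": list(seeds)}


def format_table(result: dict) -> str:
    """Two-column aligned text table (model, recall)."""
    width = max(len(name) for name, _ in result["table"]) + 2
    lines = [f"{'Model':<{width}}Recall@{result['k']}"]
    for name, rec in result["table"]:
        lines.append(f"{name:<{width}}{rec:.4f}")
    return "\n".join(lines)
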