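"""Synthetic medical knowledge graph, interactions, symptom text and images.

Real clinical interaction logs and multimodal disease records cannot be
shipped, so this module generates a miniature world with *known ground
truth*:

* a typed knowledge graph over diseases, symptoms, drugs, foods,
  departments and examinations, linked by five clinically natural relation
  types (``has_symptom``, ``treated_by_drug``, ``belongs_to_department``,
  ``recommended_food``, ``requires_examination``);
* user-item interaction logs whose positive-label probability is logistic
  in a latent user-item affinity **plus** a knowledge-graph adjacency bonus
  (``kg_weight``): users carry preferred diseases, and items connected to
  those diseases in the KG are clicked more often.  ``kg_weight`` is the
  separability knob — at 0 the labels are independent of the graph, so a
  KG-aware recommender has nothing to exploit;
* one symptom document per disease, drawn from a disease-specific topic
  distribution over a shared vocabulary;
* one grayscale image per disease with a class-specific blob pattern.

Every generator is bit-deterministic in (parameters, seed); the global seed
is split per generator through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError
from .kg_embedding import Triple

__all__ = [
    "KGSchema", "SyntheticWorld", "default_schema", "world_schema",
    "generate_kg", "generate_interactions", "generate_documents",
    "generate_images", "image_class_of", "entity_class_of",
    "hide_cold_disease_items", "synthesize_world",
    "entity_type_map", "item_entity_ids", "item_adjacency",
]

ENTITY_TYPES = ["disease", "symptom", "drug", "food", "department", "examination"]
RELATION_TYPES = [
    ("has_symptom", "disease", "symptom"),
    ("treated_by_drug", "disease", "drug"),
    ("belongs_to_department", "disease", "department"),
    ("recommended_food", "disease", "food"),
    ("requires_examination", "disease", "examination"),
]
ITEM_TYPES = ("drug", "food", "examination")


@dataclass
class KGSchema:
    """Entity types, typed relations and per-type entity counts."""

    entity_types: list[str] = field(default_factory=lambda: list(ENTITY_TYPES))
    relation_types: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(RELATION_TYPES))
    counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        touched = set()
        for name, head_t, tail_t in self.relation_types:
            if head_t not in self.entity_types or tail_t not in self.entity_types:
                raise SchemaError(
                    f"relation {name!r} touches unknown entity type(s) "
                    f"{head_t!r}/{tail_t!r}")
            touched |= {head_t, tail_t}
        for ty in touched:
            if self.counts.get(ty, 0) < 1:
                raise SchemaError(f"entity type {ty!r} is used by a relation "
                                  f"but has count {self.counts.get(ty, 0)}")

    def entity_ids(self, etype: str) -> list[str]:
        return [f"{etype}_{i}" for i in range(self.counts.get(etype, 0))]


def default_schema() -> KGSchema:
    """Small graph (~60 entities) used for link-prediction experiments."""
    return KGSchema(counts={"disease": 12, "symptom": 18, "drug": 12,
                            "food": 10, "department": 4, "examination": 6})


def world_schema() -> KGSchema:
    """Graph for the recommendation experiments: ~545 entities, 280
    recommendable items.  The item pool is deliberately much larger than
    the ~18 training interactions a user contributes, so per-item label
    frequencies are under-determined and pooling information across items
    through their KG links is the only way to generalize — the sparsity /
    cold-start regime that knowledge-graph side information targets."""
    return KGSchema(counts={"disease": 20, "symptom": 40, "drug": 120,
                            "food": 100, "department": 5, "examination": 60})


@dataclass
class SyntheticWorld:
    """A complete generated world plus its latent ground truth."""

    schema: KGSchema
    triples: list[Triple]            # the observed (possibly incomplete) graph
    interactions: list
    documents: dict[str, str]
    images: dict[str, np.ndarray]
    latent_user_factors: np.ndarray
    latent_item_factors: np.ndarray
    user_ids: list[str]
    item_ids: list[str]
    preferred_diseases: dict[str, list[str]]
    kg_weight: float
    seed: int
    full_triples: list[Triple] = field(default_factory=list)  # ground truth
    cold_diseases: list[str] = field(default_factory=list)
    n_classes: int = 4


def _spawn(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# knowledge graph
# ---------------------------------------------------------------------------

def entity_class_of(entity_id: str, n_classes: int = 4) -> int:
    """Deterministic latent class: entity index mod n_classes."""
    return int(entity_id.rsplit("_", 1)[1]) % n_classes


def generate_kg(schema: KGSchema, density: float = 0.3, seed: int = 0,
                class_mixing: float = 0.8, n_classes: int = 4) -> list[Triple]:
    """Sample a typed KG; each (relation, head) keeps at least one tail.

    Each head-tail pair of a relation is linked independently, with the
    expected triple count per relation approximately density x heads x
    tails.  Disease-to-item relations are class-structured: diseases and
    items carry a latent class (index mod `n_classes`) and a fraction
    `class_mixing` of a disease's expected item links fall inside its own
    class, emulating therapeutic families (antivirals for viral diseases
    etc.).  Other relations are class-blind.  Heads left isolated under a
    relation get one uniformly chosen tail.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    if not 0.0 <= class_mixing <= 1.0:
        raise ValueError("class_mixing must lie in [0, 1]")
    schema.validate()
    rng = _spawn(seed, 0)
    triples: list[Triple] = []
    for name, head_t, tail_t in schema.relation_types:
        heads, tails = schema.entity_ids(head_t), schema.entity_ids(tail_t)
        classed = head_t == "disease" and tail_t in ITEM_TYPES and n_classes > 1
        if classed:
            # conserve the expected per-head degree density*T: when the
            # in-class probability saturates, the excess mass spills into
            # out-of-class links
            T = float(len(tails))
            t_in = T / n_classes
            p_in = min(1.0, density * class_mixing * n_classes)
            p_out = np.clip((density * T - t_in * p_in) / (T - t_in), 0.0, 1.0)
            hc = np.array([entity_class_of(h, n_classes) for h in heads])
            tc = np.array([entity_class_of(t, n_classes) for t in tails])
            prob = np.where(hc[:, None] == tc[None, :], p_in, p_out)
        else:
            prob = np.full((len(heads), len(tails)), density)
        mask = rng.random((len(heads), len(tails))) < prob
        for i, h in enumerate(heads):
            if not mask[i].any():
                mask[i, int(rng.integers(len(tails)))] = True
            for j in np.flatnonzero(mask[i]):
                triples.append(Triple(h, name, tails[int(j)]))
    return triples


def hide_cold_disease_items(triples: list[Triple], cold_fraction: float = 0.3,
                            n_classes: int = 4) -> tuple[list[Triple], list[str]]:
    """Drop the disease-to-item links of a deterministic subset of diseases.

    The returned "observed" graph emulates an incomplete knowledge base:
    for cold diseases the item links exist in the world's ground truth (and
    drive interaction labels) but are absent from the triples a model sees,
    so only side channels (symptom text, images) reveal which items fit
    them.  An item that would lose its last triple keeps one link so
    referential integrity is preserved.
    """
    diseases = sorted({t.head for t in triples if t.head.startswith("disease")})
    n_cold = int(round(cold_fraction * len(diseases)))
    cold = set(diseases[:n_cold])  # deterministic: lowest-index diseases
    item_deg: dict[str, int] = {}
    for t in triples:
        ty = t.tail.rsplit("_", 1)[0]
        if ty in ITEM_TYPES:
            item_deg[t.tail] = item_deg.get(t.tail, 0) + 1
    observed = []
    for t in triples:
        ty = t.tail.rsplit("_", 1)[0]
        if t.head in cold and ty in ITEM_TYPES:
            if item_deg[t.tail] <= 1:
                observed.append(t)      # keep the item's last anchor
            else:
                item_deg[t.tail] -= 1
        else:
            observed.append(t)
    return observed, sorted(cold)


def entity_type_map(schema: KGSchema) -> dict[str, str]:
    return {eid: ty for ty in schema.entity_types for eid in schema.entity_ids(ty)}


def item_entity_ids(triples: list[Triple], schema: KGSchema,
                    item_types: tuple[str, ...] = ITEM_TYPES) -> list[str]:
    """KG entity ids of item-eligible types that occur in the graph."""
    present = {t.head for t in triples} | {t.tail for t in triples}
    return [eid for ty in item_types for eid in schema.entity_ids(ty)
            if eid in present]


def item_adjacency(triples: list[Triple]) -> dict[str, set[str]]:
    """disease id -> set of entities it links to (any relation)."""
    adj: dict[str, set[str]] = {}
    for t in triples:
        adj.setdefault(t.head, set()).add(t.tail)
    return adj


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def generate_interactions(triples: list[Triple], n_users: int = 200,
                          n_per_user: int = 30, kg_weight: float = 10.0,
                          noise: float = 0.1, seed: int = 0,
                          schema: KGSchema | None = None,
                          n_preferred: int = 2, latent_dim: int = 4,
                          adj_offset: float = 0.2):
    """KG-informed binary interactions: exactly n_users x n_per_user records.

    Each user holds `n_preferred` preferred diseases and a latent factor
    vector; item i gets label 1 with probability
    ``(1 - noise) * sigmoid(u . q_i + kg_weight * (adj_i - adj_offset))
    + noise * 0.5`` where ``adj_i`` indicates a KG link from a preferred
    disease to the item.  The centering makes stronger KG dependence both
    raise adjacent and suppress non-adjacent click rates, so at
    kg_weight=0 labels are KG-independent with mean rate 1/2 while at
    large kg_weight positives concentrate on KG-adjacent items.  Returns
    (records, world-fragment dict with the latent ground truth).
    """
    from .multitask import InteractionRecord

    if not triples:
        raise ValueError("cannot generate interactions from an empty KG")
    if not 0.0 <= noise < 1.0:
        raise ValueError(f"noise must lie in [0, 1), got {noise}")
    if kg_weight < 0:
        raise ValueError("kg_weight must be nonnegative")
    schema = schema or _infer_schema(triples)
    rng = _spawn(seed, 1)
    items = item_entity_ids(triples, schema)
    if n_per_user > len(items):
        raise ValueError(f"n_per_user={n_per_user} exceeds item pool ({len(items)})")
    diseases = [d for d in schema.entity_ids("disease")
                if any(t.head == d for t in triples)]
    adj = item_adjacency(triples)

    users = [f"user_{u}" for u in range(n_users)]
    U = rng.standard_normal((n_users, latent_dim)) / np.sqrt(latent_dim)
    Q = rng.standard_normal((len(items), latent_dim)) / np.sqrt(latent_dim)
    prefs = {u: [diseases[int(j)] for j in
                 rng.choice(len(diseases), size=min(n_preferred, len(diseases)),
                            replace=False)]
             for u in users}

    records = []
    for ui, u in enumerate(users):
        picked = rng.choice(len(items), size=n_per_user, replace=False)
        for ii in picked:
            item = items[int(ii)]
            adjacent = any(item in adj.get(d, ()) for d in prefs[u])
            logit = (float(U[ui] @ Q[int(ii)])
                     + kg_weight * (float(adjacent) - adj_offset))
            p = (1.0 - noise) / (1.0 + np.exp(-logit)) + 0.5 * noise
            records.append(InteractionRecord(u, item, int(rng.random() < p)))
    truth = {"user_ids": users, "item_ids": items,
             "latent_user_factors": U, "latent_item_factors": Q,
             "preferred_diseases": prefs}
    return records, truth


def _infer_schema(triples: list[Triple]) -> KGSchema:
    """Recover a schema from `type_index`-style entity ids."""
    counts: dict[str, int] = {}
    for t in triples:
        for eid in (t.head, t.tail):
            ty, idx = eid.rsplit("_", 1)
            counts[ty] = max(counts.get(ty, 0), int(idx) + 1)
    rels = sorted({(t.relation, t.head.rsplit("_", 1)[0], t.tail.rsplit("_", 1)[0])
                   for t in triples})
    return KGSchema(entity_types=sorted(counts), relation_types=rels, counts=counts)


# ---------------------------------------------------------------------------
# documents
# ---------------------------------------------------------------------------

def generate_documents(triples: list[Triple], vocab_size: int = 60,
                       doc_len: int = 50, seed: int = 0,
                       topic_support: dict[str, list[int]] | None = None,
                       n_classes: int = 4,
                       include_items: bool = False) -> dict[str, str]:
    """Symptom/indication documents from entity-specific topic distributions.

    Every disease gets a document.  The shared vocabulary is partitioned
    into `n_classes` blocks; an entity's topic is supported on its latent
    class's block (diseases of the same class describe overlapping
    symptomatology) with entity-specific Dirichlet weights.  With
    `include_items` the item-eligible entities (drugs, foods,
    examinations) get indication documents drawn the same way — the
    textual counterpart of a drug label listing what it treats.  An
    explicit `topic_support` (token-index lists keyed by entity) overrides
    the class blocks.  Tokens are lowercase whitespace-separated strings.
    """
    if vocab_size < 2:
        raise ValueError("vocab_size must be >= 2")
    if doc_len < 1:
        raise ValueError("doc_len must be >= 1")
    n_classes = max(1, min(n_classes, vocab_size))
    rng = _spawn(seed, 2)
    vocab = [f"sym{i}" for i in range(vocab_size)]
    entities = sorted({t.head for t in triples if t.head.startswith("disease")})
    if not entities:
        entities = sorted({t.head for t in triples})
    if include_items:
        seen = {t.head for t in triples} | {t.tail for t in triples}
        entities += sorted(e for e in seen
                           if e.rsplit("_", 1)[0] in ITEM_TYPES)
    block = vocab_size // n_classes
    docs: dict[str, str] = {}
    for d in entities:
        if topic_support and d in topic_support:
            support = np.asarray(topic_support[d])
        else:
            c = entity_class_of(d, n_classes) if "_" in d else 0
            lo = c * block
            hi = vocab_size if c == n_classes - 1 else lo + block
            support = np.arange(lo, hi)
        weights = rng.dirichlet(np.ones(len(support)))
        toks = rng.choice(support, size=doc_len, p=weights)
        docs[d] = " ".join(vocab[int(i)] for i in toks)
    return docs


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def image_class_of(disease_id: str, n_classes: int = 2) -> int:
    """Deterministic class assignment: class = disease index mod n_classes."""
    return int(disease_id.rsplit("_", 1)[1]) % n_classes


def generate_images(triples: list[Triple], size: int = 32, seed: int = 0,
                    noise: float = 0.05, n_classes: int = 2,
                    include_items: bool = False) -> dict[str, np.ndarray]:
    """One size x size grayscale image per entity, values in [0, 1].

    Class c (= entity index mod n_classes) draws 2c+1 Gaussian blobs of
    fixed radius at seeded random centers, plus uniform additive noise —
    more blobs means higher mean intensity at equal radius, which linear
    probes on any sane encoder can pick up.  Every disease gets an image;
    with `include_items` the item-eligible entities do too.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = _spawn(seed, 3)
    diseases = sorted({t.head for t in triples if t.head.startswith("disease")})
    if not diseases:
        diseases = sorted({t.head for t in triples})
    if include_items:
        seen = {t.head for t in triples} | {t.tail for t in triples}
        diseases += sorted(e for e in seen
                           if e.rsplit("_", 1)[0] in ITEM_TYPES)
    yy, xx = np.mgrid[0:size, 0:size]
    radius = size / 8.0
    images: dict[str, np.ndarray] = {}
    for d in diseases:
        c = image_class_of(d, n_classes)
        img = np.zeros((size, size))
        for _ in range(2 * c + 1):
            cy, cx = rng.uniform(radius, size - radius, 2)
            img += 0.8 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius ** 2))
        img += noise * rng.random((size, size))
        images[d] = np.clip(img, 0.0, 1.0)
    return images


# ---------------------------------------------------------------------------
# full world
# ---------------------------------------------------------------------------

def synthesize_world(schema: KGSchema | None = None, density: float = 0.08,
                     n_users: int = 200, n_per_user: int = 30,
                     kg_weight: float = 10.0, noise: float = 0.1,
                     vocab_size: int = 60, doc_len: int = 50,
                     image_size: int = 32, class_mixing: float = 0.8,
                     n_classes: int = 4, cold_fraction: float = 0.3,
                     seed: int = 0) -> SyntheticWorld:
    """Generate KG + interactions + documents + images with one global seed.

    Interaction labels are driven by the full ground-truth graph; the
    world's observed `triples` hide the item links of `cold_fraction` of
    diseases, so symptom text and images (which expose the latent disease
    class) carry information the structural channel lacks.
    """
    schema = schema or world_schema()
    full = generate_kg(schema, density=density, seed=seed,
                       class_mixing=class_mixing, n_classes=n_classes)
    records, truth = generate_interactions(
        full, n_users=n_users, n_per_user=n_per_user,
        kg_weight=kg_weight, noise=noise, seed=seed, schema=schema)
    observed, cold = hide_cold_disease_items(full, cold_fraction, n_classes)
    docs = generate_documents(full, vocab_size=vocab_size,
                              doc_len=doc_len, seed=seed, n_classes=n_classes,
                              include_items=True)
    images = generate_images(full, size=image_size, seed=seed,
                             n_classes=n_classes, include_items=True)
    return SyntheticWorld(
        schema=schema, triples=observed, interactions=records,
        documents=docs, images=images,
        full_triples=full, cold_diseases=cold, n_classes=n_classes,
        latent_user_factors=truth["latent_user_factors"],
        latent_item_factors=truth["latent_item_factors"],
        user_ids=truth["user_ids"], item_ids=truth["item_ids"],
        preferred_diseases=truth["preferred_diseases"],
        kg_weight=kg_weight, seed=seed)


def write_world(world: SyntheticWorld, out_dir, image_format: str = "txt") -> None:
    """Write triples/interactions/documents/images plus a JSON manifest."""
    import json
    from pathlib import Path

    from . import io as kio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kio.write_triples(out / "triples.tsv", world.triples)
    kio.write_interactions(out / "interactions.tsv", world.interactions)
    kio.write_documents(out / "documents.tsv", world.documents)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    ext = "png" if image_format == "png" else "txt"
    for eid, img in world.images.items():
        kio.write_image(img_dir / f"{eid}.{ext}", img)
    manifest = {
        "seed": world.seed, "kg_weight": world.kg_weight,
        "counts": world.schema.counts,
        "n_triples": len(world.triples),
        "n_interactions": len(world.interactions),
        "n_users": len(world.user_ids), "n_items": len(world.item_ids),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
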