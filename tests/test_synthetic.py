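"""Ground-truth contracts of the synthetic medical world generators."""

import numpy as np
import pytest

from kgmedrec.errors import SchemaError
from kgmedrec.kg_embedding import Triple
from kgmedrec.synthetic import (
    KGSchema, generate_kg, generate_interactions, generate_documents,
    generate_images, hide_cold_disease_items, image_class_of,
    item_adjacency, item_entity_ids, synthesize_world, world_schema,
)


def pair_schema(n_dis=1, n_sym=1):
    return KGSchema(entity_types=["disease", "symptom"],
                    relation_types=[("has_symptom", "disease", "symptom")],
                    counts={"disease": n_dis, "symptom": n_sym})


class TestGenerateKG:
    def test_single_pair_forced_link(self):
        triples = generate_kg(pair_schema(), density=1.0, seed=0)
        assert triples == [Triple("disease_0", "has_symptom", "symptom_0")]

    def test_full_density_is_exhaustive_pairing(self):
        triples = generate_kg(pair_schema(10, 20), density=1.0, seed=0)
        assert len(triples) == 200
        assert len(set(triples)) == 200

    def test_every_head_gets_a_tail(self, small_schema):
        triples = generate_kg(small_schema, density=0.05, seed=3)
        for name, head_t, tail_t in small_schema.relation_types:
            heads_linked = {t.head for t in triples if t.relation == name}
            assert heads_linked == set(small_schema.entity_ids(head_t))

    def test_expected_count_tracks_density(self):
        schema = pair_schema(30, 40)
        triples = generate_kg(schema, density=0.3, seed=5)
        expected = 0.3 * 30 * 40
        assert abs(len(triples) - expected) < 4 * np.sqrt(expected)

    def test_seed_determinism(self, small_schema):
        a = generate_kg(small_schema, density=0.4, seed=9)
        b = generate_kg(small_schema, density=0.4, seed=9)
        assert a == b

    @pytest.mark.parametrize("density", [0.0, -0.1, 1.5])
    def test_invalid_density_rejected(self, density):
        with pytest.raises(ValueError):
            generate_kg(pair_schema(), density=density, seed=0)

    def test_invalid_schema_rejected(self):
        bad = KGSchema(entity_types=["disease"],
                       relation_types=[("has_symptom", "disease", "symptom")],
                       counts={"disease": 1})
        with pytest.raises(SchemaError):
            generate_kg(bad, density=0.5, seed=0)


class TestInteractions:
    def test_record_count_contract(self, small_triples, small_schema):
        records, _ = generate_interactions(small_triples, n_users=2,
                                           n_per_user=3, kg_weight=1.0,
                                           noise=0.0, seed=0,
                                           schema=small_schema)
        assert len(records) == 6
        assert all(r.label in (0, 1) for r in records)

    def test_kg_blind_noise_half_gives_half_rate(self, small_triples, small_schema):
        records, _ = generate_interactions(small_triples, n_users=150,
                                           n_per_user=8, kg_weight=0.0,
                                           noise=0.5, seed=2,
                                           schema=small_schema)
        rate = np.mean([r.label for r in records])
        n = len(records)
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_strong_kg_weight_separates_adjacent_items(self, small_triples, small_schema):
        records, truth = generate_interactions(small_triples, n_users=100,
                                               n_per_user=8, kg_weight=10.0,
                                               noise=0.0, seed=4,
                                               schema=small_schema)
        adj = item_adjacency(small_triples)
        rates = {True: [], False: []}
        for r in records:
            adjacent = any(r.item in adj.get(d, ())
                           for d in truth["preferred_diseases"][r.user])
            rates[adjacent].append(r.label)
        assert np.mean(rates[True]) > np.mean(rates[False])

    def test_items_are_kg_entities(self, small_triples, small_schema):
        records, _ = generate_interactions(small_triples, n_users=5,
                                           n_per_user=4, seed=0,
                                           schema=small_schema)
        items = set(item_entity_ids(small_triples, small_schema))
        assert {r.item for r in records} <= items

    def test_empty_triples_rejected(self):
        with pytest.raises(ValueError):
            generate_interactions([], n_users=2, n_per_user=2, seed=0)

    def test_separability_knob_is_monotone(self, small_triples, small_schema):
        """Adjacency/label odds ratio grows with kg_weight (fixed seed)."""
        adj = item_adjacency(small_triples)
        ors = []
        for w in (0.0, 3.0, 10.0):
            records, truth = generate_interactions(
                small_triples, n_users=150, n_per_user=8, kg_weight=w,
                noise=0.1, seed=11, schema=small_schema)
            table = np.ones((2, 2)) * 0.5  # Haldane correction
            for r in records:
                a = any(r.item in adj.get(d, ())
                        for d in truth["preferred_diseases"][r.user])
                table[int(a), r.label] += 1
            ors.append((table[1, 1] * table[0, 0]) / (table[1, 0] * table[0, 1]))
        assert ors[0] < ors[1] < ors[2]


class TestDocuments:
    def test_token_count_and_vocab(self, small_triples):
        docs = generate_documents(small_triples, vocab_size=2, doc_len=4, seed=0)
        assert docs  # every disease present
        for text in docs.values():
            toks = text.split()
            assert len(toks) == 4
            assert set(toks) <= {"sym0", "sym1"}

    def test_disjoint_supports_share_no_tokens(self, small_triples):
        support = {"disease_0": [0, 1, 2], "disease_1": [10, 11, 12]}
        docs = generate_documents(small_triples, vocab_size=20, doc_len=30,
                                  seed=1, topic_support=support)
        assert not set(docs["disease_0"].split()) & set(docs["disease_1"].split())

    def test_seed_determinism(self, small_triples):
        a = generate_documents(small_triples, vocab_size=10, doc_len=10, seed=5)
        b = generate_documents(small_triples, vocab_size=10, doc_len=10, seed=5)
        assert a == b

    def test_doc_len_validation(self, small_triples):
        with pytest.raises(ValueError):
            generate_documents(small_triples, vocab_size=10, doc_len=0, seed=0)

    def test_item_documents_optional(self, small_triples):
        base = generate_documents(small_triples, seed=0)
        extended = generate_documents(small_triples, seed=0, include_items=True)
        assert set(base) < set(extended)
        assert any(k.startswith("drug_") for k in extended)


class TestImages:
    def test_values_in_unit_interval(self, small_triples):
        images = generate_images(small_triples, size=16, seed=0)
        for img in images.values():
            assert img.shape == (16, 16)
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_seed_determinism(self, small_triples):
        a = generate_images(small_triples, size=16, seed=3)
        b = generate_images(small_triples, size=16, seed=3)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_more_blobs_means_brighter(self):
        # classes alternate 1 blob / 3 blobs; compare mean intensities
        triples = [Triple(f"disease_{i}", "has_symptom", "symptom_0")
                   for i in range(40)]
        images = generate_images(triples, size=32, seed=2, noise=0.0,
                                 n_classes=2)
        means = {0: [], 1: []}
        for d, img in images.items():
            means[image_class_of(d, 2)].append(img.mean())
        assert np.mean(means[1]) > np.mean(means[0])

    def test_size_validation(self, small_triples):
        with pytest.raises(ValueError):
            generate_images(small_triples, size=4, seed=0)


class TestWorld:
    def test_referential_integrity(self, tiny_world):
        in_triples = ({t.head for t in tiny_world.triples}
                      | {t.tail for t in tiny_world.triples})
        assert {r.item for r in tiny_world.interactions} <= in_triples
        assert set(tiny_world.documents) & in_triples
        assert all(r.label in (0, 1) for r in tiny_world.interactions)

    def test_world_regeneration_is_bit_identical(self, small_schema):
        kwargs = dict(schema=small_schema, density=0.5, n_users=10,
                      n_per_user=5, vocab_size=15, doc_len=10,
                      image_size=16, seed=13)
        a, b = synthesize_world(**kwargs), synthesize_world(**kwargs)
        assert a.triples == b.triples
        assert a.interactions == b.interactions
        assert a.documents == b.documents
        assert all(np.array_equal(a.images[k], b.images[k]) for k in a.images)
        assert np.array_equal(a.latent_user_factors, b.latent_user_factors)

    def test_cold_diseases_lose_item_links_only(self):
        world = synthesize_world(seed=3)
        assert world.cold_diseases
        observed = set(world.triples)
        full = set(world.full_triples)
        assert observed <= full
        removed = full - observed
        item_types = ("drug", "food", "examination")
        assert removed
        for t in removed:
            assert t.head in world.cold_diseases
            assert t.tail.rsplit("_", 1)[0] in item_types

    def test_hide_cold_keeps_item_anchors(self, small_triples):
        observed, cold = hide_cold_disease_items(small_triples,
                                                 cold_fraction=1.0)
        tails = {t.tail for t in small_triples}
        assert {t.tail for t in observed} == tails
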