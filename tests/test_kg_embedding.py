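"""TransD operations against hand computations and brute-force oracles."""

import numpy as np
import pytest

from kgmedrec.errors import VocabularyError
from kgmedrec.kg_embedding import (
    Triple, TransDConfig, TransDParams, corrupt, link_predict,
    link_prediction_metrics, mapping_matrix, margin_loss, project,
    score_triple, train_transd,
)


def make_params(entity_vecs: dict, relation_vecs: dict, margin=1.0,
                zero_proj=True):
    """Handcrafted parameters with zero projection vectors by default."""
    ents = sorted(entity_vecs)
    rels = sorted(relation_vecs)
    ev = np.stack([np.asarray(entity_vecs[e], float) for e in ents])
    rv = np.stack([np.asarray(relation_vecs[r], float) for r in rels])
    return TransDParams(ents, rels, ev, np.zeros_like(ev), rv,
                        np.zeros_like(rv), margin=margin)


class TestMappingAndProjection:
    def test_zero_relation_projection_gives_identity(self):
        m = mapping_matrix(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert np.array_equal(m, np.eye(3))

    def test_hand_outer_product(self):
        m = mapping_matrix(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert np.array_equal(m, np.array([[1.0, 1.0], [0.0, 1.0]]))

    def test_projection_hand_example(self):
        h = project(np.array([1.0, 1.0]), np.array([1.0, 0.0]),
                    np.array([2.0, 0.0]))
        assert np.allclose(h, [3.0, 1.0])

    def test_identity_projection_when_rel_proj_zero(self):
        h = np.array([0.3, -0.7, 2.0])
        assert np.array_equal(project(h, np.ones(3), np.zeros(3)), h)

    def test_vector_form_equals_matrix_oracle(self, rng):
        for _ in range(100):
            m, n = rng.integers(1, 9, 2)
            e = rng.standard_normal(n)
            ep = rng.standard_normal(n)
            rp = rng.standard_normal(m)
            fast = project(e, ep, rp)
            explicit = mapping_matrix(rp, ep) @ e
            assert np.abs(fast - explicit).max() < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project(np.ones(3), np.ones(2), np.ones(3))


class TestScoring:
    def test_exact_translation_scores_zero(self):
        assert score_triple([1.0, 0.0], [0.0, 1.0], [1.0, 1.0]) == 0.0

    def test_squared_norm(self):
        assert score_triple(np.zeros(2), [3.0, 4.0], np.zeros(2)) == 25.0

    def test_permutation_invariance(self, rng):
        h, r, t = rng.standard_normal((3, 5))
        perm = rng.permutation(5)
        assert np.isclose(score_triple(h, r, t),
                          score_triple(h[perm], r[perm], t[perm]))

    def test_nonnegative_and_zero_iff_translation(self, rng):
        for _ in range(20):
            h, r, t = rng.standard_normal((3, 4))
            s = score_triple(h, r, t)
            assert s >= 0.0
            assert (s == 0.0) == np.allclose(h + r - t, 0.0, atol=0)


class TestMarginLoss:
    # geometry: a=[0,0], b=[0,0] so f(a,r,b)=|r|^2=1; c=[1,0] so f(a,r,c)=0
    PARAMS = dict(entity_vecs={"a": [0.0, 0.0], "b": [0.0, 0.0],
                               "c": [1.0, 0.0], "d": [2.0, 0.0]},
                  relation_vecs={"r": [1.0, 0.0]})

    def test_hand_value(self):
        params = make_params(**self.PARAMS, margin=1.0)
        loss = margin_loss([Triple("a", "r", "b")], [Triple("a", "r", "c")],
                           params)
        assert loss == 2.0  # max(0, 1 + 1 - 0)

    def test_separated_batch_has_zero_loss(self):
        params = make_params(**self.PARAMS, margin=1.0)
        # positive (a,r,c) scores 0; negative (a,r,d) scores |[1,0]-[2,0]|^2=1
        loss = margin_loss([Triple("a", "r", "c")], [Triple("a", "r", "d")],
                           params)
        assert loss == 0.0

    def test_monotone_in_margin(self):
        losses = []
        for gamma in (0.5, 1.0, 2.0):
            params = make_params(**self.PARAMS, margin=gamma)
            losses.append(margin_loss([Triple("a", "r", "b")],
                                      [Triple("a", "r", "c")], params))
        assert losses == sorted(losses)

    def test_empty_or_mismatched_batches_rejected(self):
        params = make_params(**self.PARAMS)
        with pytest.raises(ValueError):
            margin_loss([], [], params)
        with pytest.raises(ValueError):
            margin_loss([Triple("a", "r", "b")], [], params)


class TestCorrupt:
    def test_forced_tail_choice(self):
        rng = np.random.default_rng(0)
        triple = Triple("h0", "r", "t0")
        types = {"h0": "H", "t0": "T", "t1": "T"}
        observed = {triple}
        for _ in range(20):
            c = corrupt(triple, ["h0", "t0", "t1"], rng, observed, types)
            assert c == Triple("h0", "r", "t1")

    def test_exactly_one_slot_changes(self, rng):
        triple = Triple("e0", "r", "e1")
        vocab = [f"e{i}" for i in range(10)]
        for _ in range(50):
            c = corrupt(triple, vocab, rng, {triple})
            assert (c.head == triple.head) != (c.tail == triple.tail)
            assert c.relation == triple.relation

    def test_head_tail_balance(self):
        rng = np.random.default_rng(42)
        triple = Triple("e0", "r", "e1")
        vocab = [f"e{i}" for i in range(20)]
        heads = sum(corrupt(triple, vocab, rng).head != "e0"
                    for _ in range(10_000))
        assert abs(heads / 10_000 - 0.5) < 3 * np.sqrt(0.25 / 10_000)


class TestTraining:
    def test_single_triple_kg_reaches_zero_loss(self):
        triples = [Triple("a", "r", "b")]
        cfg = TransDConfig(dim_entity=8, dim_relation=8, epochs=50,
                           lr=0.1, margin=0.5, seed=0)
        _, trace = train_transd(triples, cfg)
        assert trace[-1] == 0.0

    def test_zero_learning_rate_is_noop(self, small_triples):
        cfg = TransDConfig(dim_entity=8, dim_relation=8, epochs=3,
                           lr=0.0, seed=0)
        params, trace = train_transd(small_triples, cfg)
        reference = TransDParams.init_random(small_triples, cfg)
        # norm projection may still rescale rows outside the unit ball
        norms = np.linalg.norm(reference.entity_vec, axis=1, keepdims=True)
        expected = np.where(norms > 1, reference.entity_vec / norms,
                            reference.entity_vec)
        assert np.allclose(params.entity_vec, expected)
        assert all(np.isfinite(trace))

    def test_seeded_trace_is_reproducible(self, small_triples):
        cfg = TransDConfig(dim_entity=8, dim_relation=8, epochs=5, seed=3)
        _, t1 = train_transd(small_triples, cfg)
        _, t2 = train_transd(small_triples, cfg)
        assert t1 == t2

    def test_meaning_vectors_respect_unit_ball(self, small_triples):
        cfg = TransDConfig(dim_entity=8, dim_relation=8, epochs=5, seed=3)
        params, _ = train_transd(small_triples, cfg)
        assert np.linalg.norm(params.entity_vec, axis=1).max() <= 1.0 + 1e-12

    def test_empty_triples_rejected(self):
        with pytest.raises(ValueError):
            train_transd([], TransDConfig())

    def test_training_improves_mean_rank(self, small_triples):
        cfg = TransDConfig(dim_entity=16, dim_relation=16, epochs=40,
                           lr=0.02, seed=5)
        trained, _ = train_transd(small_triples, cfg)
        untrained = TransDParams.init_random(small_triples, cfg)
        known = set(small_triples)
        cands = trained.entity_ids
        m1 = link_prediction_metrics(trained, small_triples, cands, known=known)
        m0 = link_prediction_metrics(untrained, small_triples, cands, known=known)
        assert m1["mean_rank"] < m0["mean_rank"]


class TestLinkPrediction:
    def test_single_candidate_is_forced_hit(self):
        params = make_params(entity_vecs={"a": [0.0, 0.0], "b": [1.0, 0.0]},
                             relation_vecs={"r": [1.0, 0.0]})
        metrics = link_prediction_metrics(params, [Triple("a", "r", "b")],
                                          ["b"], k=1)
        assert metrics["hits_at_k"] == 1.0
        assert metrics["mean_rank"] == 1.0

    def test_ranking_is_by_ascending_distance(self):
        params = make_params(entity_vecs={"a": [0.0, 0.0], "b": [1.0, 0.0],
                                          "c": [5.0, 0.0]},
                             relation_vecs={"r": [1.0, 0.0]})
        ranked = link_predict(params, ("a", "r"), ["c", "b"])
        assert [c for c, _ in ranked] == ["b", "c"]
        assert ranked[0][1] <= ranked[1][1]

    def test_unknown_ids_rejected(self):
        params = make_params(entity_vecs={"a": [0.0]},
                             relation_vecs={"r": [0.0]})
        with pytest.raises(VocabularyError):
            link_predict(params, ("nope", "r"), ["a"])

    def test_untrained_hits_match_uniform_null(self):
        # 100 candidates, ~uniform ranks: hits@10 ~ 0.1
        triples = [Triple(f"e{i}", "r", f"e{(i + 1) % 100}")
                   for i in range(100)]
        cfg = TransDConfig(dim_entity=8, dim_relation=8, seed=17)
        params = TransDParams.init_random(triples, cfg)
        queries = (triples * 2)[:200]
        m = link_prediction_metrics(params, queries, params.entity_ids, k=10)
        se = np.sqrt(0.1 * 0.9 / len(queries))
        assert abs(m["hits_at_k"] - 0.1) < 3 * se + 0.03
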