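"""Cross-compression unit, coupled heads, joint loss and alternating training."""

import numpy as np
import pytest
from scipy.special import expit

from kgmedrec.autodiff import Adam, Tensor
from kgmedrec.errors import HarnessError, VocabularyError
from kgmedrec.kg_embedding import Triple
from kgmedrec.multitask import (
    CrossUnitParams, InteractionRecord, MTKRConfig, MultitaskModel,
    cross_compress, joint_loss, tail_similarity, train_joint,
)
from kgmedrec.synthetic import entity_type_map


def unit(d, **overrides):
    rng = np.random.default_rng(0)
    p = CrossUnitParams.init_random(d, rng)
    for name in ("w_vv", "w_ev", "w_ve", "w_ee", "b_v", "b_e"):
        vec = overrides.get(name, np.zeros(d))
        getattr(p, name).data = np.asarray(vec, float)
    return p


SMALL_CFG = MTKRConfig(dim=8, dim_struct=8, dim_text=4, dim_image=4,
                       epochs=3, batch_size=16, kg_batch_size=16, seed=0)


@pytest.fixture(scope="module")
def tiny_model(tiny_world):
    users = tiny_world.user_ids
    return MultitaskModel(users, tiny_world.triples, SMALL_CFG)


class TestCrossCompress:
    def test_hand_outer_product_example(self):
        p = unit(2, w_vv=[1.0, 0.0])
        v_next, e_next = cross_compress([1.0, 2.0], [3.0, 4.0], p)
        assert np.allclose(v_next, [3.0, 6.0])
        assert np.allclose(e_next, [0.0, 0.0])

    def test_zero_entity_annihilates_to_biases(self, rng):
        p = CrossUnitParams.init_random(3, np.random.default_rng(1))
        p.b_v.data = np.array([1.0, 2.0, 3.0])
        p.b_e.data = np.array([-1.0, 0.0, 1.0])
        v_next, e_next = cross_compress(rng.standard_normal(3), np.zeros(3), p)
        assert np.allclose(v_next, p.b_v.data)
        assert np.allclose(e_next, p.b_e.data)

    def test_matches_elementwise_bruteforce(self, rng):
        for _ in range(50):
            d = int(rng.integers(1, 9))
            p = CrossUnitParams.init_random(d, np.random.default_rng(int(rng.integers(1e6))))
            v, e = rng.standard_normal((2, d))
            C = np.outer(v, e)
            v_expected = C @ p.w_vv.data + C.T @ p.w_ev.data + p.b_v.data
            e_expected = C @ p.w_ve.data + C.T @ p.w_ee.data + p.b_e.data
            v_next, e_next = cross_compress(v, e, p)
            assert np.abs(v_next - v_expected).max() < 1e-10
            assert np.abs(e_next - e_expected).max() < 1e-10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_compress(np.ones(2), np.ones(3), unit(2))

    def test_model_batched_path_matches_single(self, tiny_model, rng):
        d = tiny_model.config.dim
        v = rng.standard_normal((4, d))
        e = rng.standard_normal((4, d))
        v_out, e_out = tiny_model._cross(Tensor(v), Tensor(e))
        layer = tiny_model.cross_layers[0]
        for i in range(4):
            v1, e1 = cross_compress(v[i], e[i], layer)
            assert np.abs(v_out.data[i] - v1).max() < 1e-10
            assert np.abs(e_out.data[i] - e1).max() < 1e-10


class TestPredictClick:
    def test_zero_final_layer_gives_half(self, tiny_world):
        model = MultitaskModel(tiny_world.user_ids, tiny_world.triples,
                               SMALL_CFG)
        model.comb_w2.data[...] = 0.0
        model.comb_b2.data[...] = 0.0
        p = model.predict_click(tiny_world.user_ids[0],
                                tiny_world.interactions[0].item)
        assert p == 0.5

    def test_determinism_and_range(self, tiny_model, tiny_world, rng):
        users = rng.choice(tiny_world.user_ids, 1000)
        items = rng.choice([r.item for r in tiny_world.interactions], 1000)
        p1 = tiny_model.predict_click_batch(users, items)
        p2 = tiny_model.predict_click_batch(users, items)
        assert np.array_equal(p1, p2)
        assert ((p1 > 0.0) & (p1 < 1.0)).all()

    def test_unknown_ids_rejected(self, tiny_model):
        with pytest.raises(VocabularyError):
            tiny_model.predict_click("ghost_user", "drug_0")


class TestKGHead:
    def test_tail_similarity_closed_forms(self):
        e = np.array([1.0, 0.0])
        assert tail_similarity(e, e) == pytest.approx(expit(1.0))
        assert tail_similarity(e, np.array([0.0, 1.0])) == 0.5

    def test_similarity_monotone_in_inner_product(self, rng):
        base = rng.standard_normal(4)
        sims = [tail_similarity(base * s, base) for s in (0.1, 1.0, 5.0)]
        assert sims == sorted(sims)

    def test_predict_tail_shape_and_vocab(self, tiny_model, tiny_world):
        t = tiny_world.triples[0]
        vec = tiny_model.predict_tail(t.head, t.relation)
        assert vec.shape == (tiny_model.config.dim,)
        with pytest.raises(VocabularyError):
            tiny_model.predict_tail(t.head, "no_such_relation")


class TestJointLoss:
    def _batches(self, world):
        rs = world.interactions[:10]
        pos = world.triples[:6]
        neg = [Triple(t.head, t.relation, world.triples[-1 - i].tail)
               for i, t in enumerate(pos)]
        return rs, pos, neg

    def test_total_is_sum_of_parts(self, tiny_model, tiny_world):
        rs, pos, neg = self._batches(tiny_world)
        rep = joint_loss(rs, pos, neg, tiny_model, 0.5, 1e-3)
        assert rep.total == rep.l_rs + rep.l_kg + rep.l_reg
        assert rep.l_reg >= 0.0

    def test_parts_match_independent_recomputation(self, tiny_model, tiny_world):
        rs, pos, neg = self._batches(tiny_world)
        rep = joint_loss(rs, pos, neg, tiny_model, 0.7, 1e-4)
        # L_RS from the public prediction API
        p = tiny_model.predict_click_batch([r.user for r in rs],
                                           [r.item for r in rs])
        y = np.array([r.label for r in rs], float)
        l_rs = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
        assert abs(l_rs - rep.l_rs) < 1e-8
        # L_KG from predict_tail + tail_similarity
        def s(ts):
            return sum(tail_similarity(
                tiny_model.predict_tail(t.head, t.relation),
                tiny_model.tail_vector(t.tail)) for t in ts)
        assert abs(-0.7 * (s(pos) - s(neg)) - rep.l_kg) < 1e-8
        # L_REG from the parameter list
        reg = 1e-4 * sum(float(np.sum(t.data ** 2))
                         for t in tiny_model.params())
        assert abs(reg - rep.l_reg) < 1e-8

    def test_reg_scales_linearly(self, tiny_model, tiny_world):
        rs, pos, neg = self._batches(tiny_world)
        r1 = joint_loss(rs, pos, neg, tiny_model, 0.5, 1e-3)
        r2 = joint_loss(rs, pos, neg, tiny_model, 0.5, 2e-3)
        assert r2.l_reg == pytest.approx(2 * r1.l_reg)

    def test_negative_lambdas_rejected(self, tiny_model, tiny_world):
        rs, pos, neg = self._batches(tiny_world)
        with pytest.raises(ValueError):
            joint_loss(rs, pos, neg, tiny_model, -1.0, 0.0)
        with pytest.raises(ValueError):
            joint_loss([], pos, neg, tiny_model, 0.0, 0.0)


class TestGradientIsolation:
    def test_kg_step_leaves_user_mlp_untouched(self, tiny_world):
        model = MultitaskModel(tiny_world.user_ids, tiny_world.triples,
                               SMALL_CFG)
        before_user = [t.data.copy() for t in model.user_mlp_params()]
        before_rel = [t.data.copy() for t in model.relation_mlp_params()]
        opt = Adam(model.params(), lr=0.05)
        h = np.array([model.entity_index[t.head] for t in tiny_world.triples[:8]])
        r = np.array([model.relation_index[t.relation] for t in tiny_world.triples[:8]])
        t_ = np.array([model.entity_index[t.tail] for t in tiny_world.triples[:8]])
        opt.zero_grad()
        (-model.kg_scores(h, r, t_).mean()).backward()
        opt.step()
        for a, b in zip(before_user, model.user_mlp_params()):
            assert np.array_equal(a, b.data)
        assert any(not np.array_equal(a, b.data)
                   for a, b in zip(before_rel, model.relation_mlp_params()))

    def test_rs_step_leaves_relation_mlp_untouched(self, tiny_world):
        model = MultitaskModel(tiny_world.user_ids, tiny_world.triples,
                               SMALL_CFG)
        before_rel = [t.data.copy() for t in model.relation_mlp_params()]
        before_user = [t.data.copy() for t in model.user_mlp_params()]
        opt = Adam(model.params(), lr=0.05)
        users = np.arange(8)
        items = np.array([model.entity_index[r.item]
                          for r in tiny_world.interactions[:8]])
        opt.zero_grad()
        model.rs_logits(users, items).mean().backward()
        opt.step()
        for a, b in zip(before_rel, model.relation_mlp_params()):
            assert np.array_equal(a, b.data)
        assert any(not np.array_equal(a, b.data)
                   for a, b in zip(before_user, model.user_mlp_params()))


class TestTrainJoint:
    def test_seeded_trace_bit_identical(self, tiny_world):
        etype = entity_type_map(tiny_world.schema)
        args = (tiny_world.user_ids, tiny_world.interactions,
                tiny_world.triples, SMALL_CFG)
        _, t1 = train_joint(*args, entity_type=etype)
        _, t2 = train_joint(*args, entity_type=etype)
        assert [(r.l_rs, r.l_kg, r.l_reg) for r in t1] \
            == [(r.l_rs, r.l_kg, r.l_reg) for r in t2]

    def test_item_entity_overlap_required(self, tiny_world):
        bad = list(tiny_world.interactions[:5])
        bad.append(InteractionRecord("user_0", "not_an_entity", 1))
        with pytest.raises(HarnessError):
            train_joint(tiny_world.user_ids, bad, tiny_world.triples,
                        SMALL_CFG)

    def test_loss_trace_decreases(self, tiny_world):
        from dataclasses import replace

        cfg = replace(SMALL_CFG, epochs=5, lr=0.05)
        _, trace = train_joint(tiny_world.user_ids, tiny_world.interactions,
                               tiny_world.triples, cfg,
                               entity_type=entity_type_map(tiny_world.schema))
        l_rs = [r.l_rs for r in trace]
        assert l_rs[-1] < l_rs[0]
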