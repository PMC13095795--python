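import numpy as np
import pytest

from mvfuse.dataset_io import ViewTriplet
from mvfuse.engine import Linear, Tensor, global_avg_pool
from mvfuse.multiview_model import (AttentionWeights, FeatureBundle,
                                    ModelConfig, MultiViewClassifier,
                                    build_model, classify, compute_attention,
                                    encode_views, fuse_concat, fuse_views,
                                    _to_input)
from mvfuse.trainer import set_global_seed

VIEWS = ("dorsal", "lateral", "ventral")


def _triplet(rng, views=VIEWS, size=32):
    imgs = {v: rng.integers(0, 255, (size, size, 3)).astype(np.uint8)
            for v in views}
    return ViewTriplet(images=imgs,
                       availability=tuple(v in views for v in VIEWS),
                       label=0, subfamily=0, specimen_id="t0")


def _bundle(vectors: dict) -> FeatureBundle:
    return FeatureBundle(maps={v: f.reshape(-1, 1, 1) for v, f in vectors.items()},
                         vectors=vectors)


def _scorer(dim, weight=0.0, bias=0.0):
    head = Linear(dim, 1)
    head.weight.data[:] = weight
    head.bias.data[:] = bias
    return head


class TestEncodeViews:
    def test_gap_of_constant_map_is_the_constant(self):
        F = np.full((5, 3, 3), 2.5, np.float32)
        assert np.allclose(F.mean(axis=(1, 2)), 2.5)
        t = Tensor(F[None])
        np.testing.assert_allclose(global_avg_pool(t).data, 2.5)

    def test_gap_arithmetic_mean(self):
        F = np.array([[[1.0, 2.0], [3.0, 4.0]]], np.float32)
        assert global_avg_pool(Tensor(F[None])).data[0, 0] == pytest.approx(2.5)

    def test_shared_weights_give_identical_features_for_identical_views(self, rng):
        set_global_seed(0)
        from mvfuse.backbone_zoo import build_encoder
        enc = build_encoder("tinycnn").eval()
        img = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        t = ViewTriplet(images={"dorsal": img, "lateral": img.copy()},
                        availability=(True, True, False), label=0, subfamily=0)
        bundle = encode_views(t, enc)
        np.testing.assert_array_equal(bundle.vectors["dorsal"],
                                      bundle.vectors["lateral"])

    def test_empty_triplet_rejected(self):
        from mvfuse.backbone_zoo import build_encoder
        enc = build_encoder("tinycnn")
        t = ViewTriplet(images={}, availability=(False,) * 3, label=0, subfamily=0)
        with pytest.raises(ValueError):
            encode_views(t, enc)


class TestComputeAttention:
    def test_equal_scores_give_uniform_weights(self, rng):
        vecs = {v: rng.normal(0, 1, 4).astype(np.float32) for v in VIEWS}
        heads = {v: _scorer(4, 0.0, 0.7) for v in VIEWS}
        w = compute_attention(_bundle(vecs), heads, sigma="identity")
        for v in VIEWS:
            assert w.alpha[v] == pytest.approx(1 / 3, abs=1e-6)

    def test_log2_score_closed_form(self):
        # scores (ln2, 0, 0) -> softmax = (2,1,1)/4
        vecs = {v: np.ones(1, np.float32) for v in VIEWS}
        heads = {"dorsal": _scorer(1, 0.0, np.log(2.0)),
                 "lateral": _scorer(1, 0.0, 0.0),
                 "ventral": _scorer(1, 0.0, 0.0)}
        w = compute_attention(_bundle(vecs), heads, sigma="identity")
        assert w.alpha["dorsal"] == pytest.approx(0.5, abs=1e-6)
        assert w.alpha["lateral"] == pytest.approx(0.25, abs=1e-6)
        assert w.alpha["ventral"] == pytest.approx(0.25, abs=1e-6)

    def test_missing_view_is_masked_with_exact_zero(self, rng):
        vecs = {v: rng.normal(0, 1, 4).astype(np.float32)
                for v in ("dorsal", "lateral")}
        heads = {v: _scorer(4, 0.0, 0.3) for v in VIEWS}
        w = compute_attention(_bundle(vecs), heads)
        assert w.alpha["ventral"] == 0.0
        assert w.alpha["dorsal"] == pytest.approx(0.5, abs=1e-6)
        assert sum(w.alpha.values()) == pytest.approx(1.0, abs=1e-6)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_attention(_bundle({}), {})


class TestFusion:
    def test_one_hot_weights_select_a_view(self, rng):
        vecs = {v: rng.normal(0, 1, 6).astype(np.float32) for v in VIEWS}
        w = AttentionWeights(scores={}, alpha={"dorsal": 1.0, "lateral": 0.0,
                                               "ventral": 0.0})
        np.testing.assert_allclose(fuse_views(_bundle(vecs), w), vecs["dorsal"])

    def test_uniform_weights_give_view_mean(self, rng):
        vecs = {v: rng.normal(0, 1, 6).astype(np.float32) for v in VIEWS}
        w = AttentionWeights(scores={}, alpha={v: 1 / 3 for v in VIEWS})
        expected = np.mean([vecs[v] for v in VIEWS], axis=0)
        np.testing.assert_allclose(fuse_views(_bundle(vecs), w), expected,
                                   rtol=1e-6)

    def test_basis_vector_combination(self):
        e = np.eye(4, dtype=np.float32)
        vecs = dict(zip(VIEWS, e[:3]))
        w = AttentionWeights(scores={}, alpha={"dorsal": 0.5, "lateral": 0.25,
                                               "ventral": 0.25})
        np.testing.assert_allclose(fuse_views(_bundle(vecs), w),
                                   [0.5, 0.25, 0.25, 0.0])

    def test_concat_fixed_order(self, rng):
        vecs = {v: rng.normal(0, 1, 4).astype(np.float32) for v in VIEWS}
        out = fuse_concat(_bundle(vecs))
        assert out.shape == (12,)
        np.testing.assert_allclose(out[:4], vecs["dorsal"])
        np.testing.assert_allclose(out[8:], vecs["ventral"])

    def test_concat_zero_fills_missing(self, rng):
        vecs = {v: rng.normal(0, 1, 4).astype(np.float32)
                for v in ("dorsal", "lateral")}
        out = fuse_concat(_bundle(vecs))
        assert np.all(out[8:] == 0.0)

    def test_concat_respects_custom_order(self, rng):
        vecs = {v: rng.normal(0, 1, 4).astype(np.float32) for v in VIEWS}
        out = fuse_concat(_bundle(vecs), view_order=("ventral", "dorsal", "lateral"))
        np.testing.assert_allclose(out[:4], vecs["ventral"])


class TestClassify:
    def test_zero_input_zero_bias_gives_zero_logits(self):
        head = Linear(6, 4)
        head.bias.data[:] = 0.0
        np.testing.assert_allclose(classify(np.zeros(6, np.float32), head), 0.0)

    def test_eval_mode_is_deterministic(self, rng):
        head = Linear(6, 4)
        x = rng.normal(0, 1, 6).astype(np.float32)
        a = classify(x, head, training=False, dropout_p=0.5)
        b = classify(x, head, training=False, dropout_p=0.5)
        np.testing.assert_array_equal(a, b)

    def test_identity_head_passes_through(self, rng):
        head = Linear(4, 4)
        head.weight.data[:] = np.eye(4)
        head.bias.data[:] = 0.0
        x = rng.normal(0, 1, 4).astype(np.float32)
        np.testing.assert_allclose(classify(x, head), x, rtol=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify(np.zeros(5, np.float32), Linear(6, 4))


class TestBatchedModel:
    def _model(self, variant="attention", views=VIEWS, seed=0, sigma="tanh"):
        set_global_seed(seed)
        return build_model(ModelConfig(variant=variant, views=views, n_classes=5,
                                       backbone="tinycnn", input_size=32,
                                       dropout_p=0.0, sigma=sigma))

    def _batch(self, rng, n=4, missing=()):
        imgs = {v: rng.normal(0, 1, (n, 3, 32, 32)).astype(np.float32)
                for v in VIEWS}
        avail = {v: np.ones(n, bool) for v in VIEWS}
        for v, i in missing:
            avail[v][i] = False
        return imgs, avail

    def test_attention_weights_normalized_under_masking(self, rng):
        model = self._model()
        imgs, avail = self._batch(rng, missing=[("ventral", 0), ("lateral", 2)])
        model.eval()
        model(imgs, avail)
        total = sum(model.last_alphas[v] for v in VIEWS)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)
        assert model.last_alphas["ventral"][0] == 0.0
        assert np.all(np.concatenate(list(model.last_alphas.values())) >= 0.0)

    def test_single_available_view_equals_single_view_model(self, rng):
        model = self._model()
        imgs, avail = self._batch(rng, n=2)
        avail["lateral"][:] = False
        avail["ventral"][:] = False
        logits = model.eval()(imgs, avail).data
        # same encoder/head applied as a plain single-stream classifier
        single = model.forward_images(imgs["dorsal"]).data
        np.testing.assert_allclose(logits, single, rtol=1e-5, atol=1e-6)

    def test_permuting_views_with_their_scorers_preserves_logits(self, rng):
        model = self._model()
        imgs, avail = self._batch(rng, missing=[("ventral", 1)])
        out = model.eval()(imgs, avail).data
        perm = {"dorsal": "ventral", "lateral": "dorsal", "ventral": "lateral"}
        imgs2 = {perm[v]: imgs[v] for v in VIEWS}
        avail2 = {perm[v]: avail[v] for v in VIEWS}
        model.scorers = {perm[v]: model.scorers[v] for v in VIEWS}
        out2 = model.eval()(imgs2, avail2).data
        np.testing.assert_allclose(out, out2, rtol=1e-5, atol=1e-6)

    def test_uniform_scores_equal_mean_fusion(self, rng):
        model = self._model(sigma="identity")
        for sc in model._scorer_list:
            sc.weight.data[:] = 0.0
            sc.bias.data[:] = 0.0
        imgs, avail = self._batch(rng)
        out = model.eval()(imgs, avail).data
        # mean of per-view GAP features through the same head
        from mvfuse.engine import Tensor as T
        gaps = [global_avg_pool(model.encoder(T(imgs[v]))).data for v in VIEWS]
        fused = np.mean(gaps, axis=0)
        expected = fused @ model.head.weight.data.T + model.head.bias.data
        np.testing.assert_allclose(out, expected, rtol=1e-4, atol=1e-5)

    def test_masked_view_receives_no_gradient(self, rng):
        from mvfuse.engine import softmax_cross_entropy

        model = self._model()
        imgs, avail = self._batch(rng, n=2)
        avail["ventral"][:] = False
        model.train()
        logits = model(imgs, avail)
        softmax_cross_entropy(logits, np.array([0, 1])).backward()
        assert "ventral" not in model.last_maps  # encoder never ran on it
        assert model.last_alphas["ventral"].sum() == 0.0

    def test_all_views_missing_row_rejected(self, rng):
        model = self._model()
        imgs, avail = self._batch(rng, n=2)
        for v in VIEWS:
            avail[v][1] = False
        with pytest.raises(ValueError, match="zero available"):
            model(imgs, avail)

    def test_baseline_variant_requires_image_forward(self, rng):
        model = self._model(variant="baseline")
        imgs, avail = self._batch(rng)
        with pytest.raises(ValueError, match="per-image"):
            model(imgs, avail)
        out = model.forward_images(imgs["dorsal"])
        assert out.data.shape == (4, 5)

    def test_concat_head_dimension(self):
        model = self._model(variant="concat")
        assert model.head.in_features == 3 * model.feature_dim

    def test_module_matches_functional_pipeline(self, rng):
        model = self._model()
        t = _triplet(rng)
        logits_module = model.eval().forward_triplet(t).data[0]
        bundle = encode_views(t, model.encoder)
        weights = compute_attention(bundle, model.scorers, model.config.sigma)
        fused = fuse_views(bundle, weights)
        logits_fn = classify(fused, model.head)
        np.testing.assert_allclose(logits_module, logits_fn, rtol=1e-4, atol=1e-5)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(variant="spatial").validate()
    with pytest.raises(ValueError):
        ModelConfig(views=()).validate()
    with pytest.raises(ValueError):
        ModelConfig(sigma="softplus").validate()
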