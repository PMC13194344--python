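"""Shape contracts, fusion properties and variant construction."""

import numpy as np
import pytest

import endovlm.autodiff as ad
from endovlm.autodiff import Tensor
from endovlm.model import (EmbeddingSet, ModelConfig, MultiTaskVLM,
                           make_variant)


@pytest.fixture(scope="module")
def model(small_model_config):
    return make_variant(small_model_config, "A_full", seed=1)


@pytest.fixture(scope="module")
def images(small_model_config):
    rng = np.random.default_rng(0)
    return rng.uniform(size=(3, small_model_config.image_size,
                             small_model_config.image_size, 3)).astype(np.float32)


class TestImageEncoder:
    def test_token_shape_contract(self, model, images, small_model_config):
        tokens, pooled = model.encode_image(images)
        grid = model.image_encoder.grid
        d = small_model_config.embed_dim
        assert tokens.shape == (3, grid * grid, d)
        assert pooled.shape == (3, d)

    def test_identical_images_identical_features(self, model, images):
        t1, p1 = model.encode_image(images)
        t2, p2 = model.encode_image(images)
        assert np.array_equal(t1.data, t2.data)
        two = np.stack([images[0], images[0]])
        t, _ = model.encode_image(two)
        assert np.array_equal(t.data[0], t.data[1])

    def test_pooled_equals_mean_of_tokens(self, model, images):
        tokens, pooled = model.encode_image(images)
        assert np.allclose(pooled.data, tokens.data.mean(axis=1), atol=1e-6)

    def test_shape_mismatch_raises(self, model):
        with pytest.raises(ValueError):
            model.encode_image(np.zeros((2, 64, 64)))


class TestTextEncoder:
    def test_single_token_pooled_equals_token_feature(self, model):
        ids = np.array([[5]])
        tokens, pooled = model.encode_text(ids)
        assert np.allclose(pooled.data[0], tokens.data[0, 0], atol=1e-6)

    def test_padding_excluded_from_pooling(self, model, tiny_vocab):
        ids = np.array([[5, 9, 17]])
        _, pooled_plain = model.encode_text(ids, np.ones((1, 3), bool))
        padded = np.array([[5, 9, 17, tiny_vocab.pad_id, tiny_vocab.pad_id]])
        mask = np.array([[True, True, True, False, False]])
        _, pooled_masked = model.encode_text(padded, mask)
        assert np.allclose(pooled_plain.data, pooled_masked.data, atol=1e-5)
        _, pooled_unmasked = model.encode_text(padded)
        assert not np.allclose(pooled_plain.data, pooled_unmasked.data, atol=1e-3)

    def test_out_of_vocab_id_raises(self, model, small_model_config):
        with pytest.raises(ValueError):
            model.encode_text(np.array([[small_model_config.vocab_size]]))

    def test_overlong_sequence_raises(self, model, small_model_config):
        T = small_model_config.max_text_len + 1
        with pytest.raises(ValueError):
            model.encode_text(np.zeros((1, T), dtype=np.int64))


class TestCrossAttention:
    def test_attention_rows_sum_to_one(self, model, images):
        ids = np.array([[3, 7, 11, 2], [4, 4, 1, 9], [1, 2, 3, 4]])
        emb = model.embed(images=images, text_ids=ids,
                          text_mask=np.ones_like(ids, bool))
        fused = model.cross_attend(emb)
        for name in ("image_to_text", "text_to_image"):
            assert np.allclose(fused.attention_maps[name].sum(-1), 1.0, atol=1e-6)
            assert np.all(fused.attention_maps[name] >= 0)

    def test_single_key_forces_full_attention(self, model, images):
        """One image patch: the attention weight is 1 and the context is that
        patch's (projected) value."""
        d = model.config.embed_dim
        one_patch = Tensor(np.random.default_rng(3).normal(
            size=(2, 1, d)).astype(np.float32))
        ids = np.array([[3, 7], [1, 2]])
        tt, tp = model.encode_text(ids)
        emb = EmbeddingSet(one_patch, one_patch.reshape(2, d), tt, tp,
                           np.ones_like(ids, bool))
        fused = model.cross_attend(emb)
        assert np.allclose(fused.attention_maps["text_to_image"], 1.0, atol=1e-6)
        attn = model.attn_text_to_image
        expected = attn.wo(attn.wv(one_patch)).data.reshape(2, d)
        assert np.allclose(fused.text_context.data, expected, atol=1e-5)

    def test_identical_keys_give_uniform_attention(self, model, images):
        d = model.config.embed_dim
        patch = np.random.default_rng(4).normal(size=(1, 1, d)).astype(np.float32)
        tokens = Tensor(np.repeat(patch, 6, axis=1))
        ids = np.array([[3, 7]])
        tt, tp = model.encode_text(ids)
        emb = EmbeddingSet(tokens, tokens.mean(axis=1), tt, tp,
                           np.ones_like(ids, bool))
        fused = model.cross_attend(emb)
        assert np.allclose(fused.attention_maps["text_to_image"], 1 / 6, atol=1e-6)

    def test_concatenation_order_embedding_then_context(self, model, images):
        ids = np.array([[3, 7, 11]] * 3)
        emb = model.embed(images=images, text_ids=ids,
                          text_mask=np.ones_like(ids, bool))
        fused = model.cross_attend(emb)
        d = model.config.embed_dim
        assert np.allclose(fused.classifier_input.data[:, :d],
                           emb.image_pooled.data, atol=1e-7)
        assert np.allclose(fused.classifier_input.data[:, d:],
                           fused.image_context.data, atol=1e-7)


class TestClassifier:
    def test_zero_logits_give_half_probability(self, small_model_config):
        m = make_variant(small_model_config, "A_full", seed=2)
        for p in m.classifier.fc3.parameters():
            p.data = np.zeros_like(p.data)
        x = Tensor(np.random.default_rng(0).normal(
            size=(4, 2 * small_model_config.embed_dim)).astype(np.float32))
        probs = m.classifier(x)
        assert np.allclose(probs.data, 0.5, atol=1e-7)

    def test_output_length_and_thresholding(self, model, images):
        ids = np.array([[3, 7]] * 3)
        emb = model.embed(images=images, text_ids=ids,
                          text_mask=np.ones_like(ids, bool))
        probs = model.classify_landmarks(model.cross_attend(emb))
        assert probs.shape == (3, model.config.n_classes)
        assert np.all((probs.data > 0) & (probs.data < 1))
        bits = (probs.data >= 0.5).astype(int)
        assert set(np.unique(bits)) <= {0, 1}


class TestGeneration:
    def _fused(self, model, images, ids):
        emb = model.embed(images=images, text_ids=ids,
                          text_mask=np.ones_like(ids, bool))
        return model.cross_attend(emb)

    def test_zero_budget_empty_generation(self, model, images, tiny_vocab):
        fused = self._fused(model, images, np.array([[3, 7]] * 3))
        out = model.generate_text(fused, [[tiny_vocab.start_id]] * 3,
                                  tiny_vocab, max_gen_len=0)
        assert all(len(s) == 0 for s in out)

    def test_greedy_is_deterministic(self, model, images, tiny_vocab):
        fused = self._fused(model, images, np.array([[3, 7]] * 3))
        a = model.generate_text(fused, [[tiny_vocab.start_id]] * 3, tiny_vocab)
        b = model.generate_text(fused, [[tiny_vocab.start_id]] * 3, tiny_vocab)
        assert all(np.array_equal(x.ids, y.ids) for x, y in zip(a, b))

    def test_generated_ids_valid_and_end_trimmed(self, model, images, tiny_vocab):
        fused = self._fused(model, images, np.array([[3, 7]] * 3))
        out = model.generate_text(fused, [[tiny_vocab.start_id]] * 3,
                                  tiny_vocab, max_gen_len=20)
        for seq in out:
            assert len(seq) <= 20
            assert all(0 <= i < len(tiny_vocab) for i in seq.ids)
            assert tiny_vocab.end_id not in seq.ids

    def test_empty_start_tokens_rejected(self, model, images, tiny_vocab):
        fused = self._fused(model, images, np.array([[3, 7]] * 3))
        with pytest.raises(ValueError):
            model.generate_text(fused, [[]] * 3, tiny_vocab)


class TestVariants:
    def test_unknown_variant_rejected(self, small_model_config):
        with pytest.raises(ValueError):
            make_variant(small_model_config, "E_extra")

    def test_image_only_has_no_text_outputs(self, small_model_config, images):
        m = make_variant(small_model_config, "B_image_only", seed=3)
        assert m.decoder is None and m.text_encoder is None
        emb = m.embed(images=images)
        fused = m.cross_attend(emb)
        assert fused.attention_maps == {}
        probs = m.classify_landmarks(fused)
        assert probs.shape == (3, 16)
        with pytest.raises(ValueError):
            m.generate_text(fused, [[0]], None)

    def test_text_only_has_no_classifier(self, small_model_config):
        m = make_variant(small_model_config, "C_text_only", seed=3)
        assert m.classifier is None and m.image_encoder is None
        ids = np.array([[3, 7, 1]])
        fused = m.cross_attend(m.embed(text_ids=ids,
                                       text_mask=np.ones_like(ids, bool)))
        with pytest.raises(ValueError):
            m.classify_landmarks(fused)
        d = small_model_config.embed_dim
        assert np.allclose(fused.decoder_init.data[:, d:], 0.0)

    def test_no_cross_attention_variant_zero_contexts(self, small_model_config,
                                                      images):
        m = make_variant(small_model_config, "D_no_cross_attention", seed=3)
        ids = np.array([[3, 7, 1]] * 3)
        fused = m.cross_attend(m.embed(images=images, text_ids=ids,
                                       text_mask=np.ones_like(ids, bool)))
        assert fused.attention_maps == {}
        d = small_model_config.embed_dim
        assert np.allclose(fused.classifier_input.data[:, d:], 0.0)
        assert np.allclose(fused.decoder_init.data[:, d:], 0.0)

    def test_parameter_census_a_vs_d(self, small_model_config):
        a = make_variant(small_model_config, "A_full", seed=4)
        d = make_variant(small_model_config, "D_no_cross_attention", seed=4)
        attn_params = (a.attn_image_to_text.n_parameters()
                       + a.attn_text_to_image.n_parameters())
        assert a.n_parameters() - d.n_parameters() == attn_params
        # heads are weight-compatible across A and D
        assert {k: v.shape for k, v in a.classifier.state_dict().items()} == \
               {k: v.shape for k, v in d.classifier.state_dict().items()}


class TestCheckpoint:
    def test_save_load_round_trip(self, small_model_config, images, tmp_path):
        m = make_variant(small_model_config, "A_full", seed=5)
        path = tmp_path / "model.npz"
        m.save(path)
        back = MultiTaskVLM.load(path)
        assert back.variant == m.variant
        t1, _ = m.encode_image(images)
        t2, _ = back.encode_image(images)
        assert np.array_equal(t1.data, t2.data)
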