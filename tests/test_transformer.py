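"""Architecture invariants, gradient exactness, and attention behavior."""

import numpy as np
import pytest

from semgst import STConfig, SignalTransformer, embed, merge_patches, split_patches
from semgst.transformer import attention_rollout


TINY = dict(image_size=6, patch_size=3, embed_dim=8, n_layers=2, n_heads=2,
            mlp_head_dims=(8,), n_classes=3, dropout=0.0, seed=3)


@pytest.fixture()
def tiny_model():
    return SignalTransformer(STConfig(**TINY))


class TestPatching:
    def test_canonical_geometry(self):
        """72x72 with patch 6 -> 144 patches of 36 values, 145 tokens."""
        cfg = STConfig(image_size=72, patch_size=6, n_classes=4)
        assert cfg.n_patches == 144
        assert cfg.patch_dim == 36
        patches = split_patches(np.zeros((72, 72, 1)), 6)
        assert patches.shape == (144, 36)

    def test_single_patch_is_flat_image(self, rng):
        img = rng.random((6, 6, 1))
        patches = split_patches(img, 6)
        np.testing.assert_array_equal(patches, img.reshape(1, -1))

    def test_reassembly_is_lossless(self, rng):
        img = rng.random((12, 18, 2))
        patches = split_patches(img, 3)
        back = merge_patches(patches, 12, 18, 2, 3)
        np.testing.assert_array_equal(back, img)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            split_patches(np.zeros((10, 10, 1)), 3)


class TestEmbed:
    def test_zero_input_gives_position_embeddings(self, rng):
        E = rng.standard_normal((9, 4))
        pos = rng.standard_normal((5, 4))
        tokens = embed(np.zeros((4, 9)), E, np.zeros(4), pos)
        np.testing.assert_array_equal(tokens, pos)

    def test_token_sequence_has_n_plus_one_rows(self, rng):
        E = rng.standard_normal((36, 64))
        tokens = embed(rng.standard_normal((144, 36)), E,
                       rng.standard_normal(64), rng.standard_normal((145, 64)))
        assert tokens.shape == (145, 64)

    def test_permutation_equivariance_of_logits(self, tiny_model, rng):
        """Permuting patches together with position rows 1..N leaves the
        classifier output unchanged."""
        cfg = tiny_model.config
        x = rng.standard_normal((1, cfg.n_patches, cfg.patch_dim))
        base, _ = tiny_model.forward(x)
        perm = rng.permutation(cfg.n_patches)
        pos = tiny_model.params["pos"]
        saved = pos.copy()
        pos[1:] = saved[1:][perm]
        permuted, _ = tiny_model.forward(x[:, perm])
        tiny_model.params["pos"][:] = saved
        np.testing.assert_allclose(permuted, base, rtol=1e-10)


class TestEncoder:
    def test_zeroed_branches_act_as_identity(self, tiny_model, rng):
        """With attention value/out and MLP weights zeroed, each layer is a
        pure residual pass-through, so logits equal the zero-model output."""
        m = tiny_model
        for l in range(m.config.n_layers):
            for name in ("Wv", "bv", "Wo", "bo", "W1", "b1", "W2", "b2"):
                m.params[f"enc{l}.{name}"][:] = 0.0
        x = rng.standard_normal((2, m.config.n_patches, m.config.patch_dim))
        logits, cache = m.forward(x)
        # encoder output must equal the embedded input sequence
        tok = x @ m.params["embed.E"]
        z0 = np.concatenate(
            [np.broadcast_to(m.params["cls"], (2, 1, 8)), tok], axis=1
        ) + m.params["pos"]
        np.testing.assert_allclose(cache["zL"], z0, atol=1e-12)

    def test_shape_preserved_through_layers(self, tiny_model, rng):
        x = rng.standard_normal((3, tiny_model.config.n_patches,
                                 tiny_model.config.patch_dim))
        _, cache = tiny_model.forward(x)
        assert cache["zL"].shape == (3, tiny_model.config.n_patches + 1, 8)

    def test_attention_rows_are_distributions(self, tiny_model, rng):
        x = rng.standard_normal((2, tiny_model.config.n_patches,
                                 tiny_model.config.patch_dim))
        for attn in tiny_model.attention_maps(x):
            assert np.all(attn >= 0)
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0, rtol=1e-9)


class TestClassify:
    def test_probabilities_sum_to_one(self, tiny_model, rng):
        x = rng.standard_normal((5, tiny_model.config.n_patches,
                                 tiny_model.config.patch_dim))
        probs = tiny_model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_fresh_model_is_uniform(self, tiny_model, rng):
        """The zero-initialized logit layer yields exactly uniform class
        probabilities before any training."""
        x = rng.standard_normal((2, tiny_model.config.n_patches,
                                 tiny_model.config.patch_dim))
        np.testing.assert_allclose(tiny_model.predict_proba(x), 1.0 / 3)

    def test_head_reads_only_token_zero(self, tiny_model, rng):
        zL = rng.standard_normal((2, tiny_model.config.n_patches + 1, 8))
        base = tiny_model.classify(zL)
        perturbed = zL.copy()
        perturbed[:, 1:] += rng.standard_normal(perturbed[:, 1:].shape)
        np.testing.assert_array_equal(tiny_model.classify(perturbed), base)


class TestForward:
    def test_eval_mode_deterministic(self, rng):
        m = SignalTransformer(STConfig(**{**TINY, "dropout": 0.1}))
        x = rng.standard_normal((2, m.config.n_patches, m.config.patch_dim))
        a, _ = m.forward(x, train=False)
        b, _ = m.forward(x, train=False)
        np.testing.assert_array_equal(a, b)

    def test_batch_items_independent(self, tiny_model, rng):
        x = rng.standard_normal((4, tiny_model.config.n_patches,
                                 tiny_model.config.patch_dim))
        batched, _ = tiny_model.forward(x)
        singles = np.vstack([tiny_model.forward(x[i:i + 1])[0] for i in range(4)])
        np.testing.assert_allclose(batched, singles, rtol=1e-12)

    def test_wrong_patch_geometry_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((1, 5, 9)))


class TestGradients:
    def test_analytic_matches_finite_differences(self, tiny_model, rng):
        """Backprop gradients agree with central differences on a sample of
        coordinates from every parameter tensor."""
        m = tiny_model
        x = rng.standard_normal((4, m.config.n_patches, m.config.patch_dim))
        y = np.array([0, 1, 2, 1])
        _, grads = m.loss_and_grads(x, y, train=False)
        eps = 1e-6
        for key, p in m.params.items():
            flat = p.reshape(-1)
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = m.loss_and_grads(x, y, train=False)
                flat[i] = orig - eps
                lm, _ = m.loss_and_grads(x, y, train=False)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].reshape(-1)[i]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), key

    def test_gradient_reaches_embeddings(self, tiny_model, rng):
        """One training probe sends non-zero gradient into E, E_pos and the
        CLS token."""
        m = tiny_model
        x = rng.standard_normal((4, m.config.n_patches, m.config.patch_dim))
        y = np.array([0, 1, 2, 0])
        # one optimizer step so the zero-initialized logit layer opens the
        # gradient path to everything below it
        from semgst.train_eval import AdamW
        opt = AdamW(m.params, lr=1e-3)
        _, g = m.loss_and_grads(x, y, train=False)
        opt.step(g)
        _, g = m.loss_and_grads(x, y, train=False)
        for key in ("embed.E", "pos", "cls"):
            assert np.any(g[key] != 0.0), key


class TestParameterCount:
    def test_count_depends_only_on_config(self):
        a = SignalTransformer(STConfig(**TINY)).n_parameters()
        b = SignalTransformer(STConfig(**{**TINY, "seed": 99})).n_parameters()
        assert a == b

    def test_image_size_changes_only_position_rows(self):
        small = SignalTransformer(STConfig(**TINY))
        big = SignalTransformer(STConfig(**{**TINY, "image_size": 12}))
        diff = big.n_parameters() - small.n_parameters()
        extra_tokens = big.config.n_patches - small.config.n_patches
        assert diff == extra_tokens * big.config.embed_dim


def test_attention_rollout_is_distribution(tiny_model, rng):
    x = rng.standard_normal((3, tiny_model.config.n_patches,
                             tiny_model.config.patch_dim))
    mass = attention_rollout(tiny_model.attention_maps(x))
    assert mass.shape == (3, tiny_model.config.n_patches)
    assert np.all(mass >= 0)
    np.testing.assert_allclose(mass.sum(axis=1), 1.0, rtol=1e-9)
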