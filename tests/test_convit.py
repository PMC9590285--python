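"""ConViT attention semantics, conv-initialization equivalence and training.

The functional single-head ops are checked against dense-loop oracles and
closed forms; the trainable network's attention is cross-checked against the
functional ops; conv-initialized heads are compared with an explicit
shift/convolution oracle on the 8x8 token grid.
"""

import numpy as np
import pytest

from ecgconvit.convit import (ConViTClassifier, ConViTConfig, GPSAParams,
                              TrainConfig, _ConViTNet, _softmax, conv_init,
                              extract_patches, gpsa_attention, gpsa_head,
                              head_centers, psa_attention, psa_head,
                              relative_encoding, unpatchify)

GRID = 8
N = GRID * GRID
POS = np.array([(r, c) for r in range(GRID) for c in range(GRID)])


class TestPatchEmbedding:
    def test_patch_count_and_inverse(self, rng):
        img = rng.random((160, 160))
        patches = extract_patches(img)
        assert patches.shape == (64, 400)
        assert np.array_equal(unpatchify(patches), img)

    def test_constant_image_gives_identical_tokens(self):
        patches = extract_patches(np.full((160, 160), 0.37))
        assert np.allclose(patches, patches[0])

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((100, 160)))


class TestPsaHead:
    def test_matches_dense_loop_oracle_on_small_instance(self, rng):
        params = GPSAParams.random(1, 2, 4, rng, grid_side=GRID)
        X = rng.normal(size=(N, 4))
        got = psa_head(X, params, 0)
        # dense-loop evaluation of the defining formula
        Q = X @ params.w_qry[0].T
        K = X @ params.w_key[0].T
        V = X @ params.w_val[0].T
        R = relative_encoding(GRID)
        want = np.zeros_like(got)
        for j in range(N):
            logits = np.array([Q[j] @ K[i] / np.sqrt(2) + params.v_pos[0] @ R[j, i]
                               for i in range(N)])
            e = np.exp(logits - logits.max())
            want[j] = (e / e.sum()) @ V
        assert np.abs(got - want).max() <= 1e-10

    def test_uniform_attention_when_positionless_and_tokens_identical(self, rng):
        params = GPSAParams.random(1, 3, 6, rng)
        params.v_pos[0] = 0.0
        X = np.tile(rng.normal(size=6), (N, 1))
        A = psa_attention(X, params, 0)
        assert np.allclose(A, 1.0 / N)

    def test_rows_sum_to_one(self, rng):
        params = GPSAParams.random(2, 3, 6, rng)
        X = rng.normal(size=(N, 6))
        for h in range(2):
            assert np.allclose(psa_attention(X, params, h).sum(axis=1), 1.0,
                               atol=1e-10)


class TestConvInit:
    def test_content_term_exactly_zero(self, rng):
        params = conv_init(GPSAParams.random(4, 12, 12, rng), strength=1.0)
        X = rng.normal(size=(N, 12))
        assert not ((X @ params.w_qry[0].T) @ (X @ params.w_key[0].T).T).any()

    def test_zero_offset_large_strength_is_identity(self, rng):
        params = conv_init(GPSAParams.random(1, 12, 12, rng),
                           centers=[(0.0, 0.0)], strength=100.0)
        X = rng.normal(size=(N, 12))
        assert np.abs(psa_head(X, params, 0) - X).max() <= 1e-6

    def test_each_head_is_a_grid_shift(self, rng):
        params = conv_init(GPSAParams.random(9, 12, 12, rng), strength=100.0)
        X = rng.normal(size=(N, 12))
        for h, (d1, d2) in enumerate(head_centers(9)):
            out = psa_head(X, params, h)
            # shift oracle: token j reads the token at offset Delta, or the
            # nearest in-grid offset at the boundary
            want = np.zeros_like(out)
            for j in range(N):
                target = POS[j] + np.array([d1, d2])
                i = int(np.argmin(((POS - target) ** 2).sum(axis=1)))
                want[j] = X[i]
            assert np.abs(out - want).max() <= 1e-6

    def test_nine_heads_express_3x3_convolution(self, rng):
        """Delta-filter heads assembled with filter weights reproduce a
        3x3 convolution over the token grid (interior tokens)."""
        params = conv_init(GPSAParams.random(9, 12, 12, rng), strength=100.0)
        X = rng.normal(size=(N, 12))
        filt = rng.normal(size=9)  # one scalar tap per offset
        mix = sum(filt[h] * psa_head(X, params, h) for h in range(9))
        grid_x = X.reshape(GRID, GRID, 12)
        centers = head_centers(9)
        for r in range(1, GRID - 1):
            for c in range(1, GRID - 1):
                want = sum(filt[h] * grid_x[r + int(d1), c + int(d2)]
                           for h, (d1, d2) in enumerate(centers))
                got = mix[r * GRID + c]
                assert np.abs(got - want).max() <= 1e-5

    def test_non_square_head_count_rejected(self, rng):
        with pytest.raises(ValueError):
            conv_init(GPSAParams.random(5, 2, 10, rng))


class TestGpsaHead:
    def test_gate_saturation_limits(self, rng):
        params = GPSAParams.random(1, 4, 8, rng)
        X = rng.normal(size=(N, 8))
        R = relative_encoding(GRID)
        params.lambda_gate[0] = 40.0   # sigma -> 1: positional only
        pos = _softmax(R @ params.v_pos[0], axis=1)
        assert np.abs(gpsa_attention(X, params, 0) - pos).max() <= 1e-6
        params.lambda_gate[0] = -40.0  # sigma -> 0: content only
        content = _softmax((X @ params.w_qry[0].T) @ (X @ params.w_key[0].T).T,
                           axis=1)
        assert np.abs(gpsa_attention(X, params, 0) - content).max() <= 1e-6

    def test_zero_gate_is_even_blend(self, rng):
        params = GPSAParams.random(1, 4, 8, rng)
        params.lambda_gate[0] = 0.0
        X = rng.normal(size=(N, 8))
        R = relative_encoding(GRID)
        pos = _softmax(R @ params.v_pos[0], axis=1)
        content = _softmax((X @ params.w_qry[0].T) @ (X @ params.w_key[0].T).T,
                           axis=1)
        blend = 0.5 * content + 0.5 * pos
        want = blend / blend.sum(axis=1, keepdims=True)
        assert np.abs(gpsa_attention(X, params, 0) - want).max() <= 1e-12

    def test_rows_sum_to_one(self, rng):
        params = GPSAParams.random(3, 4, 12, rng)
        X = rng.normal(size=(N, 12))
        for h in range(3):
            A = gpsa_attention(X, params, h)
            assert np.allclose(A.sum(axis=1), 1.0, atol=1e-10)

    def test_output_interpolates_between_gate_limits(self, rng):
        params = GPSAParams.random(1, 4, 8, rng)
        X = rng.normal(size=(N, 8))
        outs = []
        for lam in (-40.0, 0.0, 40.0):
            params.lambda_gate[0] = lam
            outs.append(gpsa_head(X, params, 0))
        # the mid-gate output lies between the two extremes in norm
        d_total = np.linalg.norm(outs[2] - outs[0])
        assert np.linalg.norm(outs[1] - outs[0]) <= d_total + 1e-9
        assert np.linalg.norm(outs[2] - outs[1]) <= d_total + 1e-9


class TestNetworkForward:
    def test_model_attention_matches_functional_ops(self, rng):
        """The trainable net's GPSA block must agree with the functional
        single-head semantics for the same weights."""
        cfg = ConViTConfig(n_gpsa_blocks=1, n_sa_blocks=0, embed_dim=12,
                           n_heads=4, dropout_rate=0.0)
        net = _ConViTNet(cfg, np.random.default_rng(0))
        X = rng.normal(size=(1, N, 12))
        from ecgconvit.autodiff import Tensor
        got = net._attend(Tensor(X), 0, train=False, rng=None).data[0]

        p = net.params
        d = cfg.head_dim
        heads = []
        for h in range(4):
            sl = slice(h * d, (h + 1) * d)
            fparams = GPSAParams(
                w_qry=p["b0_wq"].data.T[None, sl, :],
                w_key=p["b0_wk"].data.T[None, sl, :],
                w_val=p["b0_wv"].data.T[None, sl, :],
                v_pos=p["b0_vpos"].data[h][None, :],
                lambda_gate=p["b0_lam"].data[h][None],
                scale_content=cfg.scale_content)
            heads.append(gpsa_head(X[0], fparams, 0))
        want = np.concatenate(heads, axis=1) @ p["b0_wo"].data + p["b0_bo"].data
        assert np.abs(got - want).max() <= 1e-10

    def test_forward_is_deterministic_in_eval_mode(self, rng):
        cfg = ConViTConfig(n_gpsa_blocks=1, n_sa_blocks=1)
        net = _ConViTNet(cfg, np.random.default_rng(1))
        patches = rng.random((2, N, 400))
        a = net.forward(patches, train=False).data
        b = net.forward(patches, train=False).data
        assert np.array_equal(a, b)

    def test_probabilities_valid_and_stable(self, rng):
        clf = ConViTClassifier(n_gpsa_blocks=1, n_sa_blocks=1, epochs=1,
                               random_state=0)
        imgs = rng.random((8, 160, 160))
        labels = np.array(list("FNQSVFNQ"))
        clf.fit(imgs, labels)
        P = clf.predict_proba(imgs)
        assert P.shape == (8, 5)
        assert (P >= 0).all() and np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
        # tiny input perturbation cannot blow up the output
        imgs2 = imgs.copy()
        imgs2[0, 0, 0] += 1e-9
        assert np.abs(clf.predict_proba(imgs2) - P).max() < 1e-4


class TestTraining:
    def test_lr_schedule(self):
        tc = TrainConfig(learning_rate=1e-4, lr_decay=0.02, lr_decay_every=10)
        assert tc.lr_at_epoch(0) == 1e-4
        assert np.isclose(tc.lr_at_epoch(10), 1e-4 * 0.98)
        assert np.isclose(tc.lr_at_epoch(25), 1e-4 * 0.98 ** 2)

    def test_seed_determinism(self, rng):
        imgs = rng.random((10, 160, 160))
        labels = np.array(list("FNQSV") * 2)
        kw = dict(n_gpsa_blocks=1, n_sa_blocks=0, epochs=2, random_state=3)
        a = ConViTClassifier(**kw).fit(imgs, labels).predict_proba(imgs)
        b = ConViTClassifier(**kw).fit(imgs, labels).predict_proba(imgs)
        assert np.array_equal(a, b)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            ConViTClassifier(epochs=1).fit(np.empty((0, 160, 160)), [])

    def test_save_load_round_trip(self, tmp_path, rng):
        imgs = rng.random((5, 160, 160))
        labels = np.array(list("FNQSV"))
        clf = ConViTClassifier(n_gpsa_blocks=1, n_sa_blocks=0, epochs=1,
                               random_state=0).fit(imgs, labels)
        path = tmp_path / "model.npz"
        clf.save(path)
        back = ConViTClassifier.load(path)
        assert np.array_equal(back.predict_proba(imgs), clf.predict_proba(imgs))

    def test_sklearn_params_protocol(self):
        clf = ConViTClassifier()
        params = clf.get_params()
        assert params["embed_dim"] == 12 and params["epochs"] == 120
        clf.set_params(epochs=5)
        assert clf.epochs == 5
        with pytest.raises(ValueError):
            clf.set_params(nonsense=1)

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError):
            ConViTConfig(embed_dim=12, n_heads=5)
        with pytest.raises(ValueError):
            ConViTConfig(dropout_rate=1.0)
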