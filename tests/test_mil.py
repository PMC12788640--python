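"""Tiling, instance selection, the ordinal codec, MIL forward invariants,
training contracts, and the quadratic-weighted kappa."""

import numpy as np
import pytest

from histoimmune.mil import (
    MILClassifier,
    MILModel,
    MilModelSpec,
    TileBag,
    decode_ordinal,
    encode_ordinal,
    evaluate_mil,
    gated_attention_pool,
    mil_forward,
    qwk,
    select_instances,
    tile_slide,
)
from histoimmune.nn import GatedAttention
from histoimmune.synthetic_data import simulate_slide_bag


class TestTileSlide:
    def test_exact_grid(self):
        img = np.zeros((448, 448, 3), dtype=np.uint8)
        tiles = tile_slide(img, 224)
        coords = [c for _, c in tiles]
        assert coords == [(0, 0), (0, 224), (224, 0), (224, 224)]

    def test_partial_edges_discarded(self):
        img = np.zeros((500, 500, 3), dtype=np.uint8)
        tiles = tile_slide(img, 224)
        assert len(tiles) == 4
        assert all(t.shape == (224, 224, 3) for t, _ in tiles)

    def test_too_small_image_errors(self):
        with pytest.raises(ValueError):
            tile_slide(np.zeros((100, 100, 3), dtype=np.uint8), 224)

    def test_tiff_roundtrip(self, tmp_path):
        import tifffile

        img = np.random.default_rng(0).integers(0, 255, size=(128, 96, 3), dtype=np.uint8)
        path = tmp_path / "slide.tif"
        tifffile.imwrite(path, img)
        tiles = tile_slide(path, 64)
        assert len(tiles) == 2  # 2x1 grid
        np.testing.assert_array_equal(tiles[0][0], img[:64, :64])


class TestSelectInstances:
    def test_train_mode_takes_darkest(self):
        rng = np.random.default_rng(0)
        tiles = [np.full((8, 8, 3), v, dtype=np.uint8) for v in rng.permutation(100)]
        chosen = select_instances(tiles, 44, mode="train")
        means = sorted(float(t.mean()) for t in chosen)
        assert means == list(range(44))

    def test_small_bag_kept_whole(self):
        tiles = [np.zeros((4, 4, 3))] * 30
        assert len(select_instances(tiles, 44, mode="train")) == 30
        assert len(select_instances(tiles, 44, mode="eval")) == 30

    def test_eval_subsample_deterministic(self):
        tiles = [np.full((4, 4, 3), i) for i in range(100)]
        a = select_instances(tiles, 44, seed=9, mode="eval")
        b = select_instances(tiles, 44, seed=9, mode="eval")
        assert [t[0, 0, 0] for t in a] == [t[0, 0, 0] for t in b]
        c = select_instances(tiles, 44, seed=10, mode="eval")
        assert [t[0, 0, 0] for t in a] != [t[0, 0, 0] for t in c]


class TestOrdinalCodec:
    def test_stated_encoding(self):
        np.testing.assert_array_equal(encode_ordinal(2, 4), [1, 1, 1, 0])
        np.testing.assert_array_equal(encode_ordinal(0, 2), [1, 0])
        np.testing.assert_array_equal(encode_ordinal(1, 2), [1, 1])

    def test_roundtrip_exhaustive(self):
        for C in range(2, 17):
            for c in range(C):
                bits = encode_ordinal(c, C)
                assert np.all(np.diff(bits) <= 0)  # non-increasing
                assert bits[0] == 1.0
                assert decode_ordinal(bits) == c

    def test_decode_floors_at_zero(self):
        assert decode_ordinal([0.4, 0.3]) == 0
        assert decode_ordinal([0.9, 0.8, 0.2, 0.1]) == 1

    def test_guards(self):
        with pytest.raises(ValueError):
            encode_ordinal(4, 4)
        with pytest.raises(ValueError):
            decode_ordinal([1.5, 0.2])


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


class TestForwardInvariants:
    def test_gated_attention_single_instance(self, rng):
        att = GatedAttention(16, 8, np.random.default_rng(1))
        out = gated_attention_pool(rng.normal(size=(1, 16)), att)
        np.testing.assert_allclose(out.weights, [1.0])

    def test_gated_attention_duplicate_instances_equal_weights(self, rng):
        att = GatedAttention(16, 8, np.random.default_rng(1))
        h = rng.normal(size=(1, 16)).repeat(5, axis=0)
        out = gated_attention_pool(h, att)
        np.testing.assert_allclose(out.weights, 0.2, atol=1e-7)

    def test_gated_attention_permutation_equivariance(self, rng):
        att = GatedAttention(16, 8, np.random.default_rng(1))
        h = rng.normal(size=(10, 16))
        perm = rng.permutation(10)
        a = gated_attention_pool(h, att)
        b = gated_attention_pool(h[perm], att)
        np.testing.assert_allclose(b.weights, a.weights[perm], atol=1e-6)
        np.testing.assert_allclose(b.bag_embedding, a.bag_embedding, atol=1e-6)

    @pytest.mark.parametrize("mode", ["mean", "att", "att_trans"])
    def test_logits_permutation_invariant(self, rng, mode):
        spec = MilModelSpec(mode=mode, n_classes=3, d=32, attention_dim=16, transformer_heads=4)
        model = MILModel(spec, np.random.default_rng(2))
        bag = rng.random((12, 32, 32, 3)).astype(np.float32)
        perm = rng.permutation(12)
        out1 = mil_forward(model, bag)
        out2 = mil_forward(model, bag[perm])
        np.testing.assert_allclose(out1.logits, out2.logits, atol=1e-5)
        np.testing.assert_allclose(out1.weights.sum(), 1.0, atol=1e-6)
        np.testing.assert_allclose(out2.weights, out1.weights[perm], atol=1e-5)

    def test_mean_mode_identical_tiles_match_single_tile(self, rng):
        spec = MilModelSpec(mode="mean", n_classes=2, d=16)
        model = MILModel(spec, np.random.default_rng(3))
        tile = rng.random((1, 32, 32, 3)).astype(np.float32)
        bag = tile.repeat(7, axis=0)
        np.testing.assert_allclose(
            mil_forward(model, bag).logits, mil_forward(model, tile).logits, atol=1e-5
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            MilModelSpec(mode="concat")

    def test_gradient_flows_to_encoder(self, rng):
        from histoimmune.nn import Tensor, bce_with_logits

        spec = MilModelSpec(mode="att", n_classes=2, d=16)
        model = MILModel(spec, np.random.default_rng(4))
        bag = rng.random((5, 32, 32, 3)).astype(np.float32)
        _, _, logits = model.forward(bag)
        loss = bce_with_logits(logits, encode_ordinal(1, 2))
        loss.backward()
        gnorm = np.linalg.norm(model.encoder.conv1.weight.grad)
        assert np.isfinite(gnorm) and gnorm > 0


@pytest.fixture(scope="module")
def tiny_bags():
    bags, labels = [], []
    for i in range(24):
        lvl = i % 2
        s = simulate_slide_bag(lvl, n_tiles=16, tile_size=32, seed=50 + i)
        bags.append(s.tiles)
        labels.append(lvl)
    return bags, np.array(labels)


class TestTraining:
    def test_constant_label_converges_to_it(self, tiny_bags):
        bags, _ = tiny_bags
        clf = MILClassifier(mode="att", epochs=6, seed=0, augment=False)
        clf.fit(bags[:10], [1] * 10)
        assert np.all(clf.predict(bags[:10]) == 1)

    def test_same_seed_identical_first_epoch_loss(self, tiny_bags):
        bags, labels = tiny_bags
        runs = []
        for _ in range(2):
            clf = MILClassifier(mode="att", epochs=1, seed=3)
            clf.fit(bags[:12], labels[:12])
            runs.append(clf.history_["train_loss"][0])
        assert runs[0] == runs[1]

    def test_early_stopping_restores_best(self, tiny_bags):
        bags, labels = tiny_bags
        clf = MILClassifier(mode="att", epochs=12, patience=3, seed=1)
        clf.fit(bags[:16], labels[:16], val_bags=bags[16:], val_labels=labels[16:])
        best = max(clf.history_["val_metric"])
        acc = evaluate_mil(clf, bags[16:], labels[16:])["accuracy"]
        assert acc == pytest.approx(best)

    def test_empty_validation_with_early_stopping_errors(self, tiny_bags):
        bags, labels = tiny_bags
        with pytest.raises(ValueError):
            MILClassifier(epochs=1).fit(bags[:4], labels[:4], val_bags=[], val_labels=[])

    def test_label_range_validated(self, tiny_bags):
        bags, _ = tiny_bags
        with pytest.raises(ValueError):
            MILClassifier(n_classes=2, epochs=1).fit(bags[:4], [0, 1, 2, 0])

    def test_save_load_roundtrip(self, tiny_bags, tmp_path):
        bags, labels = tiny_bags
        clf = MILClassifier(mode="att_trans", epochs=2, seed=2, transformer_layers=1)
        clf.fit(bags[:8], labels[:8])
        path = tmp_path / "mil.npz"
        clf.save(path)
        loaded = MILClassifier.load(path)
        np.testing.assert_allclose(
            loaded.predict_logits(bags[8:12]), clf.predict_logits(bags[8:12]), atol=1e-7
        )

    def test_bags_with_more_than_k_instances_are_subsampled(self, tiny_bags):
        bags, labels = tiny_bags
        clf = MILClassifier(mode="mean", epochs=1, k_instances=8, seed=0)
        clf.fit(bags[:6], labels[:6])
        pred = clf.predict(bags[:2])  # 16 tiles > k=8 triggers eval subsampling
        assert pred.shape == (2,)


class TestQwk:
    def test_identical_vectors(self):
        assert qwk([0, 1, 2, 1], [0, 1, 2, 1], 3) == 1.0

    def test_hand_computed_antidiagonal(self):
        # O entirely off-diagonal, E uniform: kappa = 1 - 2/1 = -1
        assert qwk([0, 1], [1, 0], 2) == -1.0

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.integers(0, 4, size=40)
        t = rng.integers(0, 4, size=40)
        perm = rng.permutation(40)
        assert qwk(p, t, 4) == pytest.approx(qwk(p[perm], t[perm], 4), abs=1e-12)

    def test_matches_sklearn_quadratic_kappa(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        for _ in range(25):
            p = rng.integers(0, 4, size=60)
            t = rng.integers(0, 4, size=60)
            want = cohen_kappa_score(p, t, labels=range(4), weights="quadratic")
            assert qwk(p, t, 4) == pytest.approx(want, abs=1e-12)

    def test_constant_prediction_near_zero_kappa(self):
        t = np.array([0, 1] * 30)
        p = np.ones_like(t)
        assert abs(qwk(p, t, 2)) < 1e-12  # marginal-based chance correction

    def test_guards(self):
        with pytest.raises(ValueError):
            qwk([0], [0], 1)
        with pytest.raises(ValueError):
            qwk([0, 1], [0], 2)


class TestEvaluate:
    def test_perfect_predictions(self, tiny_bags):
        bags, labels = tiny_bags
        clf = MILClassifier(mode="att", epochs=8, seed=0)
        clf.fit(bags[:16], labels[:16], val_bags=bags[16:], val_labels=labels[16:])
        m = evaluate_mil(clf, bags[16:], labels[16:])
        assert set(m) == {"accuracy", "qwk", "predictions"}
        assert 0 <= m["accuracy"] <= 1

    def test_random_predictions_near_half_accuracy(self):
        rng = np.random.default_rng(2)
        pred = rng.integers(0, 2, size=10000)
        labels = rng.integers(0, 2, size=10000)
        assert abs(np.mean(pred == labels) - 0.5) < 0.02

    def test_tilebag_container_validation(self):
        with pytest.raises(ValueError):
            TileBag(slide_id="s", instances=np.zeros((4, 8, 8)), label=0)
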