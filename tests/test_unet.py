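"""Numpy encoder-decoder: gradients, training contracts, inference path."""

import numpy as np
import pytest

from endooct import (
    EncoderDecoder,
    compute_vet,
    evaluate_segmentation,
    segment_epithelium_classical,
    segment_epithelium_network,
    train_network,
)
from endooct.unet import _bce_dice_loss, predict_proba


def toy_pairs(n, size=16, seed=0):
    """Synthetic band images a tiny net can fit: bright band = mask."""
    rng = np.random.default_rng(seed)
    imgs = rng.random((n, size, size)).astype(np.float32) * 0.2
    masks = np.zeros((n, size, size), dtype=bool)
    for i in range(n):
        top = rng.integers(2, size - 6)
        masks[i, top:top + 4] = True
        imgs[i][masks[i]] += 0.7
    return imgs, masks


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        # directional derivative over all parameters, float64 for precision
        rng = np.random.default_rng(0)
        model = EncoderDecoder(base_channels=2, seed=1)
        for layer in model.layers.values():
            layer.W = layer.W.astype(np.float64)
            layer.b = layer.b.astype(np.float64)
            layer.dW = np.zeros_like(layer.W)
            layer.db = np.zeros_like(layer.b)
        x = rng.random((2, 8, 8))
        t = (rng.random((2, 8, 8)) > 0.5).astype(float)
        logits = model.forward(x, keep_cache=True)
        _, dlog = _bce_dice_loss(logits, t)
        model.backward(dlog.astype(np.float64))
        dirs, dot = {}, 0.0
        for name, layer in model.layers.items():
            for attr in ("W", "b"):
                d = rng.standard_normal(getattr(layer, attr).shape)
                dirs[(name, attr)] = d
                dot += float((getattr(layer, "d" + attr) * d).sum())
        eps = 1e-6
        for (n, a), d in dirs.items():
            getattr(model.layers[n], a)[...] += eps * d
        l1, _ = _bce_dice_loss(model.forward(x), t)
        for (n, a), d in dirs.items():
            getattr(model.layers[n], a)[...] -= 2 * eps * d
        l2, _ = _bce_dice_loss(model.forward(x), t)
        fd = (l1 - l2) / (2 * eps)
        assert dot == pytest.approx(fd, rel=1e-4)


class TestTrainingContracts:
    def test_empty_training_set_rejected(self):
        x = np.zeros((0, 16, 16))
        with pytest.raises(ValueError, match="empty"):
            train_network((x, x), (x, x))

    def test_too_few_pairs_rejected(self):
        imgs, masks = toy_pairs(10)
        with pytest.raises(ValueError, match="50"):
            train_network((imgs, masks), (imgs, masks))

    def test_shape_mismatch_rejected(self):
        imgs, masks = toy_pairs(60)
        with pytest.raises(ValueError, match="identical shapes"):
            train_network((imgs, masks[:, :8, :]), (imgs, masks))

    def test_identical_seed_identical_history(self):
        imgs, masks = toy_pairs(50)
        val = toy_pairs(8, seed=1)
        _, h1 = train_network((imgs, masks), val, epochs=2, seed=5, base_channels=2)
        _, h2 = train_network((imgs, masks), val, epochs=2, seed=5, base_channels=2)
        assert h1 == h2

    def test_learns_toy_band_task(self):
        imgs, masks = toy_pairs(60)
        val = toy_pairs(10, seed=1)
        model, hist = train_network((imgs, masks), val, epochs=6, seed=0,
                                    base_channels=4)
        assert hist[-1]["val_dice"] > 0.8
        assert model.trained

    def test_best_checkpoint_kept(self):
        imgs, masks = toy_pairs(60)
        val = toy_pairs(10, seed=1)
        model, hist = train_network((imgs, masks), val, epochs=4, seed=0,
                                    base_channels=2)
        best = max(h["val_dice"] for h in hist)
        restored = predict_proba(model, val[0])
        dice = np.mean([
            evaluate_segmentation(restored[i] >= 0.6, val[1][i]).dice
            for i in range(len(val[0]))
        ])
        assert dice == pytest.approx(best, abs=1e-6)


class TestInference:
    class _StubModel(EncoderDecoder):
        """Forward returns fixed logits so threshold semantics are isolated."""

        def __init__(self, prob_map):
            super().__init__(base_channels=2, seed=0)
            self.trained = True
            p = np.clip(prob_map, 1e-6, 1 - 1e-6)
            self._logits = np.log(p / (1 - p))

        def forward(self, x, keep_cache=False):
            return np.broadcast_to(self._logits, (x.shape[0],) + self._logits.shape)

    def test_threshold_semantics(self):
        # probabilities {0.5, 0.7} with threshold 0.6: only 0.7 retained
        prob = np.full((8, 8), 0.5)
        prob[3:5] = 0.7
        seg = segment_epithelium_network(np.ones((8, 8)), self._StubModel(prob),
                                         threshold=0.6)
        assert set(np.unique(seg.upper_boundary[seg.valid])) == {3}
        assert set(np.unique(seg.lower_boundary[seg.valid])) == {5}
        assert seg.probability_threshold == 0.6

    def test_all_one_probability_full_mask(self):
        prob = np.full((8, 8), 0.99)
        seg = segment_epithelium_network(np.ones((8, 8)), self._StubModel(prob))
        assert seg.mask.all()

    def test_largest_band_kept(self):
        prob = np.full((12, 12), 0.1)
        prob[2:6] = 0.9      # large band
        prob[9:10, :3] = 0.9  # small spur
        seg = segment_epithelium_network(np.ones((12, 12)), self._StubModel(prob))
        assert set(np.unique(seg.upper_boundary[seg.valid])) == {2}
        assert not seg.mask[9].any()

    def test_untrained_model_rejected(self):
        model = EncoderDecoder(base_channels=2, seed=0)
        with pytest.raises(ValueError, match="train"):
            segment_epithelium_network(np.ones((8, 8)), model)

    def test_bad_threshold_rejected(self):
        model = EncoderDecoder(base_channels=2, seed=0)
        model.trained = True
        with pytest.raises(ValueError, match="threshold"):
            segment_epithelium_network(np.ones((8, 8)), model, threshold=1.0)


class TestTrainedModel:
    def test_validation_dice_on_synthetic_bscans(self, trained_model):
        _, history = trained_model
        assert max(h["val_dice"] for h in history) > 0.9

    def test_agreement_with_classical_segmenter(self, trained_model,
                                                segmentation_data):
        # near-noiseless phantoms in the studied thickness range: the two
        # segmenters' mean VET should agree within one axial pixel
        model, _ = trained_model
        images, masks, thicknesses = segmentation_data
        diffs = []
        for i in range(250, 260):
            if not 100 <= thicknesses[i] <= 200:
                continue
            vet_net = compute_vet(segment_epithelium_network(images[i], model),
                                  14.0).mean_vet_um
            vet_cls = compute_vet(segment_epithelium_classical(images[i]),
                                  14.0).mean_vet_um
            diffs.append(vet_net - vet_cls)
        assert len(diffs) >= 3
        assert np.mean(np.abs(diffs)) <= 14.0

    def test_save_load_roundtrip(self, trained_model, tmp_path):
        model, _ = trained_model
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = EncoderDecoder.load(path)
        x = np.random.default_rng(0).random((2, 64, 64)).astype(np.float32)
        np.testing.assert_allclose(model.forward(x), loaded.forward(x))
        assert loaded.trained
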