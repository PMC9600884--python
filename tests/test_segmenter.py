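import numpy as np
import pytest

from ivcfind.segmenter import (
    TrainConfig,
    UNet,
    UNetConfig,
    UNetSegmenter,
    build_unet,
    train_val_split,
)


def _conv_block_params(c_in, c_out, bn, kernel=3):
    """Hand arithmetic for one conv->[BN]->activation stage."""
    return c_out * c_in * kernel * kernel + c_out + (2 * c_out if bn else 0)


def _expected_unet_params(depth, base, bn, n_classes=2, in_ch=1):
    """Layer-by-layer enumeration of the architecture's trainable arrays."""
    total, c = 0, in_ch
    for i in range(depth):
        f = base * 2 ** i
        total += _conv_block_params(c, f, bn) + _conv_block_params(f, f, bn)
        c = f
    fb = base * 2 ** depth
    total += _conv_block_params(c, fb, bn) + _conv_block_params(fb, fb, bn)
    c = fb
    for i in reversed(range(depth)):
        f = base * 2 ** i
        total += (_conv_block_params(c, f, bn) + _conv_block_params(2 * f, f, bn)
                  + _conv_block_params(f, f, bn))
        c = f
    return total + _conv_block_params(c, n_classes, bn=False, kernel=1)


class TestArchitecture:
    def test_miniature_parameter_count_hand_computed(self):
        """depth 1, base 1, BN: 24 (encoder) + 66 (bottleneck) + 54 (decoder) + 4 = 148."""
        net = build_unet(UNetConfig(input_shape=(8, 8), depth=1, base_filters=1))
        assert net.n_parameters == 148 == _expected_unet_params(1, 1, bn=True)

    @pytest.mark.parametrize("depth,base,bn", [(2, 3, True), (1, 4, False), (3, 2, True)])
    def test_parameter_count_matches_enumeration(self, depth, base, bn):
        cfg = UNetConfig(input_shape=(32, 32), depth=depth, base_filters=base,
                         batch_norm=bn)
        assert build_unet(cfg).n_parameters == _expected_unet_params(depth, base, bn)

    def test_doubling_base_filters_roughly_quadruples_conv_params(self):
        def conv_params(base):
            net = build_unet(UNetConfig(input_shape=(32, 32), depth=2,
                                        base_filters=base, batch_norm=False))
            return net.n_parameters

        ratio = conv_params(8) / conv_params(4)
        assert 3.5 < ratio < 4.5

    def test_indivisible_input_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig(input_shape=(250, 250), depth=3)

    def test_output_has_class_channels_at_input_resolution(self, rng):
        net = build_unet(UNetConfig(input_shape=(16, 16), depth=2, base_filters=2))
        out = net.forward(rng.random((3, 1, 16, 16)).astype(np.float32))
        assert out.shape == (3, 2, 16, 16)


class TestSplit:
    def test_reported_slice_split(self):
        """465 slices at 80/20 -> 372 train / 93 validation."""
        tr, va = train_val_split(465, 0.8, seed=0)
        assert (len(tr), len(va)) == (372, 93)
        assert sorted(np.concatenate([tr, va])) == list(range(465))

    def test_split_deterministic_per_seed(self):
        a, _ = train_val_split(100, 0.8, seed=5)
        b, _ = train_val_split(100, 0.8, seed=5)
        c, _ = train_val_split(100, 0.8, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


def _toy_data(rng, n=12, size=16):
    """Bright blob on dark background: trivially learnable segmentation."""
    X = rng.random((n, size, size)).astype(np.float32) * 0.2
    y = np.zeros((n, size, size), dtype=np.uint8)
    for k in range(n):
        r, c = rng.integers(4, size - 4, 2)
        X[k, r - 2:r + 2, c - 2:c + 2] = 1.0
        y[k, r - 2:r + 2, c - 2:c + 2] = 1
    return X, y


@pytest.fixture(scope="module")
def tiny_fitted():
    rng = np.random.default_rng(0)
    X, y = _toy_data(rng)
    est = UNetSegmenter(input_shape=(16, 16), depth=1, base_filters=2, epochs=60,
                        batch_size=4, learning_rate=1e-2, train_fraction=0.8, seed=1)
    return est.fit(X, y), X, y


class TestTraining:
    def test_loss_history_one_entry_per_epoch_and_decreasing(self, tiny_fitted):
        est, _, _ = tiny_fitted
        assert len(est.loss_history_) == est.epochs
        assert len(est.val_loss_history_) == est.epochs
        assert est.loss_history_[-1] < est.loss_history_[0]

    def test_learns_the_toy_segmentation(self, tiny_fitted):
        est, X, y = tiny_fitted
        pred = est.predict(X)
        agree = (pred == y).mean()
        assert agree > 0.95

    def test_empty_dataset_rejected(self):
        est = UNetSegmenter(input_shape=(16, 16), depth=1, base_filters=2)
        with pytest.raises(ValueError, match="empty"):
            est.fit(np.zeros((0, 16, 16)), np.zeros((0, 16, 16), dtype=np.uint8))

    def test_out_of_range_labels_rejected(self, rng):
        est = UNetSegmenter(input_shape=(16, 16), depth=1, base_filters=2, epochs=1)
        X = rng.random((4, 16, 16)).astype(np.float32)
        y = np.full((4, 16, 16), 3, dtype=np.uint8)
        with pytest.raises(ValueError, match="labels"):
            est.fit(X, y)


class TestInference:
    def test_duplicated_slices_get_identical_predictions(self, tiny_fitted, rng):
        est, X, _ = tiny_fitted
        doubled = np.stack([X[0], X[0]])
        pred = est.predict(doubled)
        np.testing.assert_array_equal(pred[0], pred[1])

    def test_forced_background_bias_yields_empty_mask(self, rng):
        cfg = UNetConfig(input_shape=(16, 16), depth=1, base_filters=2)
        est = UNetSegmenter(input_shape=(16, 16), depth=1, base_filters=2)
        est.model_ = UNet(cfg, seed=0)
        est.model_.final.params["b"][:] = [100.0, -100.0]
        est.classes_ = np.arange(2)
        pred = est.predict(rng.random((2, 16, 16)).astype(np.float32))
        assert (pred == 0).all()

    def test_shape_mismatch_with_model_grid_rejected(self, tiny_fitted):
        est, _, _ = tiny_fitted
        with pytest.raises(ValueError, match="input"):
            est.predict(np.zeros((1, 8, 8), dtype=np.float32))

    def test_checkpoint_round_trip_is_bit_identical(self, tiny_fitted, tmp_path, rng):
        est, X, _ = tiny_fitted
        path = tmp_path / "weights.npz"
        est.save(path)
        back = UNetSegmenter.load(path)
        assert back.n_parameters_ == est.n_parameters_
        probe = rng.random((3, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(est.predict(probe), back.predict(probe))
        np.testing.assert_array_equal(est.predict_proba(probe), back.predict_proba(probe))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(train_fraction=1.5)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
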