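"""Architecture, gradients, training behaviour and augmentation."""

import numpy as np
import pytest

from sevseg._nn import Adam, bce_with_logits
from sevseg.frunet import FRUNet, _apply_transform, augment


def classic_unet_parameter_count(base=64, levels=4, in_ch=1):
    """Parameter count of the classic U-Net of the same depth.

    Two 3x3 convolutions per level on both paths, channel-halving 2x2
    up-convolutions, and a 1x1 output head -- the architecture ours
    halves the feature maps of.  Serves as the comparison oracle.
    """
    def conv(ci, co, k=3):
        return ci * co * k * k + co

    total = 0
    c_prev = in_ch
    enc = [base * 2 ** i for i in range(levels)]
    for c in enc:                       # contracting: two 3x3 convs
        total += conv(c_prev, c) + conv(c, c)
        c_prev = c
    bott = base * 2 ** levels
    total += conv(c_prev, bott) + conv(bott, bott)
    c_prev = bott
    for c in reversed(enc):             # expanding: up-conv + two 3x3
        total += conv(c_prev, c, k=2)
        total += conv(c_prev, c) + conv(c, c)
        c_prev = c
    total += conv(c_prev, 1, k=1)
    return total


class TestArchitecture:
    def test_output_shape_equals_input_shape(self):
        est = FRUNet(base_features=2, epochs=0, random_state=0)
        for size in [(48, 48), (24, 40)]:
            x = np.random.default_rng(0).random((1,) + size, dtype=np.float32)
            est.fit(x, np.zeros((1,) + size, np.float32))
            assert est.predict(x).shape == (1,) + size

    def test_contracting_channel_sequence_doubles_to_8x(self):
        est = FRUNet(base_features=32, epochs=0, random_state=0)
        x = np.zeros((1, 16, 16), np.float32)
        est.fit(x, x)
        manifest = est.core_.manifest()
        assert manifest["contracting_channels"] == [32, 64, 128, 256]

    def test_untrained_model_predicts_half_everywhere(self):
        # the zero-initialised sigmoid head outputs sigmoid(0) = 0.5
        est = FRUNet(base_features=4, epochs=0, random_state=3)
        x = np.random.default_rng(1).random((2, 32, 32), dtype=np.float32)
        est.fit(x, np.zeros_like(x))
        np.testing.assert_allclose(est.predict(x), 0.5, atol=1e-6)

    def test_output_strictly_inside_unit_interval(self, trained_tiny_model,
                                                  small_scene_stack):
        p = trained_tiny_model.predict(small_scene_stack[0][:2])
        assert (p > 0).all() and (p < 1).all()

    def test_incompatible_patch_size_rejected(self):
        est = FRUNet(base_features=2, epochs=0)
        x = np.zeros((1, 30, 30), np.float32)
        with pytest.raises(ValueError, match="divisible"):
            est.fit(x, x)

    def test_fewer_parameters_than_doubled_feature_unet(self):
        est = FRUNet(base_features=32, epochs=0, random_state=0)
        x = np.zeros((1, 16, 16), np.float32)
        est.fit(x, x)
        assert est.n_parameters_ < classic_unet_parameter_count(
            base=64, levels=3)

    def test_gradients_match_finite_differences(self):
        est = FRUNet(base_features=2, dropout_rate=0.0, random_state=0)
        core = est._build(np.random.default_rng(0))
        rng = np.random.default_rng(5)
        x = rng.random((2, 1, 8, 8)).astype(np.float32)
        y = (rng.random((2, 1, 8, 8)) < 0.3).astype(np.float32)
        z = core.forward_logits(x)
        _, gz = bce_with_logits(z, y)
        for p in core.params:
            p.grad[...] = 0
        core.backward(gz)
        eps = 1e-3
        for p in core.params:
            flat = p.value.ravel()
            for i in rng.integers(0, flat.size, size=3):
                old = flat[i]
                flat[i] = old + eps
                lp = bce_with_logits(core.forward_logits(x), y)[0]
                flat[i] = old - eps
                lm = bce_with_logits(core.forward_logits(x), y)[0]
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = p.grad.ravel()[i]
                assert numeric == pytest.approx(analytic, abs=2e-3, rel=2e-2)


class TestAugment:
    def test_zero_aug_returns_only_originals(self, rng):
        patch = rng.random((16, 16))
        mask = (rng.random((16, 16)) < 0.5).astype(float)
        pairs = augment(patch, mask, n_aug=0, seed=0)
        assert len(pairs) == 1
        assert pairs[0][0] is patch and pairs[0][1] is mask

    def test_horizontal_flip_moves_disk(self):
        mask = np.zeros((200, 400))
        mask[100, 100] = 1
        t = {"flip_h": True, "flip_v": False, "rot90": 0, "zoom": 1.0}
        flipped = _apply_transform(mask, t, order=0)
        assert flipped[100, 299] == 1 and flipped.sum() == 1

    def test_reproducible_and_mask_consistent(self, rng):
        patch = rng.random((32, 32))
        mask = (rng.random((32, 32)) < 0.3).astype(np.uint8)
        a = augment(patch, mask, n_aug=5, seed=11)
        b = augment(patch, mask, n_aug=5, seed=11)
        assert len(a) == 6
        for (pa, ma), (pb, mb) in zip(a, b):
            assert np.array_equal(pa, pb) and np.array_equal(ma, mb)
            assert set(np.unique(ma)) <= {0, 1}
            assert pa.shape == ma.shape == patch.shape

    def test_geometry_applied_identically_to_patch_and_mask(self):
        # using the mask itself as the patch, both outputs must agree up
        # to the interpolation difference (bilinear patch vs nearest
        # mask), which is confined to the object boundary
        yy, xx = np.mgrid[0:32, 0:32]
        mask = ((yy - 16) ** 2 + (xx - 16) ** 2 <= 81).astype(float)
        for pa, ma in augment(mask, mask, n_aug=8, seed=3)[1:]:
            mismatch = (pa > 0.5) != (ma > 0.5)
            assert mismatch.mean() < 0.05

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((8, 8)), np.zeros((9, 8)), 1)


class TestTraining:
    def test_validation_split_is_tenth_of_real_patches(self, rng):
        X = rng.random((20, 16, 16)).astype(np.float32)
        y = (rng.random((20, 16, 16)) < 0.3).astype(np.float32)
        est = FRUNet(base_features=2, epochs=1, batch_size=4, n_aug=2,
                     random_state=0)
        est.fit(X, y)
        assert est.n_validation_ == 2
        assert est.n_training_real_ == 18
        assert est.n_training_total_ == 18 * 3   # originals + 2 augments

    def test_zero_epochs_is_noop_with_empty_history(self):
        x = np.random.default_rng(0).random((3, 16, 16), dtype=np.float32)
        est = FRUNet(base_features=2, epochs=0, random_state=1)
        est.fit(x, np.zeros_like(x))
        assert len(est.history_) == 0
        ref = FRUNet(base_features=2, epochs=0, random_state=1)
        ref.fit(x, np.zeros_like(x))
        for a, b in zip(est.core_.get_weights(), ref.core_.get_weights()):
            assert np.array_equal(a, b)

    def test_empty_training_set_rejected(self):
        est = FRUNet(base_features=2)
        with pytest.raises(ValueError):
            est.fit(np.empty((0, 16, 16)), np.empty((0, 16, 16)))

    def test_nonbinary_masks_rejected(self, rng):
        X = rng.random((2, 16, 16)).astype(np.float32)
        est = FRUNet(base_features=2, epochs=1)
        with pytest.raises(ValueError, match="binary"):
            est.fit(X, X)

    def test_loss_decreases_over_training(self, small_scene_stack):
        X, y = small_scene_stack
        est = FRUNet(base_features=4, epochs=8, batch_size=4,
                     learning_rate=2e-3, validation_fraction=0.0,
                     random_state=0)
        est.fit(X, y)
        assert est.history_.train_loss.iloc[-1] < est.history_.train_loss.iloc[0]

    def test_overfit_smoke_five_patches(self, small_scene_stack):
        """200 epochs on 5 patches must drive training loss below 0.1."""
        X, y = small_scene_stack
        est = FRUNet(base_features=8, epochs=200, batch_size=5,
                     learning_rate=2e-3, validation_fraction=0.0,
                     random_state=0)
        est.fit(X[:5], y[:5])
        assert est.history_.train_loss.iloc[-1] < 0.1

    def test_training_is_deterministic_given_seed(self, small_scene_stack):
        X, y = small_scene_stack
        runs = []
        for _ in range(2):
            est = FRUNet(base_features=2, epochs=2, batch_size=4,
                         random_state=9)
            est.fit(X[:6], y[:6])
            runs.append(est)
        for a, b in zip(runs[0].core_.get_weights(),
                        runs[1].core_.get_weights()):
            assert np.array_equal(a, b)

    def test_inference_deterministic(self, trained_tiny_model,
                                     small_scene_stack):
        X = small_scene_stack[0][:2]
        assert np.array_equal(trained_tiny_model.predict(X),
                              trained_tiny_model.predict(X))

    def test_trained_model_separates_disk_from_background(
            self, trained_tiny_model, small_scene_stack):
        X, y = small_scene_stack
        p = trained_tiny_model.predict(X[-2:])
        fg = y[-2:] > 0
        assert p[fg].mean() > p[~fg].mean() + 0.3


class TestCheckpoint:
    def test_save_load_roundtrip(self, trained_tiny_model, small_scene_stack,
                                 tmp_path):
        path = tmp_path / "model.npz"
        trained_tiny_model.save(path)
        assert (tmp_path / "model.npz.manifest.json").exists()
        loaded = FRUNet.load(path)
        X = small_scene_stack[0][:2]
        np.testing.assert_array_equal(trained_tiny_model.predict(X),
                                      loaded.predict(X))
        assert loaded.n_parameters_ == trained_tiny_model.n_parameters_

    def test_sklearn_param_interface(self):
        est = FRUNet(base_features=8)
        params = est.get_params()
        assert params["base_features"] == 8
        est.set_params(epochs=3)
        assert est.epochs == 3
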