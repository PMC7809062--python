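"""The 8-layer CNN: architecture arithmetic, features, filtering, training."""

import numpy as np
import pandas as pd
import pytest

from radfusion.deep import (
    ArchitectureSpec,
    LungStyleCNN,
    TrainConfig,
    extract_deep_features,
    filter_zero_variance,
    preprocess_roi,
    pretrain,
    select_largest_roi_slice,
)
from radfusion.synthetic import generate_roi_images


@pytest.fixture(scope="module")
def model():
    return LungStyleCNN(seed=0)


class TestArchitecture:
    def test_conv5_feature_dimension_is_64(self):
        assert ArchitectureSpec().n_features == 64

    def test_forward_pass_produces_64_features(self, model):
        x = np.random.default_rng(1).random((3, 32, 32))
        assert model.features(x).shape == (3, 64)

    def test_other_input_sizes_rejected(self, model):
        with pytest.raises(ValueError):
            model.features(np.zeros((2, 16, 16)))
        with pytest.raises(ValueError):
            model.features(np.zeros((2, 64, 64)))

    def test_zero_input_with_zero_biases_gives_zero_features(self, model):
        # biases start at zero, so a black image is annihilated by the
        # rectifier at every layer
        assert np.abs(model.features(np.zeros((1, 32, 32)))).max() == 0.0


class TestFeatureExtraction:
    def test_row_depends_only_on_its_image(self, model, rng):
        imgs = rng.random((5, 32, 32))
        batch = extract_deep_features(model, imgs)
        solo = extract_deep_features(model, imgs[2:3])
        assert np.allclose(batch.iloc[2].to_numpy(), solo.iloc[0].to_numpy())

    def test_identical_images_identical_rows(self, model):
        img = np.random.default_rng(3).random((32, 32))
        table = extract_deep_features(model, [img, img])
        assert (table.iloc[0] == table.iloc[1]).all()


class TestZeroVarianceFilter:
    def test_constant_columns_removed_order_preserved(self, rng):
        table = pd.DataFrame(rng.random((10, 5)), columns=list("abcde"))
        table["c"] = 7.0
        out = filter_zero_variance(table)
        assert list(out.columns) == ["a", "b", "d", "e"]

    def test_identity_when_no_constants(self, rng):
        table = pd.DataFrame(rng.random((6, 4)))
        assert filter_zero_variance(table).equals(table)

    def test_29_of_64_constant_leaves_35(self, rng):
        # mirrors the deep bank's 64 -> 35 reduction
        table = pd.DataFrame(rng.random((20, 64)),
                             columns=[f"deep_{j:02d}" for j in range(64)])
        dead = rng.choice(64, size=29, replace=False)
        table.iloc[:, dead] = 0.0
        out = filter_zero_variance(table)
        assert out.shape[1] == 35

    def test_idempotent(self, rng):
        table = pd.DataFrame(rng.random((8, 6)))
        table.iloc[:, 0] = 1.0
        once = filter_zero_variance(table)
        assert filter_zero_variance(once).equals(once)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            filter_zero_variance(pd.DataFrame(rng.random((1, 3))))
        with pytest.raises(ValueError):
            filter_zero_variance(pd.DataFrame(np.ones((5, 3))))


class TestPreprocess:
    def test_output_is_32_by_32_in_unit_range(self):
        img, mask, _ = generate_roi_images(1, seed=4)[0]
        out = preprocess_roi(img, mask)
        assert out.shape == (32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_background_blacked_out_before_resize(self):
        # a huge background intensity must not leak into the output range
        img = np.full((40, 40), 1e6)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        img[mask] = np.linspace(0, 100, mask.sum())
        out = preprocess_roi(img, mask)
        assert out.max() <= 1.0

    def test_constant_roi_maps_to_midgray(self):
        img = np.full((20, 20), 55.0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        out = preprocess_roi(img, mask)
        assert (out == 0.5).any()
        assert set(np.round(np.unique(out), 6)) <= {0.0, 0.5}

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            preprocess_roi(np.zeros((10, 10)), np.zeros((10, 10), bool))


class TestLargestSlice:
    def test_single_nonzero_slice_selected(self):
        vol = np.zeros((10, 8, 8))
        mask = np.zeros((10, 8, 8), dtype=bool)
        mask[7, 2:5, 2:5] = True
        img, m = select_largest_roi_slice(vol, mask)
        assert m.sum() == 9 and np.array_equal(m, mask[7])

    def test_argmax_by_area_with_tie_to_lowest_index(self):
        mask = np.zeros((9, 6, 6), dtype=bool)
        mask[2, 0, :3] = True   # area 3
        mask[5, 0, :5] = True   # area 5 (tied with slice 8)
        mask[8, 1, :5] = True
        _, m = select_largest_roi_slice(np.zeros((9, 6, 6)), mask)
        assert np.array_equal(m, mask[5])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            select_largest_roi_slice(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))


class TestPretrain:
    @pytest.fixture(scope="class")
    def textured_data(self):
        imgs = generate_roi_images(150, seed=10, texture_delta=40.0)
        x = np.stack([preprocess_roi(im, m) for im, m, _ in imgs])
        y = np.array([lab for _, _, lab in imgs])
        return x, y

    def test_learns_strong_texture_signal(self, textured_data):
        x, y = textured_data
        for seed in (0, 1, 2):
            model = LungStyleCNN(seed=seed)
            pretrain(model, x, y, TrainConfig(epochs=12, seed=seed))
            acc = (model.predict_proba(x).argmax(axis=1) == y).mean()
            assert acc > 0.9

    def test_zero_learning_rate_leaves_weights_unchanged(self, textured_data):
        x, y = textured_data
        model = LungStyleCNN(seed=5)
        before = {k: v.copy() for k, v in model.params.items()}
        pretrain(model, x[:32], y[:32], TrainConfig(epochs=1, learning_rate=0.0, seed=0))
        for k in before:
            assert np.array_equal(before[k], model.params[k])

    def test_same_seed_same_final_loss(self, textured_data):
        x, y = textured_data
        h1 = pretrain(LungStyleCNN(seed=2), x[:64], y[:64], TrainConfig(epochs=2, seed=3))
        h2 = pretrain(LungStyleCNN(seed=2), x[:64], y[:64], TrainConfig(epochs=2, seed=3))
        assert h1 == h2

    def test_single_class_rejected(self, textured_data):
        x, y = textured_data
        with pytest.raises(ValueError):
            pretrain(LungStyleCNN(seed=0), x[:8], np.zeros(8, dtype=int), TrainConfig(epochs=1))


def test_weights_round_trip(tmp_path, model):
    path = tmp_path / "weights.npz"
    model.save(path)
    other = LungStyleCNN(seed=99).load(path)
    x = np.random.default_rng(0).random((2, 32, 32))
    assert np.allclose(model.features(x), other.features(x))
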