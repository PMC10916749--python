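import numpy as np
import pandas as pd
import pytest

from petrad import classify
from petrad.grids import VolumeGrid


def blob_table(rng, n=60, sep=10.0):
    """Two Gaussian blobs separated by ``sep`` SDs in two features."""
    labels = np.repeat([0, 1], n // 2)
    x = rng.normal(0, 1, (n, 2)) + sep * labels[:, None]
    return pd.DataFrame(x, columns=["f0", "f1"]), labels


class TestSplits:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            classify.SplitSpec(fractions=(0.8, 0.1, 0.2))

    def test_shared_test_is_balanced_and_deterministic(self):
        labels = np.array([0] * 40 + [1] * 30)
        a = classify.shared_test_split(labels, n_per_class=10, seed=3)
        b = classify.shared_test_split(labels, n_per_class=10, seed=3)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 20
        assert (labels[a] == 0).sum() == 10 and (labels[a] == 1).sum() == 10

    def test_splits_partition_and_respect_shared_test(self):
        labels = np.array([0] * 50 + [1] * 40)
        test_idx = classify.shared_test_split(labels, 10, seed=1)
        splits = classify.make_splits(labels, classify.SplitSpec(seed=1), test_idx)
        np.testing.assert_array_equal(splits["test"], test_idx)
        union = np.concatenate(list(splits.values()))
        assert len(union) == len(labels) and len(np.unique(union)) == len(labels)

    def test_degenerate_split_rejected(self):
        labels = np.array([0] * 30 + [1])
        with pytest.raises(ValueError):
            classify.make_splits(labels, classify.SplitSpec(seed=0))


class TestZscore:
    def test_sample_sd_closed_form(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        (z,) = classify.zscore_fit_apply(train)
        np.testing.assert_allclose(z["f"], [-1.0, 0.0, 1.0])

    def test_train_parameters_applied_to_test(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"f": [1.0, 2.0, 3.0, 100.0]})
        _, zt = classify.zscore_fit_apply(train, test)
        np.testing.assert_allclose(zt["f"][:3], [-1.0, 0.0, 1.0])
        assert np.isfinite(zt["f"]).all()  # far outlier: finite, unclipped
        assert zt["f"].iloc[3] == pytest.approx(98.0)

    def test_zero_sd_feature_named_in_error(self):
        train = pd.DataFrame({"good": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            classify.zscore_fit_apply(train)


class TestFeatureNN:
    def test_separable_blobs_reach_perfect_accuracy(self, rng):
        table, labels = blob_table(rng)
        splits = classify.make_splits(labels, classify.SplitSpec(seed=0))
        model, scores, metrics = classify.train_feature_nn(
            table, labels, splits, classify.NNConfig(seed=0)
        )
        assert metrics["test_accuracy"] == 1.0
        assert (scores["true_group"] == scores["predicted_group"]).all()

    def test_scores_on_0_100_scale_and_winning_class(self, rng):
        table, labels = blob_table(rng, sep=2.0)
        splits = classify.make_splits(labels, classify.SplitSpec(seed=0))
        _, scores, _ = classify.train_feature_nn(table, labels, splits)
        assert ((scores["score"] >= 50.0) & (scores["score"] <= 100.0)).all()

    def test_deterministic_given_seed(self, rng):
        table, labels = blob_table(rng, sep=1.0)
        splits = classify.make_splits(labels, classify.SplitSpec(seed=4))
        _, s1, m1 = classify.train_feature_nn(table, labels, splits, classify.NNConfig(seed=9))
        _, s2, m2 = classify.train_feature_nn(table, labels, splits, classify.NNConfig(seed=9))
        pd.testing.assert_frame_equal(s1, s2)
        assert m1 == m2

    def test_label_shuffle_near_chance(self, rng):
        """Label-shuffled training cannot beat chance by much on a
        held-out set."""
        table, labels = blob_table(rng, n=200, sep=6.0)
        shuffled = rng.permutation(labels)
        splits = classify.make_splits(shuffled, classify.SplitSpec(seed=2))
        _, _, metrics = classify.train_feature_nn(table, shuffled, splits)
        assert abs(metrics["test_accuracy"] - 0.5) <= 0.35


def toy_volumes(rng, n=24, shape=(8, 8, 8), offset=3.0):
    labels = np.repeat([0, 1], n // 2)
    vols = [
        VolumeGrid(rng.normal(0, 1, shape) + offset * y) for y in labels
    ]
    return vols, labels


class TestCNN:
    def _config(self, shape=(8, 8, 8)):
        return classify.CNNConfig(
            channels=(4, 8), dense_size=16, input_shape=shape, epochs=12,
            batch_size=8, patience=4, seed=0,
        )

    def test_separable_volumes_reach_perfect_accuracy(self, rng):
        vols, labels = toy_volumes(rng)
        splits = classify.make_splits(labels, classify.SplitSpec(seed=0))
        _, scores, metrics = classify.train_cnn_3d(vols, labels, splits, self._config())
        assert metrics["test_accuracy"] == 1.0
        assert ((scores["score"] >= 50.0) & (scores["score"] <= 100.0)).all()

    def test_identical_volumes_stay_at_chance(self, rng):
        base = rng.normal(0, 1, (8, 8, 8))
        vols = [VolumeGrid(base.copy()) for _ in range(24)]
        labels = np.repeat([0, 1], 12)
        splits = classify.make_splits(labels, classify.SplitSpec(seed=0))
        _, _, metrics = classify.train_cnn_3d(vols, labels, splits, self._config())
        assert metrics["val_accuracy"] == pytest.approx(0.5, abs=0.5)

    def test_deterministic_given_seed(self, rng):
        vols, labels = toy_volumes(rng, offset=0.5)
        splits = classify.make_splits(labels, classify.SplitSpec(seed=0))
        cfg = self._config()
        cfg.epochs = 3
        _, s1, _ = classify.train_cnn_3d(vols, labels, splits, cfg)
        _, s2, _ = classify.train_cnn_3d(vols, labels, splits, cfg)
        pd.testing.assert_frame_equal(s1, s2)

    def test_shape_mismatch_rejected(self, rng):
        vols = [VolumeGrid(rng.normal(0, 1, (8, 8, 8))),
                VolumeGrid(rng.normal(0, 1, (6, 8, 8)))]
        with pytest.raises(ValueError, match="mismatch"):
            classify.train_cnn_3d(vols, np.array([0, 1]), {}, self._config())

    def test_resampling_path(self, rng):
        vols, labels = toy_volumes(rng, shape=(10, 12, 9))
        splits = classify.make_splits(labels, classify.SplitSpec(seed=0))
        cfg = self._config(shape=(8, 8, 8))
        cfg.epochs = 2
        _, scores, _ = classify.train_cnn_3d(vols, labels, splits, cfg)
        assert len(scores) == len(splits["test"])
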