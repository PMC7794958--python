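"""Random-forest pixel classification and confusion-matrix metrics."""

import numpy as np
import pytest

from cucurbita.classify import (FRUIT, NON_FRUIT, ConfusionMatrix,
                                LabeledPixelSet, build_training_set,
                                classify_image, confusion_metrics,
                                train_classifier)
from cucurbita.scene import SceneConfig, render_scene


def _pixelset(features, labels):
    n = len(labels)
    return LabeledPixelSet(np.asarray(features, float), np.asarray(labels, np.int8),
                           np.zeros(n, int), np.arange(n))


class TestBuildTrainingSet:
    def test_split_sizes(self, clean_scene):
        split = build_training_set(clean_scene, n_per_class=3000,
                                   n_test_eval=1000, seed=0)
        assert len(split.train) == 3000
        assert len(split.test) == 3000
        assert len(split.evaluation) == 2000
        for part in (split.train, split.test):
            assert (part.labels == FRUIT).sum() == 1500

    def test_evaluation_subset_balanced(self, clean_scene):
        split = build_training_set(clean_scene, n_per_class=3000,
                                   n_test_eval=700, seed=1)
        assert (split.evaluation.labels == FRUIT).sum() == 700
        assert (split.evaluation.labels == NON_FRUIT).sum() == 700

    def test_no_fruit_pixels_is_an_error(self):
        scene = render_scene(SceneConfig(shape=(200, 200), n_fruits=0, seed=0))
        with pytest.raises(ValueError):
            build_training_set(scene, n_per_class=100)

    def test_deterministic_for_seed(self, clean_scene):
        a = build_training_set(clean_scene, n_per_class=500, n_test_eval=100, seed=3)
        b = build_training_set(clean_scene, n_per_class=500, n_test_eval=100, seed=3)
        assert np.array_equal(a.train.features, b.train.features)


class TestTrainClassifier:
    def test_separable_colors_classified_perfectly(self):
        rng = np.random.default_rng(0)
        red = np.column_stack([rng.uniform(200, 255, 200),
                               rng.uniform(0, 40, 200), rng.uniform(0, 40, 200)])
        green = np.column_stack([rng.uniform(0, 40, 200),
                                 rng.uniform(200, 255, 200), rng.uniform(0, 40, 200)])
        train = _pixelset(np.vstack([red[:150], green[:150]]),
                          [FRUIT] * 150 + [NON_FRUIT] * 150)
        model = train_classifier(train, n_trees=50, seed=0)
        probe = np.vstack([red[150:], green[150:]])
        pred = model.forest.predict(probe)
        assert (pred == [FRUIT] * 50 + [NON_FRUIT] * 50).all()

    def test_default_tree_count(self):
        train = _pixelset([[255, 0, 0], [0, 255, 0], [250, 5, 5], [5, 250, 5],
                           [255, 10, 0], [0, 245, 10]],
                          [1, 0, 1, 0, 1, 0])
        model = train_classifier(train, seed=0)
        assert model.n_trees == 500

    def test_single_class_rejected(self):
        train = _pixelset([[1, 2, 3], [4, 5, 6], [7, 8, 9]], [1, 1, 1])
        with pytest.raises(ValueError):
            train_classifier(train)

    def test_deterministic_predictions(self, clean_scene):
        split = build_training_set(clean_scene, n_per_class=400,
                                   n_test_eval=100, seed=0)
        m1 = train_classifier(split.train, n_trees=30, seed=9)
        m2 = train_classifier(split.train, n_trees=30, seed=9)
        probe = split.evaluation.features
        assert np.array_equal(m1.forest.predict(probe), m2.forest.predict(probe))


class TestClassifyImage:
    def test_mask_dimensions_match_raster(self, clean_scene):
        split = build_training_set(clean_scene, n_per_class=600,
                                   n_test_eval=150, seed=0)
        model = train_classifier(split.train, n_trees=40, seed=0)
        mask = classify_image(model, clean_scene)
        assert mask.shape == clean_scene.image.shape[:2]
        assert set(np.unique(mask)) <= {0, 1}

    def test_background_only_image_all_zero(self):
        scene = render_scene(SceneConfig(shape=(250, 250), n_fruits=4, seed=5))
        split = build_training_set(scene, n_per_class=500, n_test_eval=100, seed=0)
        model = train_classifier(split.train, n_trees=40, seed=0)
        background = render_scene(SceneConfig(shape=(150, 150), n_fruits=0, seed=5))
        mask = classify_image(model, background)
        assert mask.mean() < 0.01

    def test_band_mismatch_rejected(self, clean_scene):
        split = build_training_set(clean_scene, n_per_class=200,
                                   n_test_eval=50, seed=0)
        model = train_classifier(split.train, n_trees=10, seed=0)
        with pytest.raises(ValueError):
            classify_image(model, np.zeros((50, 50, 4), np.uint8))

    def test_evaluation_accuracy_on_synthetic_scene(self, hard_scene):
        """Held-out pixel OA on the standard palette should exceed 90%."""
        split = build_training_set(hard_scene, n_per_class=2000,
                                   n_test_eval=1000, seed=0)
        model = train_classifier(split.train, n_trees=100, seed=0)
        mask = classify_image(model, hard_scene)
        pred = mask[split.evaluation.rows, split.evaluation.cols]
        cm = confusion_metrics(pred, split.evaluation.labels)
        assert cm.oa >= 90.0


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        labels = np.array([0, 1, 1, 0, 1])
        cm = confusion_metrics(labels, labels)
        assert cm.oa == 100.0
        assert all(v == 100.0 for v in cm.pa.values())
        assert all(v == 100.0 for v in cm.ua.values())

    def test_hand_computed_counts(self):
        cm = ConfusionMatrix(np.array([[90, 10], [5, 95]]))
        first = cm.classes[0]
        assert cm.oa == pytest.approx(92.5)
        assert cm.pa[first] == pytest.approx(90.0)
        assert cm.ua[first] == pytest.approx(100 * 90 / 95)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([0, 1], [0, 1, 1])

    def test_row_sums_equal_truth_counts_and_oa_bounds(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 500)
        pred = np.where(rng.random(500) < 0.8, truth, 1 - truth)
        cm = confusion_metrics(pred, truth)
        assert cm.counts.sum(axis=1)[0] == (truth == 0).sum()
        assert cm.counts.sum(axis=1)[1] == (truth == 1).sum()
        pa = list(cm.pa.values())
        assert min(pa) - 1e-9 <= cm.oa <= max(pa) + 1e-9

    def test_class_swap_transposes_matrix(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 2, 300)
        pred = np.where(rng.random(300) < 0.7, truth, 1 - truth)
        cm = confusion_metrics(pred, truth)
        sw = confusion_metrics(1 - pred, 1 - truth)
        assert np.array_equal(sw.counts, cm.counts[::-1, ::-1])
        assert sw.pa[0] == pytest.approx(cm.pa[1])
        assert sw.ua[0] == pytest.approx(cm.ua[1])
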