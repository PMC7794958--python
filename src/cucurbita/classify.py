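"""Random-forest pixel classification of fruit vs. non-fruit.

Pixels are described by their raw R, G, B values and classified by a
random forest (default 500 trees, Gini impurity, majority vote over
trees).  Training samples are drawn from a scene's truth mask — the
synthetic stand-in for manually digitized pixel polygons — or read from
labeled GeoJSON polygons for real imagery.  Map accuracy is summarized
by the remote-sensing confusion-matrix conventions: overall accuracy
(OA), producer's accuracy (PA, per-class recall) and user's accuracy
(UA, per-class precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .raster import RasterTransform
from .scene import Scene

__all__ = [
    "LabeledPixelSet",
    "PixelSplit",
    "FruitPixelModel",
    "ConfusionMatrix",
    "build_training_set",
    "train_classifier",
    "classify_image",
    "confusion_metrics",
    "read_label_polygons",
]

FRUIT, NON_FRUIT = 1, 0


@dataclass
class LabeledPixelSet:
    """Per-pixel RGB features with binary labels and pixel provenance."""

    features: np.ndarray      # (n, bands) float
    labels: np.ndarray        # (n,) in {0, 1}
    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self):
        n = len(self.features)
        if not (len(self.labels) == len(self.rows) == len(self.cols) == n):
            raise ValueError("features, labels and provenance must be same length")
        if not np.isin(self.labels, (FRUIT, NON_FRUIT)).all():
            raise ValueError("labels must be binary (0 = non-fruit, 1 = fruit)")

    def __len__(self) -> int:
        return len(self.labels)

    def take(self, idx: np.ndarray) -> "LabeledPixelSet":
        return LabeledPixelSet(self.features[idx], self.labels[idx],
                               self.rows[idx], self.cols[idx])


@dataclass
class PixelSplit:
    """Train/test split plus the fixed-size evaluation subset of the test set."""

    train: LabeledPixelSet
    test: LabeledPixelSet
    evaluation: LabeledPixelSet


@dataclass
class FruitPixelModel:
    """A fitted per-pixel fruit classifier."""

    forest: RandomForestClassifier
    n_bands: int

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators


def _sample_class(rng, rows, cols, n):
    if len(rows) < n:
        raise ValueError(
            f"class has only {len(rows)} labeled pixels, need {n}")
    idx = rng.choice(len(rows), size=n, replace=False)
    return rows[idx], cols[idx]


def build_training_set(
    scene: Scene,
    n_per_class: int = 4000,
    test_fraction: float = 0.5,
    n_test_eval: int = 1000,
    seed: int = 0,
) -> PixelSplit:
    """Sample labeled pixels from a scene and split them for training.

    Per class, ``n_per_class`` pixels are sampled without replacement
    from the truth labeling (fruit pixels from the *visible* fruit area,
    mirroring what an analyst digitizing the orthophoto would label),
    split into train/test halves, and an evaluation subset of
    ``n_test_eval`` pixels per class is drawn from the test half.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    fruit_mask = scene.visible_mask
    bg_mask = ~scene.label_mask

    parts = {"features": [], "labels": [], "rows": [], "cols": []}
    for mask, lab in ((fruit_mask, FRUIT), (bg_mask, NON_FRUIT)):
        rows, cols = np.nonzero(mask)
        if len(rows) == 0:
            raise ValueError("scene has no pixels of class "
                             + ("fruit" if lab == FRUIT else "non-fruit"))
        r, c = _sample_class(rng, rows, cols, n_per_class)
        parts["features"].append(scene.image[r, c].astype(float))
        parts["labels"].append(np.full(n_per_class, lab, dtype=np.int8))
        parts["rows"].append(r)
        parts["cols"].append(c)

    full = LabeledPixelSet(
        np.concatenate(parts["features"]),
        np.concatenate(parts["labels"]),
        np.concatenate(parts["rows"]),
        np.concatenate(parts["cols"]),
    )

    train_idx, test_idx = [], []
    for lab in (FRUIT, NON_FRUIT):
        cls = np.flatnonzero(full.labels == lab)
        cls = rng.permutation(cls)
        n_test = int(round(len(cls) * test_fraction))
        test_idx.append(cls[:n_test])
        train_idx.append(cls[n_test:])
    train = full.take(np.concatenate(train_idx))
    test = full.take(np.concatenate(test_idx))

    eval_idx = []
    for lab in (FRUIT, NON_FRUIT):
        cls = np.flatnonzero(test.labels == lab)
        if len(cls) < n_test_eval:
            raise ValueError(
                f"test set has {len(cls)} pixels of class {lab}, "
                f"need {n_test_eval} for evaluation")
        eval_idx.append(rng.choice(cls, size=n_test_eval, replace=False))
    evaluation = test.take(np.concatenate(eval_idx))
    return PixelSplit(train=train, test=test, evaluation=evaluation)


def train_classifier(train: LabeledPixelSet, n_trees: int = 500,
                     seed: int = 0) -> FruitPixelModel:
    """Fit the random forest (Gini splits, bagging, sqrt feature draw)."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train.features, train.labels)
    return FruitPixelModel(forest=forest, n_bands=train.features.shape[1])


def classify_image(model: FruitPixelModel, scene: Scene | np.ndarray) -> np.ndarray:
    """Classify every pixel of a scene; returns a binary fruit mask.

    RGB images are 8-bit, so the number of distinct colors is far below
    the number of pixels; prediction runs once per unique color and is
    broadcast back, which keeps full-orthomosaic classification cheap.
    """
    image = scene.image if isinstance(scene, Scene) else scene
    if image.ndim != 3 or image.shape[2] != model.n_bands:
        raise ValueError(
            f"raster has {image.shape[2] if image.ndim == 3 else 1} bands, "
            f"model expects {model.n_bands}")
    flat = image.reshape(-1, model.n_bands)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    pred = model.forest.predict(uniq.astype(float)).astype(np.uint8)
    return pred[inverse].reshape(image.shape[:2])


@dataclass
class ConfusionMatrix:
    """2x2 confusion counts (rows = truth, cols = prediction) and the
    derived OA/PA/UA percentages."""

    counts: np.ndarray
    classes: tuple[int, int] = (NON_FRUIT, FRUIT)
    oa: float = field(init=False)
    pa: dict = field(init=False)
    ua: dict = field(init=False)

    def __post_init__(self):
        m = np.asarray(self.counts, dtype=np.int64)
        if m.shape != (2, 2) or (m < 0).any():
            raise ValueError("counts must be a 2x2 non-negative matrix")
        self.counts = m
        total = m.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        self.oa = 100.0 * np.trace(m) / total
        row = m.sum(axis=1)
        col = m.sum(axis=0)
        self.pa = {c: (100.0 * m[i, i] / row[i] if row[i] else float("nan"))
                   for i, c in enumerate(self.classes)}
        self.ua = {c: (100.0 * m[i, i] / col[i] if col[i] else float("nan"))
                   for i, c in enumerate(self.classes)}


def confusion_metrics(pred, truth) -> ConfusionMatrix:
    """Confusion matrix of binary predictions against truth labels."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if len(pred) == 0:
        raise ValueError("empty inputs")
    counts = np.zeros((2, 2), np.int64)
    for i, t in enumerate((NON_FRUIT, FRUIT)):
        for j, p in enumerate((NON_FRUIT, FRUIT)):
            counts[i, j] = np.sum((truth == t) & (pred == p))
    if counts.sum() != len(pred):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionMatrix(counts)


def read_label_polygons(path: str, image: np.ndarray,
                        transform: RasterTransform,
                        class_property: str = "label") -> LabeledPixelSet:
    """Rasterize labeled GeoJSON polygons into a LabeledPixelSet.

    Each feature must carry ``class_property`` with value ``fruit`` or
    ``non-fruit`` (or 1/0) and a Polygon geometry in world coordinates.
    """
    from skimage.draw import polygon as draw_polygon

    with open(path) as fh:
        doc = json.load(fh)
    feats, labels, rows, cols = [], [], [], []
    for feature in doc.get("features", []):
        geom = feature["geometry"]
        if geom["type"] != "Polygon":
            continue
        value = feature["properties"][class_property]
        lab = FRUIT if value in (1, "1", "fruit") else NON_FRUIT
        ring = np.asarray(geom["coordinates"][0], float)
        rr, cc = transform.world_to_pixel(ring[:, 0], ring[:, 1])
        prr, pcc = draw_polygon(rr, cc, shape=image.shape[:2])
        feats.append(image[prr, pcc].astype(float))
        labels.append(np.full(len(prr), lab, np.int8))
        rows.append(prr)
        cols.append(pcc)
    if not feats:
        raise ValueError(f"no polygon features found in {path}")
    return LabeledPixelSet(np.concatenate(feats), np.concatenate(labels),
                           np.concatenate(rows), np.concatenate(cols))
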