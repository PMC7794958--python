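"""Evaluation of detections against surveyed ground truth.

Detections are paired with ground-truth fruits by greedy one-to-one
nearest-neighbor matching within a radius (default 0.5 m, generous
relative to fruit size but tight against neighbor confusion at typical
planting densities).  A precision audit re-creates the manual check of
randomly drawn detections: a detection counts as a true positive when
its center falls on a real fruit footprint.  Paired Pearson
correlations with explicit outlier exclusion compare observed and
estimated per-fruit quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .quantify import FruitRecord
from .raster import RasterTransform
from .scene import GroundTruthFruit

__all__ = ["MatchResult", "match_detections", "precision_audit",
           "paired_correlation"]


@dataclass
class MatchResult:
    """One-to-one truth/detection matching within a radius."""

    pairs: list[tuple[int, int, float]]     # (truth id, detection id, distance m)
    unmatched_truth: list[int]
    unmatched_detections: list[int]
    radius_m: float

    @property
    def detection_rate(self) -> float:
        total = len(self.pairs) + len(self.unmatched_truth)
        return len(self.pairs) / total if total else float("nan")


def match_detections(truth: list[GroundTruthFruit],
                     detections: list[FruitRecord],
                     radius_m: float = 0.5) -> MatchResult:
    """Greedy nearest-first one-to-one matching within ``radius_m``."""
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if not truth or not detections:
        return MatchResult([], [f.id for f in truth],
                           [d.id for d in detections], radius_m)
    t_xy = np.array([[f.x, f.y] for f in truth])
    d_xy = np.array([[d.x, d.y] for d in detections])
    dist = cdist(t_xy, d_xy)
    ti, di = np.nonzero(dist <= radius_m)
    order = np.argsort(dist[ti, di], kind="stable")
    used_t, used_d = set(), set()
    pairs = []
    for k in order:
        i, j = int(ti[k]), int(di[k])
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        pairs.append((truth[i].id, detections[j].id, float(dist[i, j])))
    unmatched_truth = [f.id for i, f in enumerate(truth) if i not in used_t]
    unmatched_det = [d.id for j, d in enumerate(detections) if j not in used_d]
    return MatchResult(pairs, unmatched_truth, unmatched_det, radius_m)


def precision_audit(detections: list[FruitRecord],
                    truth,
                    n_sample: int = 200,
                    seed: int = 0,
                    transform: RasterTransform | None = None) -> float:
    """Fraction of randomly audited detections that are real fruits.

    ``truth`` is either a per-pixel truth label mask (then ``transform``
    maps detection world positions to pixels) or a list of
    GroundTruthFruit (then a detection passes when its center lies
    within the truth fruit's semi-diameter).
    """
    if not detections:
        raise ValueError("no detections to audit")
    rng = np.random.default_rng(seed)
    n = min(n_sample, len(detections))
    picked = rng.choice(len(detections), size=n, replace=False)
    sample = [detections[i] for i in picked]

    if isinstance(truth, np.ndarray):
        transform = transform or RasterTransform()
        hits = 0
        for det in sample:
            r, c = transform.world_to_pixel(det.x, det.y)
            if 0 <= r < truth.shape[0] and 0 <= c < truth.shape[1] and truth[r, c]:
                hits += 1
        return hits / n
    t_xy = np.array([[f.x, f.y] for f in truth])
    radii = np.array([f.diameter_cm / 200.0 for f in truth])  # semi-diameter, m
    hits = 0
    for det in sample:
        d = np.hypot(t_xy[:, 0] - det.x, t_xy[:, 1] - det.y)
        if (d <= radii).any():
            hits += 1
    return hits / n


def paired_correlation(observed, estimated, exclude_ids=(), ids=None) -> float:
    """Pearson r of paired values after dropping excluded ids.

    ``ids`` defaults to positional indices (0-based); the exclusion list
    mirrors the removal of known-bad pairs (e.g. occlusion or
    mosaicking artifacts) before correlating.
    """
    observed = np.asarray(observed, float)
    estimated = np.asarray(estimated, float)
    if observed.shape != estimated.shape:
        raise ValueError("observed and estimated must have equal length")
    ids = np.arange(len(observed)) if ids is None else np.asarray(ids)
    keep = ~np.isin(ids, list(exclude_ids))
    if keep.sum() < 3:
        raise ValueError("need at least 3 pairs after exclusions")
    return float(stats.pearsonr(observed[keep], estimated[keep]).statistic)
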