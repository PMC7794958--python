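"""Fruit dimensions, spheroid volumes, weights and retail classes.

A Hokkaido pumpkin is modeled as an oblate spheroid: round in plan
view, flattened in height.  From the fitted image ellipse, the longer
axis (times the GSD) is taken as the fruit diameter and the shorter
axis as its height, giving the volume

    V = (4 pi / 3) * (d / 2)^2 * (h / 2)     [cm^3]

Weight is predicted from volume by an empirical linear regression
calibrated on harvested, weighed fruits, and each fruit is then binned
into the retail weight classes <0.5, 0.5-0.8, 0.8-1.0, 1.0-1.5 and
>=1.5 kg; fruits under 500 g are non-marketable (forage).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import EllipseFit
from .raster import RasterTransform

__all__ = [
    "WEIGHT_CLASSES",
    "FruitRecord",
    "WeightModel",
    "ellipse_dimensions",
    "spheroid_volume",
    "fit_weight_model",
    "predict_weight",
    "assign_weight_class",
    "class_summary",
    "summarize_class_counts",
    "records_from_detections",
]

#: Retail weight classes in kg; lower edges in g, lower-inclusive bins.
WEIGHT_CLASSES = ("<0.5", "0.5-0.8", "0.8-1.0", "1.0-1.5", ">=1.5")
_CLASS_EDGES_G = (0.0, 500.0, 800.0, 1000.0, 1500.0, math.inf)


@dataclass
class FruitRecord:
    """One detected fruit with derived physical quantities."""

    id: int
    x: float
    y: float
    diameter_cm: float
    height_cm: float
    volume_cm3: float
    weight_g: float
    weight_class: str
    marketable: bool


@dataclass(frozen=True)
class WeightModel:
    """Linear volume-to-weight calibration."""

    slope: float          # g per cm^3
    intercept: float      # g
    r_squared: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("calibration needs at least 3 fruits")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def ellipse_dimensions(fit: EllipseFit, gsd_cm: float = 1.0) -> tuple[float, float]:
    """Diameter and height in cm from an ellipse fit.

    The longer ellipse axis is the fruit diameter, the shorter its
    height; the ellipse orientation plays no role.
    """
    if gsd_cm <= 0:
        raise ValueError("gsd must be positive")
    return fit.major_px * gsd_cm, fit.minor_px * gsd_cm


def spheroid_volume(diameter_cm: float, height_cm: float) -> float:
    """Oblate-spheroid volume (cm^3) from diameter and height (cm)."""
    if diameter_cm <= 0 or height_cm <= 0:
        raise ValueError("dimensions must be positive")
    if height_cm > diameter_cm:
        warnings.warn(
            "height exceeds diameter (vertically growing fruit?); "
            "the top view cannot observe the true height",
            stacklevel=2)
    a = diameter_cm / 2.0
    c = height_cm / 2.0
    return (4.0 * math.pi / 3.0) * a * a * c


def fit_weight_model(volumes_cm3, weights_g, through_origin: bool = False) -> WeightModel:
    """Ordinary least-squares weight ~ volume calibration.

    With ``through_origin`` the intercept is forced to zero and r^2 is
    still reported about the mean (so it remains comparable).
    """
    v = np.asarray(volumes_cm3, float)
    w = np.asarray(weights_g, float)
    if v.shape != w.shape:
        raise ValueError("volumes and weights must have equal length")
    if len(v) < 3:
        raise ValueError("need at least 3 calibration fruits")
    if np.ptp(v) == 0:
        raise ValueError("volumes have zero variance")
    if through_origin:
        slope = float(v @ w / (v @ v))
        intercept = 0.0
        resid = w - slope * v
        ss_tot = float(((w - w.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot else 0.0
    else:
        res = stats.linregress(v, w)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue ** 2)
    return WeightModel(slope=slope, intercept=intercept,
                       r_squared=max(min(r2, 1.0), 0.0), n=len(v))


def predict_weight(model: WeightModel, volume_cm3: float) -> float:
    """Predicted fruit weight in g, floored at 0."""
    return max(model.slope * volume_cm3 + model.intercept, 0.0)


def assign_weight_class(weight_g: float) -> str:
    """Retail class of a fruit weight (lower-inclusive bin edges)."""
    if weight_g < 0:
        raise ValueError("weight must be >= 0")
    for label, lo, hi in zip(WEIGHT_CLASSES, _CLASS_EDGES_G, _CLASS_EDGES_G[1:]):
        if lo <= weight_g < hi:
            return label
    return WEIGHT_CLASSES[-1]


def is_marketable(weight_g: float) -> bool:
    return weight_g >= 500.0


def summarize_class_counts(counts) -> pd.DataFrame:
    """Class table from raw per-class counts (ordered as WEIGHT_CLASSES).

    Percentages are rounded half-even to one decimal; the marketable
    share is 100 * (total - count of "<0.5") / total.
    """
    counts = np.asarray(counts, int)
    if counts.shape != (len(WEIGHT_CLASSES),):
        raise ValueError(f"need {len(WEIGHT_CLASSES)} class counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("no fruits to summarize")
    percent = np.round(100.0 * counts / total, 1)
    table = pd.DataFrame({
        "weight_class": WEIGHT_CLASSES,
        "count": counts,
        "percent": percent,
    })
    table.attrs["total"] = int(total)
    table.attrs["marketable_share"] = float(
        round(100.0 * (total - counts[0]) / total, 1))
    return table


def class_summary(records: list[FruitRecord]) -> pd.DataFrame:
    """Per-class counts/percentages and the marketable share for records."""
    if not records:
        raise ValueError("no records to summarize")
    counts = np.zeros(len(WEIGHT_CLASSES), int)
    index = {label: i for i, label in enumerate(WEIGHT_CLASSES)}
    for rec in records:
        counts[index[rec.weight_class]] += 1
    return summarize_class_counts(counts)


def records_from_detections(
    detections,
    model: WeightModel,
    transform: RasterTransform = RasterTransform(),
) -> list[FruitRecord]:
    """Turn (SegmentedObject, EllipseFit) detections into FruitRecords."""
    records = []
    gsd = transform.gsd_cm
    for i, (_, fit) in enumerate(detections, start=1):
        d, h = ellipse_dimensions(fit, gsd)
        volume = spheroid_volume(d, h)
        weight = predict_weight(model, volume)
        x, y = transform.pixel_to_world(fit.center_row, fit.center_col)
        records.append(FruitRecord(
            id=i, x=float(x), y=float(y),
            diameter_cm=d, height_cm=h, volume_cm3=volume,
            weight_g=weight, weight_class=assign_weight_class(weight),
            marketable=is_marketable(weight),
        ))
    return records


def records_to_frame(records: list[FruitRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
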