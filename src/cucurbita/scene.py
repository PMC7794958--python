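"""Synthetic orthomosaic scenes with exact ground truth.

The study system is a Hokkaido pumpkin (*Cucurbita maxima*) field imaged
from a UAV at ~1 cm ground sampling distance: reddish-orange oval fruits
lying between green canopy and brown soil, half of the field in direct
sun (light fruits with overexposed bright spots) and half in shade
(evenly saturated red fruits, everything darker), some fruits partly
hidden under leaves, and some pairs of fruits touching.  This module
renders small scenes with those properties and records per-fruit ground
truth (position, diameter, height, optional weight, visible fraction),
so every downstream stage — pixel classification, morphology, object
splitting, quantification, evaluation — can be tested against a known
answer.

Fruit sizes are drawn from truncated normal distributions whose defaults
match the field survey statistics this package is calibrated against
(diameter 13.8 +/- 3.0 cm in [6, 21]; height 12.4 +/- 2.6 cm in
[6.5, 19]).  The two dimensions are allometrically coupled through a
Gaussian copula while keeping those marginals exact; a small share of
fruits still comes out taller than wide, as vertically growing fruits
do in real fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .raster import RasterTransform

__all__ = [
    "SizeDistribution",
    "SceneConfig",
    "GroundTruthFruit",
    "Scene",
    "sample_fruit_population",
    "render_scene",
    "assign_weights",
    "TABLE_DIAMETER",
    "TABLE_HEIGHT",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated-normal spec for one fruit dimension, in cm."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not self.minimum <= self.mean <= self.maximum:
            raise ValueError("require minimum <= mean <= maximum")

    def _bounds(self):
        return ((self.minimum - self.mean) / self.sd,
                (self.maximum - self.mean) / self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a, b = self._bounds()
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                             random_state=rng)

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF transform of uniforms (copula sampling)."""
        a, b = self._bounds()
        return truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


#: Field-survey fruit size statistics used as generator defaults.
TABLE_DIAMETER = SizeDistribution(mean=13.8, sd=3.0, minimum=6.0, maximum=21.0)
TABLE_HEIGHT = SizeDistribution(mean=12.4, sd=2.6, minimum=6.5, maximum=19.0)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a rendered synthetic scene.

    ``fraction_touching`` is the share of fruits that belong to a tangent
    pair (so ``n_fruits * fraction_touching / 2`` pairs are placed);
    ``fraction_occluded`` is the share with a leaf polygon painted over
    part of the fruit.  With ``illumination_split`` the left half of the
    field is shaded (all channels dimmed) and fruits on the right half
    carry a near-white overexposure disc.
    """

    shape: tuple[int, int] = (600, 600)
    gsd_cm: float = 1.0
    n_fruits: int = 50
    diameter: SizeDistribution = TABLE_DIAMETER
    height: SizeDistribution = TABLE_HEIGHT
    size_correlation: float = 0.85
    fraction_touching: float = 0.0
    fraction_occluded: float = 0.0
    occlusion_cover: float = 0.35
    illumination_split: bool = False
    min_spacing_px: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_fruits < 0:
            raise ValueError("n_fruits must be >= 0")
        if self.gsd_cm <= 0:
            raise ValueError("gsd must be positive")
        for name in ("fraction_touching", "fraction_occluded", "occlusion_cover"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruthFruit:
    """One surveyed fruit: world position, dimensions, optional weight."""

    id: int
    x: float                 # m
    y: float                 # m
    diameter_cm: float
    height_cm: float
    weight_g: float | None = None
    visible_fraction: float = 1.0
    orientation_deg: float = 0.0


@dataclass
class Scene:
    """A rendered scene: RGB raster, transform, truth list and masks.

    ``label_mask`` marks the *full* extent of every fruit, including
    pixels later overpainted by occluding leaves; ``visible_mask`` marks
    only fruit pixels that actually look like fruit in the RGB image.
    ``instance_map`` holds the 1-based truth fruit id per pixel (0 =
    background).
    """

    image: np.ndarray
    transform: RasterTransform
    fruits: list[GroundTruthFruit]
    label_mask: np.ndarray
    visible_mask: np.ndarray
    instance_map: np.ndarray
    config: SceneConfig | None = None

    def __post_init__(self):
        if self.label_mask.shape != self.image.shape[:2]:
            raise ValueError("label mask dimensions must equal raster dimensions")


class PlacementError(RuntimeError):
    """Raised when fruits cannot be placed within the retry budget."""


def sample_fruit_population(
    n: int,
    diameter: SizeDistribution = TABLE_DIAMETER,
    height: SizeDistribution = TABLE_HEIGHT,
    seed: int = 0,
    correlation: float = 0.85,
) -> list[GroundTruthFruit]:
    """Draw ``n`` fruits with truncated-normal diameter and height.

    The two dimensions follow their truncated-normal marginals exactly
    and are coupled through a Gaussian copula with the given rank-scale
    ``correlation`` (default 0.85): fruit size is strongly allometric,
    so a large-diameter fruit is almost always also tall, while a small
    share of fruits still comes out taller than wide, as vertically
    growing fruits do.  ``correlation=0`` gives independent draws.
    Positions are left at the origin; :func:`render_scene` places
    fruits in the raster.  Deterministic for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not -1.0 < correlation < 1.0:
        raise ValueError("correlation must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = correlation * z1 + math.sqrt(1.0 - correlation**2) * rng.standard_normal(n)
    from scipy.stats import norm

    d = diameter.from_uniform(norm.cdf(z1))
    h = height.from_uniform(norm.cdf(z2))
    theta = rng.uniform(0.0, 180.0, size=n)
    return [
        GroundTruthFruit(id=i + 1, x=0.0, y=0.0, diameter_cm=float(d[i]),
                         height_cm=float(h[i]), orientation_deg=float(theta[i]))
        for i in range(n)
    ]


def _spheroid_volume(diameter_cm: float, height_cm: float) -> float:
    # local copy to avoid a circular import with quantify
    a = diameter_cm / 2.0
    c = height_cm / 2.0
    return (4.0 * math.pi / 3.0) * a * a * c


def assign_weights(
    fruits: list[GroundTruthFruit],
    slope: float = 0.96,
    intercept: float = 0.0,
    noise_sd: float = 35.0,
    seed: int = 0,
) -> list[GroundTruthFruit]:
    """Attach weights via a linear volume-weight law plus Gaussian noise.

    weight = slope * V_spheroid(d, h) + intercept + N(0, noise_sd),
    floored at 1 g.  The default slope (0.96 g/cm^3, no intercept) makes
    a mean-sized fruit (13.8 x 12.4 cm, ~1236 cm^3) weigh ~1187 g,
    matching the surveyed mean weight; the noise default is ~3% of that.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(fruits)) if noise_sd > 0 else np.zeros(len(fruits))
    out = []
    for fruit, eps in zip(fruits, noise):
        w = slope * _spheroid_volume(fruit.diameter_cm, fruit.height_cm) + intercept + eps
        out.append(replace_weight(fruit, max(w, 1.0)))
    return out


def replace_weight(fruit: GroundTruthFruit, weight_g: float) -> GroundTruthFruit:
    return replace(fruit, weight_g=float(weight_g))


# ---------------------------------------------------------------------------
# rendering


def _ellipse_pixels(shape, row_c, col_c, semi_major_px, semi_minor_px, theta_deg):
    """Pixel indices inside a rotated ellipse, clipped to the raster."""
    rmax = max(semi_major_px, semi_minor_px)
    r0 = max(int(row_c - rmax - 2), 0)
    r1 = min(int(row_c + rmax + 3), shape[0])
    c0 = max(int(col_c - rmax - 2), 0)
    c1 = min(int(col_c + rmax + 3), shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    th = math.radians(theta_deg)
    x = cols - col_c
    y = rows - row_c
    xp = x * math.cos(th) + y * math.sin(th)
    yp = -x * math.sin(th) + y * math.cos(th)
    inside = (xp / semi_major_px) ** 2 + (yp / semi_minor_px) ** 2 <= 1.0
    return rows[inside], cols[inside]


def _fruit_semiaxes_px(fruit: GroundTruthFruit, gsd_cm: float):
    return fruit.diameter_cm / (2 * gsd_cm), fruit.height_cm / (2 * gsd_cm)


def _mottled_background(shape, rng):
    """Soil/canopy mottle: smooth random field thresholded into patches."""
    rows, cols = shape
    coarse = rng.normal(size=(max(rows // 24, 2), max(cols // 24, 2)))
    fy = -(-rows // coarse.shape[0])
    fx = -(-cols // coarse.shape[1])
    fieldmap = np.repeat(np.repeat(coarse, fy, axis=0), fx, axis=1)[:rows, :cols]
    fieldmap = ndimage.gaussian_filter(fieldmap, sigma=8.0)
    canopy = fieldmap > 0.02
    img = np.empty((rows, cols, 3), np.float32)
    img[...] = (128.0, 100.0, 72.0)          # soil brown
    img[canopy] = (62.0, 112.0, 48.0)        # canopy green
    img += rng.normal(0.0, 9.0, size=img.shape)
    return img


def _leaf_polygon_pixels(shape, row_c, col_c, radius_px, rng):
    """A rough leaf: irregular polygon around (row_c, col_c)."""
    n_vert = 7
    angles = np.sort(rng.uniform(0, 2 * math.pi, n_vert))
    radii = radius_px * rng.uniform(0.7, 1.3, n_vert)
    rr = row_c + radii * np.sin(angles)
    cc = col_c + radii * np.cos(angles)
    from skimage.draw import polygon

    prr, pcc = polygon(rr, cc, shape=shape)
    return prr, pcc


def _place_positions(cfg: SceneConfig, fruits, rng):
    """Rejection-sample fruit centres; tangent pairs placed together.

    Returns per-fruit (row, col) centres.  Non-touching fruits keep a
    boundary gap of at least ``cfg.min_spacing_px``; each touching pair
    is placed tangent along a random direction (adjacency is enforced at
    raster level by the caller nudging the second fruit).
    """
    n = len(fruits)
    shape = cfg.shape
    budget = 100 * max(n, 1)
    n_pairs = int(round(n * cfg.fraction_touching / 2.0))
    pair_partner = {}           # index of first member -> index of second
    for k in range(n_pairs):
        pair_partner[2 * k] = 2 * k + 1

    semi = [_fruit_semiaxes_px(f, cfg.gsd_cm) for f in fruits]
    rmax = [s[0] for s in semi]  # semi-major in px
    centers = np.full((n, 2), np.nan)

    def conflicts(i, r, c):
        for j in range(n):
            if j == i or math.isnan(centers[j, 0]):
                continue
            if pair_partner.get(i) == j or pair_partner.get(j) == i:
                continue
            d = math.hypot(r - centers[j, 0], c - centers[j, 1])
            if d < rmax[i] + rmax[j] + cfg.min_spacing_px:
                return True
        return False

    attempts = 0
    i = 0
    while i < n:
        if attempts > budget:
            raise PlacementError(
                f"could not place {n} fruits in a {shape} raster "
                f"within {budget} attempts; enlarge the scene")
        attempts += 1
        margin = rmax[i] + 2
        if shape[0] <= 2 * margin or shape[1] <= 2 * margin:
            raise PlacementError("raster too small for fruit size")
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if conflicts(i, r, c):
            continue
        if i in pair_partner:
            j = pair_partner[i]
            ok = False
            for _ in range(20):
                phi = rng.uniform(0, 2 * math.pi)
                dist = rmax[i] + rmax[j]     # tangent along phi, refined later
                rj = r + dist * math.sin(phi)
                cj = c + dist * math.cos(phi)
                mj = rmax[j] + 2
                if not (mj <= rj < shape[0] - mj and mj <= cj < shape[1] - mj):
                    continue
                if not conflicts(j, rj, cj):
                    centers[j] = (rj, cj)
                    ok = True
                    break
            if not ok:
                continue
            centers[i] = (r, c)
            i += 1
            while i < n and not math.isnan(centers[i, 0]):
                i += 1
        else:
            centers[i] = (r, c)
            i += 1
            while i < n and not math.isnan(centers[i, 0]):
                i += 1
    return centers, pair_partner


def _rasterize_fruit(cfg, fruit, row_c, col_c):
    a_px, c_px = _fruit_semiaxes_px(fruit, cfg.gsd_cm)
    return _ellipse_pixels(cfg.shape, row_c, col_c, a_px, c_px,
                           fruit.orientation_deg)


def _nudge_tangent(cfg, fruits, centers, i, j):
    """Pull fruit j toward fruit i until their rasters are 8-adjacent."""
    ri, ci = _rasterize_fruit(cfg, fruits[i], *centers[i])
    base = np.zeros(cfg.shape, bool)
    base[ri, ci] = True
    grown = ndimage.binary_dilation(base, np.ones((3, 3), bool))
    vec = centers[i] - centers[j]
    dist = np.hypot(*vec)
    if dist == 0:
        return
    step = vec / dist
    pos = centers[j].copy()
    for _ in range(int(dist) + 2):
        nxt = pos + step
        rj, cj = _rasterize_fruit(cfg, fruits[j], *nxt)
        if not len(rj) or base[rj, cj].any():
            break                # next step would overlap: stay adjacent
        pos = nxt
        if grown[rj, cj].any():
            break                # rasters are now 8-adjacent
    centers[j] = pos


def render_scene(config: SceneConfig) -> Scene:
    """Render a scene from its config; bit-identical for equal configs."""
    rng = np.random.default_rng(config.seed)
    fruits = sample_fruit_population(
        config.n_fruits, config.diameter, config.height,
        seed=int(rng.integers(2**31)), correlation=config.size_correlation)
    img = _mottled_background(config.shape, rng)
    label = np.zeros(config.shape, bool)
    visible = np.zeros(config.shape, bool)
    instance = np.zeros(config.shape, np.int32)

    centers, pair_partner = _place_positions(config, fruits, rng)
    for i, j in pair_partner.items():
        _nudge_tangent(config, fruits, centers, i, j)

    transform = RasterTransform(gsd_cm=config.gsd_cm)
    split_col = config.shape[1] / 2.0

    n = len(fruits)
    occluded = set(
        rng.choice(n, size=int(round(n * config.fraction_occluded)),
                   replace=False)) if n else set()

    fruit_pixels = []
    for i, fruit in enumerate(fruits):
        rr, cc = _rasterize_fruit(config, fruit, *centers[i])
        fruit_pixels.append((rr, cc))
        label[rr, cc] = True
        instance[rr, cc] = fruit.id
        base = np.array([226.0, 88.0, 30.0])          # orange-red
        jitter = rng.uniform(0.9, 1.1, size=3)        # +/-10% channel jitter
        color = base * jitter
        illuminated = config.illumination_split and centers[i][1] >= split_col
        if illuminated:
            # very light reddish appearance in direct sun
            color = color + (np.array([255.0, 210.0, 180.0]) - color) * 0.45
        img[rr, cc] = color + rng.normal(0, 5.0, size=(len(rr), 3))
        if illuminated and len(rr):
            a_px, c_px = _fruit_semiaxes_px(fruit, config.gsd_cm)
            spot_r = 0.35 * c_px
            off = rng.uniform(-0.3, 0.3, size=2) * c_px
            srr, scc = _ellipse_pixels(config.shape, centers[i][0] + off[0],
                                       centers[i][1] + off[1], spot_r, spot_r, 0.0)
            keep = instance[srr, scc] == fruit.id
            img[srr[keep], scc[keep]] = (252.0, 250.0, 244.0)

    # occluding leaves: overpainted in the RGB only; the label mask keeps
    # the full fruit extent so evaluation can stratify by visible_fraction
    visible[:] = label
    for i in occluded:
        fruit = fruits[i]
        rr, cc = fruit_pixels[i]
        if not len(rr):
            continue
        a_px, _ = _fruit_semiaxes_px(fruit, config.gsd_cm)
        edge = rng.uniform(0, 2 * math.pi)
        leaf_r = a_px * (0.6 + 0.8 * config.occlusion_cover)
        lrow = centers[i][0] + 0.9 * a_px * math.sin(edge)
        lcol = centers[i][1] + 0.9 * a_px * math.cos(edge)
        lrr, lcc = _leaf_polygon_pixels(config.shape, lrow, lcol, leaf_r, rng)
        img[lrr, lcc] = np.array([58.0, 118.0, 46.0]) + rng.normal(
            0, 6.0, size=(len(lrr), 3))
        visible[lrr, lcc] = False

    for i, fruit in enumerate(fruits):
        rr, cc = fruit_pixels[i]
        total = len(rr)
        fruits[i] = replace(
            fruit,
            x=float(transform.pixel_to_world(centers[i][0], centers[i][1])[0]),
            y=float(transform.pixel_to_world(centers[i][0], centers[i][1])[1]),
            visible_fraction=float(visible[rr, cc].sum() / total) if total else 0.0,
        )

    if config.illumination_split:
        img[:, : int(split_col)] *= 0.6               # shaded half

    img = np.clip(img, 0, 255).astype(np.uint8)
    return Scene(image=img, transform=transform, fruits=fruits,
                 label_mask=label, visible_mask=visible,
                 instance_map=instance, config=config)


def truth_to_frame(fruits: list[GroundTruthFruit]):
    """Ground truth as a DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [f.id for f in fruits],
            "x": [f.x for f in fruits],
            "y": [f.y for f in fruits],
            "diameter_cm": [f.diameter_cm for f in fruits],
            "height_cm": [f.height_cm for f in fruits],
            "weight_g": [f.weight_g for f in fruits],
            "visible_fraction": [f.visible_fraction for f in fruits],
        }
    )
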