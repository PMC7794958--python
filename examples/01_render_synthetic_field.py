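"""Render a synthetic pumpkin field and inspect its ground truth.

The generator emulates a UAV orthomosaic at 1 cm/pixel: orange-red
fruits between mottled soil and canopy, a shaded left half and an
illuminated right half with overexposure spots, some fruits partly
covered by leaves and some placed tangent to a neighbor.
"""

import numpy as np

from cucurbita import SceneConfig, render_scene
from cucurbita.scene import truth_to_frame

config = SceneConfig(
    shape=(800, 800),          # 8 m x 8 m at 1 cm GSD
    n_fruits=80,
    fraction_touching=0.10,    # 10% of fruits belong to a tangent pair
    fraction_occluded=0.10,    # 10% partly hidden under a leaf polygon
    illumination_split=True,
    seed=42,
)
scene = render_scene(config)

truth = truth_to_frame(scene.fruits)
print(f"rendered {len(scene.fruits)} fruits on a "
      f"{scene.image.shape[0]}x{scene.image.shape[1]} px raster")
print(f"fruit pixels in truth mask: {int(scene.label_mask.sum())} "
      f"({100 * scene.label_mask.mean():.2f}% of the image)")
print("\nper-fruit truth (first 5 rows):")
print(truth.head().to_string(index=False))
print(f"\ndiameter: mean {truth.diameter_cm.mean():.1f} cm, "
      f"range [{truth.diameter_cm.min():.1f}, {truth.diameter_cm.max():.1f}]")
print(f"height:   mean {truth.height_cm.mean():.1f} cm, "
      f"range [{truth.height_cm.min():.1f}, {truth.height_cm.max():.1f}]")
occluded = truth[truth.visible_fraction < 1.0]
print(f"{len(occluded)} fruits partly occluded "
      f"(lowest visible fraction {truth.visible_fraction.min():.2f})")
# The truth mask keeps the full fruit extent even where leaves overpaint
# the RGB, so detection errors caused by occlusion can be isolated later.
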