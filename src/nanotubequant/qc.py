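"""Quality-control overlay images.

Renders the grayscale channel with classified regions outlined/tinted —
green for positive cells (protrusion-positive or donor-positive), red
for negative — mirroring the visual spot-checks used when screening
micrographs by eye.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .imgio import CalibratedImage
from .segmentation import Region

GREEN = (0, 255, 0)
RED = (255, 0, 0)


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(pixels, (1, 99.9))
    if hi <= lo:
        hi = lo + 1
    scaled = np.clip((pixels.astype(float) - lo) / (hi - lo), 0, 1)
    return (scaled * 255).astype(np.uint8)


def overlay(
    image: CalibratedImage,
    classified: list[tuple[Region, bool]],
    outline_only: bool = True,
) -> np.ndarray:
    """RGB uint8 overlay: green = positive, red = negative."""
    base = _to_uint8(image.pixels)
    rgb = np.stack([base, base, base], axis=-1)
    for region, positive in classified:
        color = GREEN if positive else RED
        r0, c0, r1, c1 = region.bbox
        m = region.mask.pixels
        if outline_only:
            m = m & ~ndi.binary_erosion(m, border_value=0)
        view = rgb[r0:r1, c0:c1]
        for ch in range(3):
            view[..., ch][m] = color[ch]
    return rgb


def save_overlay(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), rgb)
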