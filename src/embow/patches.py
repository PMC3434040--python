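"""Dense circular patch layout.

Local features are computed on a regular grid of overlapping circles laid
over the (pre-aligned) image; the centre of each circle is kept so that the
spatial pooling stage knows where every visual word was observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

DEFAULT_RADIUS = 16
DEFAULT_STRIDE = 16  # = radius: 50% linear overlap between neighbours


@dataclass(frozen=True)
class PatchLayout:
    """Ordered circle centres (row-major) plus the common radius."""

    centers: np.ndarray  # (I, 2) int array of (x, y), 0-based, x right / y down
    radius: int
    image_width: int
    image_height: int

    @property
    def n_patches(self) -> int:
        return len(self.centers)


def make_layout(
    image_width: int,
    image_height: int,
    radius: int = DEFAULT_RADIUS,
    stride: int = DEFAULT_STRIDE,
) -> PatchLayout:
    """Regular grid of centres starting at (radius, radius), step ``stride``.

    Only centres whose full circle fits inside the image are kept; with
    ``stride < 2 * radius`` adjacent circles overlap.
    """
    if radius < 1 or stride < 1:
        raise ValueError("radius and stride must be >= 1")
    if image_width < 2 * radius or image_height < 2 * radius:
        raise ValueError(
            f"image smaller than one patch: {image_width}x{image_height} "
            f"cannot hold a circle of radius {radius}"
        )
    xs = np.arange(radius, image_width - radius + 1, stride)
    ys = np.arange(radius, image_height - radius + 1, stride)
    gx, gy = np.meshgrid(xs, ys)  # row-major: y outer, x inner
    centers = np.column_stack([gx.ravel(), gy.ravel()]).astype(np.int64)
    return PatchLayout(centers=centers, radius=int(radius),
                       image_width=int(image_width), image_height=int(image_height))


@lru_cache(maxsize=16)
def disk_mask(radius: int) -> np.ndarray:
    """Boolean (2r+1)² mask of the inscribed disk (dist <= r)."""
    d = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(d, d)
    return dx * dx + dy * dy <= radius * radius


def extract_patch(image: np.ndarray, center, radius: int) -> np.ndarray:
    """Square crop of side 2r+1 around ``center`` with pixels outside the
    inscribed circle zeroed (circular support; corners are always zero).

    Valid centres satisfy radius <= x <= width - radius (same for y); for a
    centre on that upper boundary the crop overhangs the pixel grid by one
    row/column, which is filled with the zero background.
    """
    x, y = int(center[0]), int(center[1])
    h, w = image.shape[:2]
    if x < radius or y < radius or x > w - radius or y > h - radius:
        raise ValueError(f"patch at ({x}, {y}) with radius {radius} exceeds image bounds")
    side = 2 * radius + 1
    patch = np.zeros((side, side))
    y1 = min(y + radius + 1, h)
    x1 = min(x + radius + 1, w)
    patch[: y1 - (y - radius), : x1 - (x - radius)] = np.asarray(
        image[y - radius:y1, x - radius:x1], dtype=np.float64
    )
    patch[~disk_mask(radius)] = 0.0
    return patch
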