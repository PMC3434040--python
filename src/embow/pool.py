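"""Pooling patch codes into bag-of-words vectors.

The global bag H sums code vectors over all patches (for hard codes this is
the visual-word count histogram h_j = sum_i e_ij). The spatial bag M_n
partitions the image into a rows x cols grid of rectangles, pools each cell
separately and concatenates the n = rows*cols per-cell bags row-major, so the
representation length grows by the factor n (18 for the default 3x6 grid).
Group-level vectors are element-wise sums of image vectors, optionally
L1-normalized to remove group-size effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encode import ImageCodes

DEFAULT_GRID = (3, 6)
GLOBAL_GRID = (1, 1)


@dataclass
class BagVector:
    values: np.ndarray  # length n_cells * n_words, non-negative
    grid: tuple[int, int]
    n_words: int
    level: str = "image"  # "image" | "group"

    @property
    def n_cells(self) -> int:
        return self.grid[0] * self.grid[1]

    def blocks(self) -> np.ndarray:
        """(n_cells, n_words) view of the concatenated per-cell bags."""
        return self.values.reshape(self.n_cells, self.n_words)

    def to_global(self) -> "BagVector":
        return BagVector(values=self.blocks().sum(axis=0), grid=GLOBAL_GRID,
                         n_words=self.n_words, level=self.level)


def assign_cells(centers: np.ndarray, image_width: int, image_height: int,
                 grid: tuple[int, int]) -> np.ndarray:
    """Cell index (row-major) per patch centre.

    Cells are half-open rectangles [x0, x1) x [y0, y1) of equal size
    width//cols x height//rows; remainder pixels are absorbed by the last
    row/column, so a centre exactly on an interior boundary falls in the
    higher-index cell.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    centers = np.asarray(centers)
    x, y = centers[:, 0], centers[:, 1]
    if np.any((x < 0) | (x >= image_width) | (y < 0) | (y >= image_height)):
        raise ValueError("patch centre outside image bounds")
    cw = image_width // cols
    ch = image_height // rows
    col = np.minimum(x // cw, cols - 1)
    row = np.minimum(y // ch, rows - 1)
    return (row * cols + col).astype(np.int64)


def pool_image(codes: ImageCodes | np.ndarray, cells: np.ndarray,
               grid: tuple[int, int], n_words: int | None = None) -> BagVector:
    """Sum code rows per cell; block b is the bag of cell b."""
    mat = codes.codes if isinstance(codes, ImageCodes) else np.asarray(codes)
    if n_words is None:
        n_words = mat.shape[1]
    cells = np.asarray(cells)
    if len(cells) != len(mat):
        raise ValueError("cell assignment does not align with code rows")
    rows, cols = grid
    n_cells = rows * cols
    blocks = np.zeros((n_cells, n_words))
    np.add.at(blocks, cells, mat)
    return BagVector(values=blocks.ravel(), grid=(rows, cols), n_words=n_words,
                     level="image")


def pool_group(image_bags: Sequence[BagVector], normalize: bool = True) -> BagVector:
    """Element-wise sum of image bags; L1-normalized when requested.

    A zero sum (a group of entirely flat images) is left as the zero vector.
    """
    if not image_bags:
        raise ValueError("cannot pool an empty group")
    first = image_bags[0]
    for b in image_bags[1:]:
        if b.grid != first.grid or b.n_words != first.n_words:
            raise ValueError("cannot pool bags with mixed grids or word counts")
    total = np.sum([b.values for b in image_bags], axis=0)
    if normalize:
        s = total.sum()
        if s > 0:
            total = total / s
    return BagVector(values=total, grid=first.grid, n_words=first.n_words,
                     level="group")
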