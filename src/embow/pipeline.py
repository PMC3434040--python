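"""End-to-end feature computation: images -> group/image representations.

The four representation modes compared throughout the package are named
``global-hard``, ``global-sparse``, ``spatial-hard`` and ``spatial-sparse``:
global pools over the whole image (grid 1x1), spatial over the default 3x6
grid; hard is single-word quantization, sparse the non-negative L1 code.

Descriptors and codes are computed once per image and shared across modes;
sparse coding runs as one batched solve over every patch of every image.
"""

from __future__ import annotations

import numpy as np

from .codebook import Codebook
from .descriptors import describe_image
from .encode import DEFAULT_LAMBDA, hard_assign_batch, sparse_encode_batch
from .patches import DEFAULT_RADIUS, DEFAULT_STRIDE, make_layout
from .pool import DEFAULT_GRID, GLOBAL_GRID, BagVector, assign_cells, pool_group, pool_image
from .synthetic import LabeledGroupSet

MODES = ("global-hard", "global-sparse", "spatial-hard", "spatial-sparse")


def mode_parts(mode: str) -> tuple[tuple[int, int], str]:
    """Map a mode name to (grid, coding)."""
    try:
        spatial, coding = mode.split("-")
        grid = {"global": GLOBAL_GRID, "spatial": DEFAULT_GRID}[spatial]
        if coding not in ("hard", "sparse"):
            raise KeyError(coding)
    except (ValueError, KeyError):
        raise ValueError(f"unknown representation mode {mode!r}; expected one of {MODES}")
    return grid, coding


def _image_code_matrices(images, codebook, codings, lam, radius, stride,
                         spatial_grid=DEFAULT_GRID):
    """Per-image code matrices for the requested codings ('hard'/'sparse').

    Returns (codes: dict coding -> list of (I, c) arrays, cells per image for
    the spatial grid, n active patches per image).
    """
    h, w = images[0].shape
    layout = make_layout(w, h, radius=radius, stride=stride)
    cells = assign_cells(layout.centers, w, h, spatial_grid)

    dsets = []
    for img in images:
        if img.shape != (h, w):
            raise ValueError("all images must share the canvas dimensions")
        dsets.append(describe_image(img, layout))
    active = [~ds.zero_flags for ds in dsets]
    Y = np.vstack([ds.vectors[a] for ds, a in zip(dsets, active)])
    bounds = np.cumsum([0] + [int(a.sum()) for a in active])

    out: dict[str, list[np.ndarray]] = {}
    for coding in codings:
        if coding == "hard":
            idx = hard_assign_batch(Y, codebook)
            full = np.zeros((len(Y), codebook.c))
            full[np.arange(len(Y)), idx] = 1.0
        else:
            full = sparse_encode_batch(Y, codebook, lam=lam)
        per_image = []
        for i, a in enumerate(active):
            mat = np.zeros((layout.n_patches, codebook.c))
            mat[a] = full[bounds[i]:bounds[i + 1]]
            per_image.append(mat)
        out[coding] = per_image
    return out, cells


def image_vectors(
    images,
    codebook: Codebook,
    mode: str = "global-sparse",
    lam: float = DEFAULT_LAMBDA,
    radius: int = DEFAULT_RADIUS,
    stride: int = DEFAULT_STRIDE,
    normalize: bool = True,
) -> np.ndarray:
    """One representation row per image (L1-normalized by default)."""
    grid, coding = mode_parts(mode)
    codes, cells = _image_code_matrices(images, codebook, [coding], lam, radius,
                                        stride, spatial_grid=grid if grid != GLOBAL_GRID else DEFAULT_GRID)
    gcells = cells if grid != GLOBAL_GRID else np.zeros(len(cells), dtype=np.int64)
    rows = []
    for mat in codes[coding]:
        bag = pool_image(mat, gcells, grid, n_words=codebook.c)
        v = bag.values
        if normalize:
            s = v.sum()
            v = v / s if s > 0 else v
        rows.append(v)
    return np.vstack(rows)


def group_features(
    group_set: LabeledGroupSet,
    codebook: Codebook,
    modes=MODES,
    lam: float = DEFAULT_LAMBDA,
    radius: int = DEFAULT_RADIUS,
    stride: int = DEFAULT_STRIDE,
    normalize: bool = True,
) -> dict[str, np.ndarray]:
    """Group-level feature matrix per requested mode.

    Every image is described and encoded once; hard and sparse codes are
    pooled to both grids as needed, then summed (and L1-normalized) within
    each group.
    """
    modes = tuple(modes)
    codings = sorted({mode_parts(m)[1] for m in modes})
    flat_images = [img for _, imgs in group_set.groups for img in imgs]
    sizes = [len(imgs) for _, imgs in group_set.groups]
    codes, cells = _image_code_matrices(flat_images, codebook, codings, lam,
                                        radius, stride)
    out: dict[str, np.ndarray] = {}
    for mode in modes:
        grid, coding = mode_parts(mode)
        gcells = cells if grid != GLOBAL_GRID else np.zeros(len(cells), dtype=np.int64)
        bags = [pool_image(mat, gcells, grid, n_words=codebook.c)
                for mat in codes[coding]]
        rows = []
        start = 0
        for n in sizes:
            gb = pool_group(bags[start:start + n], normalize=normalize)
            rows.append(gb.values)
            start += n
        out[mode] = np.vstack(rows)
    return out
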