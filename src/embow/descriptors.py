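"""Upright SIFT-style local descriptors for circular patches.

Each patch is summarised by a 128-dimensional gradient-orientation histogram:
4x4 spatial bins x 8 orientation bins, Gaussian-weighted (sigma = radius/2),
trilinearly interpolated, L2-normalised, clipped at 0.2 and renormalised.
Orientation is *not* normalised to a dominant direction: the images this
package targets are pre-aligned, and the spatial semantics of the pooling
grid depend on keeping the patch frame fixed.

Gradients are restricted to the disk interior (distance <= radius-1 from the
centre), so the circular mask applied by :func:`embow.patches.extract_patch`
never contributes an artificial edge: a constant patch has a zero descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .patches import PatchLayout, disk_mask

DESCRIPTOR_LENGTH = 128
N_SPATIAL = 4  # 4x4 spatial bins
N_ORIENT = 8
_CLIP = 0.2
_EPS = 1e-12


@dataclass
class DescriptorSet:
    """Per-image descriptors, rows aligned one-to-one with patch centres."""

    vectors: np.ndarray  # (I, 128) float64
    centers: np.ndarray  # (I, 2), carried from the layout
    d: int = DESCRIPTOR_LENGTH

    @property
    def zero_flags(self) -> np.ndarray:
        """True for flat patches that produced the (flagged) zero vector."""
        return ~np.any(self.vectors, axis=1)


@lru_cache(maxsize=8)
def _patch_tables(radius: int):
    """Precomputed, image-independent binning tables for a given radius.

    Returns (interior flat mask, gaussian weights, spatial contributions)
    where spatial contributions is a list of (bin_base_index, weight) pairs
    per pixel for the up-to-4 neighbouring spatial bins.
    """
    side = 2 * radius + 1
    d = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(d, d)
    interior = (dx * dx + dy * dy) <= (radius - 1) ** 2
    sigma = radius / 2.0
    gauss = np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))

    # continuous spatial bin coordinates in [−0.5, 3.5]
    cols = np.arange(side)
    u = (cols + 0.5) / side * N_SPATIAL - 0.5
    uu, vv = np.meshgrid(u, u)  # uu: x-bin coord, vv: y-bin coord
    u0 = np.floor(uu).astype(np.int64)
    v0 = np.floor(vv).astype(np.int64)
    fu = uu - u0
    fv = vv - v0

    contribs = []
    for dv, dw_v in ((0, 1.0 - fv), (1, fv)):
        for du, dw_u in ((0, 1.0 - fu), (1, fu)):
            vb = v0 + dv
            ub = u0 + du
            valid = (vb >= 0) & (vb < N_SPATIAL) & (ub >= 0) & (ub < N_SPATIAL)
            # invalid contributions get weight 0; park their index at bin 0
            base = (np.clip(vb, 0, N_SPATIAL - 1) * N_SPATIAL
                    + np.clip(ub, 0, N_SPATIAL - 1)) * N_ORIENT
            w = dw_v * dw_u
            contribs.append((base.ravel(), (w * valid).ravel()))
    return interior.ravel(), gauss.ravel(), contribs


def _sift_from_gradients(gx: np.ndarray, gy: np.ndarray, radius: int) -> np.ndarray:
    interior, gauss, contribs = _patch_tables(radius)
    mag = np.hypot(gx, gy).ravel() * gauss
    mag[~interior] = 0.0
    ori = np.mod(np.arctan2(gy, gx).ravel(), 2.0 * np.pi) / (2.0 * np.pi) * N_ORIENT
    o0 = np.floor(ori).astype(np.int64) % N_ORIENT
    fo = ori - np.floor(ori)
    o1 = (o0 + 1) % N_ORIENT

    hist = np.zeros(DESCRIPTOR_LENGTH)
    for base, w in contribs:
        sw = w * mag
        hist += np.bincount(base + o0, weights=sw * (1.0 - fo), minlength=DESCRIPTOR_LENGTH)
        hist += np.bincount(base + o1, weights=sw * fo, minlength=DESCRIPTOR_LENGTH)

    norm = np.linalg.norm(hist)
    if norm < _EPS:
        return np.zeros(DESCRIPTOR_LENGTH)
    hist /= norm
    np.clip(hist, None, _CLIP, out=hist)
    hist /= np.linalg.norm(hist)
    return hist


def describe_patch(patch: np.ndarray) -> np.ndarray:
    """128-vector for one (circularly masked) square patch.

    A patch with no gradient inside its disk interior returns the zero
    vector; callers treat such rows as flagged, not as errors.
    """
    patch = np.asarray(patch, dtype=np.float64)
    side = patch.shape[0]
    if patch.shape != (side, side) or side % 2 != 1:
        raise ValueError("patch must be square with odd side 2*radius+1")
    radius = (side - 1) // 2
    gy, gx = np.gradient(patch)
    return _sift_from_gradients(gx, gy, radius)


def describe_image(image: np.ndarray, layout: PatchLayout) -> DescriptorSet:
    """One descriptor row per layout centre, in layout order.

    Gradients are computed once on the whole image and sliced per patch;
    because the descriptor only uses pixels strictly inside each disk, this
    equals running :func:`describe_patch` on every masked crop.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if w != layout.image_width or h != layout.image_height:
        raise ValueError("layout was built for a different image size")
    # one zero row/column of padding so centres on the far layout boundary
    # (x = W - r) see the same zero background as the per-patch path
    padded = np.zeros((h + 1, w + 1))
    padded[:h, :w] = image
    gy, gx = np.gradient(padded)
    r = layout.radius
    vectors = np.empty((layout.n_patches, DESCRIPTOR_LENGTH))
    for i, (x, y) in enumerate(layout.centers):
        sl = np.s_[y - r:y + r + 1, x - r:x + r + 1]
        vectors[i] = _sift_from_gradients(gx[sl], gy[sl], r)
    return DescriptorSet(vectors=vectors, centers=layout.centers.copy())
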