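"""Visual-word dictionary: k-means over a sample of local descriptors.

The dictionary D is a d x c matrix whose columns are cluster centroids
("visual words") in descriptor space. Initialization uses k-means++ with a
fixed seed; the Lloyd iterations are run in-package so the per-iteration
objective trace is available (it must be non-increasing) and the whole fit
is reproducible bit-for-bit. Centroids are kept in raw descriptor units —
no renormalization — so sparse reconstruction errors are in the same units
as the descriptors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import pairwise_distances_argmin_min

from .descriptors import describe_image
from .patches import PatchLayout
from .synthetic import LabeledGroupSet

DEFAULT_CODEBOOK_SIZE = 2000
_FORMAT_VERSION = 1


@dataclass
class Codebook:
    D: np.ndarray  # (d, c): each column is a visual word
    training_meta: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.D.shape[0]

    @property
    def c(self) -> int:
        return self.D.shape[1]

    def __post_init__(self):
        if self.D.ndim != 2 or self.D.shape[1] < 2:
            raise ValueError("codebook needs a 2-D matrix with at least 2 words")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("codebook contains non-finite entries")


def sample_descriptors(
    group_set: LabeledGroupSet,
    layout: PatchLayout,
    fraction: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Pool descriptors from a seeded random subset of images.

    ``fraction`` selects round(fraction * n_images) images without
    replacement; zero (flat-patch) descriptors are excluded from the sample.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    flat = [img for _, imgs in group_set.groups for img in imgs]
    n_sel = max(1, int(round(fraction * len(flat))))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(flat), size=n_sel, replace=False)
    blocks = []
    for i in sorted(idx):
        ds = describe_image(flat[i], layout)
        keep = ~ds.zero_flags
        if keep.any():
            blocks.append(ds.vectors[keep])
    if not blocks:
        raise ValueError("no nonzero descriptors in the sampled images")
    return np.vstack(blocks)


def _lloyd(sample, centers, max_iter, tol=1e-7):
    """Vectorized Lloyd iterations; returns centers, labels, objective trace."""
    trace = []
    labels = None
    for _ in range(max_iter):
        labels, dists = pairwise_distances_argmin_min(sample, centers)
        obj = float(np.sum(dists ** 2))
        # reassign any empty cluster to the farthest point (deterministic)
        counts = np.bincount(labels, minlength=len(centers))
        for k in np.flatnonzero(counts == 0):
            far = int(np.argmax(dists))
            centers[k] = sample[far]
            labels[far] = k
            dists[far] = 0.0
            counts = np.bincount(labels, minlength=len(centers))
        trace.append(obj)
        new_centers = np.zeros_like(centers)
        np.add.at(new_centers, labels, sample)
        new_centers /= np.bincount(labels, minlength=len(centers))[:, None]
        if np.allclose(new_centers, centers, rtol=0, atol=tol):
            centers = new_centers
            break
        centers = new_centers
    labels, dists = pairwise_distances_argmin_min(sample, centers)
    trace.append(float(np.sum(dists ** 2)))
    return centers, labels, trace


def build_codebook(
    sample: np.ndarray,
    c: int = DEFAULT_CODEBOOK_SIZE,
    seed: int = 0,
    max_iter: int = 100,
    n_restarts: int = 10,
) -> Codebook:
    """Cluster the descriptor sample into ``c`` visual words.

    k-means++ seeding, ``n_restarts`` seeded restarts, best objective kept.
    The winning restart's per-iteration objective trace (non-increasing) is
    stored in ``training_meta['objective_trace']``.
    """
    sample = np.asarray(sample, dtype=np.float64)
    if sample.shape[0] < c:
        raise ValueError(
            f"cannot build {c} visual words from only {sample.shape[0]} descriptors"
        )
    best = None
    for r in range(n_restarts):
        init, _ = kmeans_plusplus(sample, n_clusters=c, random_state=seed + r)
        centers, _, trace = _lloyd(sample, init.copy(), max_iter)
        if best is None or trace[-1] < best[1][-1]:
            best = (centers, trace)
    centers, trace = best
    meta = {
        "sample_size": int(sample.shape[0]),
        "seed": int(seed),
        "n_restarts": int(n_restarts),
        "n_iterations": len(trace) - 1,
        "objective_trace": trace,
    }
    return Codebook(D=centers.T.copy(), training_meta=meta)


def save_codebook(codebook: Codebook, path: str | Path) -> None:
    """Flat binary array (.npy) plus a JSON sidecar (d, c, seed, checksum)."""
    path = Path(path)
    npy = path.with_suffix(".npy")
    np.save(npy, codebook.D)
    sidecar = {
        "version": _FORMAT_VERSION,
        "d": codebook.d,
        "c": codebook.c,
        "checksum": hashlib.sha256(np.ascontiguousarray(codebook.D).tobytes()).hexdigest(),
        "training_meta": codebook.training_meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_codebook(path: str | Path) -> Codebook:
    path = Path(path)
    D = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported codebook format version {sidecar.get('version')}")
    if D.shape != (sidecar["d"], sidecar["c"]):
        raise ValueError(
            f"codebook shape {D.shape} does not match sidecar "
            f"({sidecar['d']}, {sidecar['c']})"
        )
    checksum = hashlib.sha256(np.ascontiguousarray(D).tobytes()).hexdigest()
    if checksum != sidecar["checksum"]:
        raise ValueError("codebook checksum mismatch")
    return Codebook(D=D, training_meta=sidecar.get("training_meta", {}))
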