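"""Content-based retrieval: top-k most similar images by cosine similarity.

Retrieval operates on per-image representation vectors (any mode; default
global-sparse). Vectors are L1-normalized and compared with cosine
similarity, so an exact duplicate of the query always scores 1.0 — which is
also why the query itself is removed from its own result list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .codebook import Codebook
from .encode import DEFAULT_LAMBDA
from .patches import DEFAULT_RADIUS, DEFAULT_STRIDE
from .pipeline import image_vectors
from .pool import GLOBAL_GRID

DEFAULT_K = 8


@dataclass
class RetrievalIndex:
    image_ids: list[str]
    X: np.ndarray  # (n_images, n_features), L1-normalized rows
    metric: str = "cosine"

    def __post_init__(self):
        if len(self.image_ids) != len(self.X):
            raise ValueError("ids do not align with representation rows")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("image ids must be unique")


def build_index(
    images: Sequence[np.ndarray],
    image_ids: Sequence[str],
    codebook: Codebook,
    mode: str = "global-sparse",
    lam: float = DEFAULT_LAMBDA,
    radius: int = DEFAULT_RADIUS,
    stride: int = DEFAULT_STRIDE,
) -> RetrievalIndex:
    """Per-image (not per-group) representation index."""
    if len(images) == 0:
        raise ValueError("cannot build an index over an empty image set")
    X = image_vectors(images, codebook, mode=mode, lam=lam, radius=radius,
                      stride=stride, normalize=True)
    return RetrievalIndex(image_ids=list(image_ids), X=X)


def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity; zero vectors score 0 against everything."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def query(index: RetrievalIndex, q, k: int = DEFAULT_K) -> list[tuple[str, float]]:
    """Top-k (image_id, similarity), descending; ties broken by id.

    ``q`` is either an indexed image id (the query image itself is then
    excluded from the results) or a raw representation vector.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(q, str):
        if q not in index.image_ids:
            raise KeyError(f"unknown image id {q!r}")
        qi = index.image_ids.index(q)
        qvec = index.X[qi]
        exclude = qi
    else:
        qvec = np.asarray(q, dtype=np.float64)
        exclude = None

    norms = np.linalg.norm(index.X, axis=1)
    qn = np.linalg.norm(qvec)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where((norms > 0) & (qn > 0), index.X @ qvec / (norms * qn), 0.0)
    order = sorted(
        (i for i in range(len(sims)) if i != exclude),
        key=lambda i: (-sims[i], index.image_ids[i]),
    )
    return [(index.image_ids[i], float(sims[i])) for i in order[:k]]


def precision_at_k(index: RetrievalIndex, relevance: Sequence[str],
                   k: int = DEFAULT_K) -> float:
    """Mean precision@k over all indexed images as queries.

    ``relevance`` gives one cluster/class label per indexed image; a
    retrieved image is a hit when it shares the query's label.
    """
    labels = dict(zip(index.image_ids, relevance))
    precs = []
    for qid in index.image_ids:
        hits = query(index, qid, k=k)
        precs.append(np.mean([labels[h] == labels[qid] for h, _ in hits]))
    return float(np.mean(precs))
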