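"""Patch encoding: hard visual-word assignment and sparse "visual sentences".

A local descriptor y in R^d is mapped onto the codebook D in R^{d x c} in one
of two ways:

* hard — the classic vector-quantization step: the single nearest centroid

      min_e 1/2 ||D e − y||²  s.t.  e_i in {0,1},  sum_i e_i = 1,

  i.e. a one-hot code at the nearest visual word (ties to the lowest index).

* sparse — a non-negative L1-regularized reconstruction,

      min_x 1/2 ||D x − y||² + λ ||x||₁  s.t.  x >= 0,

  so that several similar visual words can share the description of one
  patch, with their contributions as weights (the LASSO-style relaxation of
  the hard assignment; λ controls sparsity, default 0.01).

The sparse problem is solved by cyclic coordinate descent on the Gram
formulation with deterministic initialization at x = 0; the per-coordinate
update is the one-sided soft threshold

      x_j <- max(0, (D_j'y − sum_{k != j} G_{jk} x_k − λ) / G_{jj}).

Coordinate descent is run simultaneously over many patches (columns) so an
entire image set is encoded with dense matrix arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codebook import Codebook
from .descriptors import DescriptorSet

DEFAULT_LAMBDA = 0.01
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000


@dataclass
class PatchCode:
    x: np.ndarray  # length-c non-negative code
    mode: str  # "hard" | "sparse"
    objective_value: float


@dataclass
class ImageCodes:
    """Per-image code matrix with the patch centres carried through."""

    codes: np.ndarray  # (I, c)
    centers: np.ndarray  # (I, 2)
    mode: str
    zero_flags: np.ndarray  # True where the descriptor was flat (zero code row)

    @property
    def n_active(self) -> int:
        return int((~self.zero_flags).sum())


def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in descriptor or codebook")


def hard_assign_batch(Y: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-centroid index per row of Y (N, d); ties -> lowest index."""
    D = codebook.D
    _check_finite(Y, D)
    # ||D_j - y||² = ||D_j||² - 2 y·D_j + ||y||²; the ||y||² term is constant
    # per row but kept so tied distances are tied exactly in the test cases.
    d2 = (
        np.sum(D * D, axis=0)[None, :]
        - 2.0 * Y @ D
        + np.sum(Y * Y, axis=1)[:, None]
    )
    return np.argmin(d2, axis=1)


def hard_assign(y: np.ndarray, codebook: Codebook) -> PatchCode:
    """One-hot code at the nearest visual word."""
    y = np.asarray(y, dtype=np.float64)
    j = int(hard_assign_batch(y[None, :], codebook)[0])
    x = np.zeros(codebook.c)
    x[j] = 1.0
    obj = 0.5 * float(np.sum((codebook.D[:, j] - y) ** 2))
    return PatchCode(x=x, mode="hard", objective_value=obj)


def _objective_batch(G, B, ysq, X, lam):
    """Per-column objective 1/2||DX−Y||² + λ||x||₁ via the Gram form."""
    quad = np.einsum("ji,ji->i", X, G @ X)
    lin = np.einsum("ji,ji->i", B, X)
    return 0.5 * (quad - 2.0 * lin + ysq) + lam * X.sum(axis=0)


def sparse_encode_batch(
    Y: np.ndarray,
    codebook: Codebook,
    lam: float = DEFAULT_LAMBDA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    return_objective: bool = False,
):
    """Solve the non-negative lasso for every row of Y (N, d) at once.

    Returns an (N, c) code matrix (and per-row objectives if requested).
    Convergence: relative objective decrease < ``tol`` on every problem, or
    ``max_iter`` full coordinate sweeps.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    D = codebook.D
    Yd = np.ascontiguousarray(np.asarray(Y, dtype=np.float64).T)  # (d, N)
    _check_finite(Yd, D)
    if Yd.shape[0] != D.shape[0]:
        raise ValueError(
            f"descriptor length {Yd.shape[0]} does not match codebook d={D.shape[0]}"
        )
    c = D.shape[1]
    n = Yd.shape[1]
    G = D.T @ D  # (c, c)
    B = D.T @ Yd  # (c, N)
    ysq = np.einsum("ji,ji->i", Yd, Yd)
    diag = np.diag(G).copy()
    dead = diag <= 0.0  # zero dictionary columns can never activate
    X = np.zeros((c, n))

    prev_obj = _objective_batch(G, B, ysq, X, lam)
    for _ in range(max_iter):
        changed = False
        for j in range(c):
            if dead[j]:
                continue
            xj_new = np.maximum(0.0, (B[j] - G[j] @ X + diag[j] * X[j] - lam) / diag[j])
            if not changed and np.any(xj_new != X[j]):
                changed = True
            X[j] = xj_new
        obj = _objective_batch(G, B, ysq, X, lam)
        if not changed:
            break
        denom = np.maximum(np.abs(prev_obj), 1.0)
        if np.all((prev_obj - obj) / denom < tol):
            prev_obj = obj
            break
        prev_obj = obj
    if return_objective:
        return X.T.copy(), prev_obj
    return X.T.copy()


def sparse_encode(
    y: np.ndarray,
    codebook: Codebook,
    lam: float = DEFAULT_LAMBDA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PatchCode:
    """Sparse visual-sentence code for a single descriptor."""
    y = np.asarray(y, dtype=np.float64)
    X, obj = sparse_encode_batch(
        y[None, :], codebook, lam=lam, tol=tol, max_iter=max_iter, return_objective=True
    )
    return PatchCode(x=X[0], mode="sparse", objective_value=float(obj[0]))


def encode_image(
    descriptors: DescriptorSet,
    codebook: Codebook,
    mode: str = "sparse",
    lam: float = DEFAULT_LAMBDA,
) -> ImageCodes:
    """Code matrix for one image's descriptors; flat patches get zero rows."""
    if descriptors.d != codebook.d:
        raise ValueError(
            f"descriptor length {descriptors.d} does not match codebook d={codebook.d}"
        )
    zero = descriptors.zero_flags
    codes = np.zeros((len(descriptors.vectors), codebook.c))
    active = ~zero
    if active.any():
        Y = descriptors.vectors[active]
        if mode == "hard":
            idx = hard_assign_batch(Y, codebook)
            hot = np.zeros((len(idx), codebook.c))
            hot[np.arange(len(idx)), idx] = 1.0
            codes[active] = hot
        elif mode == "sparse":
            codes[active] = sparse_encode_batch(Y, codebook, lam=lam)
        else:
            raise ValueError(f"unknown encoding mode {mode!r}")
    elif mode not in ("hard", "sparse"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    return ImageCodes(codes=codes, centers=descriptors.centers, mode=mode,
                      zero_flags=zero.copy())
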