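"""Sparse/hard patch-coding checks against independent oracles.

The non-negative L1 solver is compared with a support-enumeration oracle:
for small c the global minimum of  1/2 ||Dx - y||^2 + lam ||x||_1, x >= 0
can be found exactly by trying every support S, solving the unconstrained
stationarity system  D_S' D_S x_S = D_S' y - lam  and keeping feasible
(all-positive) candidates.
"""

import itertools

import numpy as np
import pytest

from embow import (describe_image, encode_image, generate_image, hard_assign,
                   sparse_encode, sparse_encode_batch)
from embow.codebook import Codebook
from embow.encode import hard_assign_batch


def nn_lasso_oracle(D, y, lam):
    """Exact minimum objective by enumerating all sign supports."""
    c = D.shape[1]
    best = 0.5 * float(y @ y)  # empty support
    for k in range(1, c + 1):
        for S in itertools.combinations(range(c), k):
            DS = D[:, S]
            G = DS.T @ DS
            rhs = DS.T @ y - lam
            try:
                xS = np.linalg.solve(G, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.all(xS > -1e-12):
                xS = np.maximum(xS, 0.0)
                r = DS @ xS - y
                best = min(best, 0.5 * float(r @ r) + lam * float(xS.sum()))
    return best


def random_instance(rng, d=8, c=5):
    D = rng.normal(size=(d, c))
    y = rng.normal(size=d)
    return Codebook(D=D), y


def test_solver_matches_support_enumeration_oracle():
    rng = np.random.default_rng(1)
    worst = 0.0
    for _ in range(100):
        cb, y = random_instance(rng)
        for lam in (0.0, 0.01, 0.1):
            code = sparse_encode(y, cb, lam=lam)
            oracle = nn_lasso_oracle(cb.D, y, lam)
            worst = max(worst, code.objective_value - oracle)
            assert code.objective_value <= oracle + 1e-6
            assert np.all(code.x >= 0)
    assert worst < 1e-6


def test_identity_dictionary_exact_reconstruction(rng):
    y = np.abs(rng.random(6))
    cb = Codebook(D=np.eye(6))
    code = sparse_encode(y, cb, lam=0.0)
    assert np.allclose(code.x, y, atol=1e-12)


def test_kkt_threshold_kills_all_coordinates(rng):
    cb, y = random_instance(rng)
    lam = float(np.max(cb.D.T @ y)) + 1e-9
    code = sparse_encode(y, cb, lam=lam)
    assert np.all(code.x == 0)
    assert code.objective_value == pytest.approx(0.5 * float(y @ y))


def test_regularization_path_l1_norm_nonincreasing():
    rng = np.random.default_rng(2)
    lams = np.linspace(0.0, 0.5, 10)
    for _ in range(20):
        cb, y = random_instance(rng)
        norms = [float(np.abs(sparse_encode(y, cb, lam=l).x).sum()) for l in lams]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))


def test_hard_assignment_matches_exhaustive_search():
    rng = np.random.default_rng(3)
    for _ in range(50):
        cb, y = random_instance(rng, d=6, c=9)
        code = hard_assign(y, cb)
        dists = [np.sum((cb.D[:, j] - y) ** 2) for j in range(cb.c)]
        assert np.argmax(code.x) == int(np.argmin(dists))
        assert code.x.sum() == 1.0


def test_hard_assignment_tie_goes_to_lowest_index():
    # y equidistant from two mirrored words
    cb = Codebook(D=np.array([[1.0, -1.0], [0.0, 0.0]]))
    code = hard_assign(np.array([0.0, 0.5]), cb)
    assert np.argmax(code.x) == 0
    cb2 = Codebook(D=np.array([[0.0, 1.0], [0.0, 1.0]]))
    assert np.argmax(hard_assign(np.array([0.9, 0.9]), cb2).x) == 1


def test_hard_agrees_with_sparse_argmax_for_orthonormal_words(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
    cb = Codebook(D=Q[:, :5])
    for _ in range(20):
        y = rng.normal(size=8)
        hard_j = int(np.argmax(hard_assign(y, cb).x))
        x = sparse_encode(y, cb, lam=1e-6).x
        if x.max() > 0 and (cb.D.T @ y)[hard_j] > 1e-6:
            assert int(np.argmax(x)) == hard_j


def test_batch_matches_single_solves(rng):
    cb = Codebook(D=rng.normal(size=(8, 5)))
    Y = rng.normal(size=(20, 8))
    X = sparse_encode_batch(Y, cb, lam=0.01)
    D = cb.D
    for i in range(len(Y)):
        single = sparse_encode(Y[i], cb, lam=0.01)
        # both runs stop at the same relative-objective tolerance, so the
        # iterates agree to roughly sqrt(tol) in x and tol in objective
        assert np.allclose(X[i], single.x, atol=1e-4)
        obj = 0.5 * np.sum((D @ X[i] - Y[i]) ** 2) + 0.01 * X[i].sum()
        assert obj == pytest.approx(single.objective_value, abs=1e-8)


def test_encode_image_row_properties(clean_spec, layout, small_codebook):
    img = generate_image(clean_spec, {"stripes3"})
    ds = describe_image(img, layout)
    hard = encode_image(ds, small_codebook, mode="hard")
    active = ~hard.zero_flags
    assert np.allclose(hard.codes[active].sum(axis=1), 1.0)
    assert np.all(hard.codes[~active] == 0)

    sparse = encode_image(ds, small_codebook, mode="sparse", lam=0.01)
    support = (sparse.codes[active] > 1e-10).sum(axis=1)
    assert 1 < support.mean() < small_codebook.c  # a sentence, not a word

    # sparse objective never exceeds the hard one-hot objective under the
    # same penalty, row by row
    D = small_codebook.D
    for i in np.flatnonzero(active)[:10]:
        y = ds.vectors[i]
        obj_sparse = 0.5 * np.sum((D @ sparse.codes[i] - y) ** 2) + 0.01 * sparse.codes[i].sum()
        obj_hard = 0.5 * np.sum((D @ hard.codes[i] - y) ** 2) + 0.01 * hard.codes[i].sum()
        assert obj_sparse <= obj_hard + 1e-10


def test_encode_dimension_mismatch_errors(small_codebook, rng):
    with pytest.raises(ValueError, match="does not match"):
        sparse_encode_batch(rng.random((3, 7)), small_codebook, lam=0.01)
    with pytest.raises(ValueError):
        sparse_encode(np.array([np.nan] * small_codebook.d), small_codebook)
    with pytest.raises(ValueError):
        sparse_encode_batch(rng.random((2, small_codebook.d)), small_codebook, lam=-1)
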