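import numpy as np
import pytest

from embow import (BagVector, assign_cells, describe_image, encode_image,
                   generate_image, pool_group, pool_image)


def test_single_cell_grid_collects_everything(layout):
    cells = assign_cells(layout.centers, 192, 96, (1, 1))
    assert np.all(cells == 0)


def test_grid_cell_arithmetic(layout):
    cells = assign_cells(np.array([[16, 16], [176, 80], [32, 16], [31, 16]]),
                         192, 96, (3, 6))
    # 192x96 with a 3x6 grid: 32x32 cells; (16,16)->cell 0, (176,80)->cell 17
    assert cells.tolist() == [0, 17, 1, 0]  # 32 on a boundary -> higher cell


def test_boundary_centers_go_to_higher_cell():
    cells = assign_cells(np.array([[32, 0], [0, 32]]), 96, 96, (3, 3))
    assert cells.tolist() == [1, 3]


def test_out_of_bounds_center_errors():
    with pytest.raises(ValueError):
        assign_cells(np.array([[200, 10]]), 192, 96, (3, 6))


def test_hard_global_histogram_counts_patches(clean_spec, layout, small_codebook):
    img = generate_image(clean_spec, {"anterior_spot"})
    codes = encode_image(describe_image(img, layout), small_codebook, mode="hard")
    cells = assign_cells(layout.centers, 192, 96, (1, 1))
    bag = pool_image(codes, cells, (1, 1))
    assert bag.values.sum() == codes.n_active
    assert len(bag.values) == small_codebook.c


def test_spatial_block_sum_equals_global_bag(noisy_spec, layout, small_codebook):
    cells = assign_cells(layout.centers, 192, 96, (3, 6))
    gcells = np.zeros(layout.n_patches, dtype=np.int64)
    for mode, tol in (("hard", 0.0), ("sparse", 1e-9)):
        for seed in (1, 2):
            img = generate_image(noisy_spec, {"stripes3", "dorsal_band"}, seed=seed)
            codes = encode_image(describe_image(img, layout), small_codebook, mode=mode)
            spatial = pool_image(codes, cells, (3, 6))
            assert len(spatial.values) == 18 * small_codebook.c
            global_bag = pool_image(codes, gcells, (1, 1))
            assert np.allclose(spatial.blocks().sum(axis=0), global_bag.values, atol=tol)


def test_patch_permutation_invariance(rng):
    codes = rng.random((30, 7))
    cells = rng.integers(0, 6, size=30)
    perm = rng.permutation(30)
    a = pool_image(codes, cells, (2, 3))
    b = pool_image(codes[perm], cells[perm], (2, 3))
    assert np.allclose(a.values, b.values)


def test_pool_image_matches_brute_force(rng):
    codes = rng.random((20, 4))
    cells = rng.integers(0, 4, size=20)
    bag = pool_image(codes, cells, (2, 2))
    for b in range(4):
        assert np.allclose(bag.blocks()[b], codes[cells == b].sum(axis=0))


def test_group_pooling_rules(rng):
    v1 = rng.random(12)
    v2 = rng.random(12)
    bags = [BagVector(values=v, grid=(1, 1), n_words=12) for v in (v1, v2)]
    summed = pool_group(bags, normalize=False)
    assert np.allclose(summed.values, v1 + v2)
    assert summed.level == "group"
    # single image, unnormalized: group vector equals the image vector
    assert np.allclose(pool_group(bags[:1], normalize=False).values, v1)
    # duplicated image, normalized: same direction as one image
    twice = pool_group([bags[0], bags[0]], normalize=True)
    assert np.allclose(twice.values, v1 / v1.sum())
    zero = BagVector(values=np.zeros(12), grid=(1, 1), n_words=12)
    assert np.all(pool_group([zero], normalize=True).values == 0)


def test_mixed_grids_error(rng):
    a = BagVector(values=rng.random(12), grid=(1, 1), n_words=12)
    b = BagVector(values=rng.random(24), grid=(2, 1), n_words=12)
    with pytest.raises(ValueError, match="mixed"):
        pool_group([a, b])
    with pytest.raises(ValueError):
        pool_group([])
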