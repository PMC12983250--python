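"""Farthest point sampling, block partitioning and merge-back round trips."""

import numpy as np
import pytest

from canopycomplete.blocks import (Block, farthest_point_sample,
                                   merge_completed, partition_blocks,
                                   resample_block)


def _fps_oracle(points, m, start):
    """Naive greedy re-implementation with explicit loops."""
    selected = [start]
    for _ in range(m - 1):
        best, best_d = -1, -1.0
        for i in range(len(points)):
            d = min(np.sum((points[i] - points[j]) ** 2) for j in selected)
            if d > best_d:
                best, best_d = i, d
        selected.append(best)
    return np.array(selected)


def test_fps_hand_worked_example():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0]])
    idx = farthest_point_sample(pts, 3, start_index=0)
    # greedy: start 0, farthest is 10, then 2 (min-dist 2 beats 1's 1)
    np.testing.assert_array_equal(idx, [0, 3, 2])


def test_fps_exhaustive_selection_returns_all():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(20, 3))
    idx = farthest_point_sample(pts, 20)
    assert sorted(idx) == list(range(20))


@pytest.mark.parametrize("n,m,seed", [(50, 10, 0), (200, 37, 1), (500, 120, 2)])
def test_fps_matches_naive_oracle(n, m, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    got = farthest_point_sample(pts, m, start_index=0)
    want = _fps_oracle(pts, m, 0)
    np.testing.assert_array_equal(got, want)


def test_fps_selected_set_properties():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(120, 3))
    prev_min = np.inf
    for m in (5, 20, 60):
        idx = farthest_point_sample(pts, m)
        assert len(set(idx)) == m  # subset of distinct input indices
        sub = pts[idx]
        d = np.linalg.norm(sub[:, None] - sub[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        cur_min = d.min()
        assert cur_min <= prev_min + 1e-12  # packing radius shrinks with m
        prev_min = cur_min
    with pytest.raises(ValueError):
        farthest_point_sample(pts, 121)


def test_partition_conserves_points():
    rng = np.random.default_rng(4)
    pts = rng.uniform([0, 0, 0], [200, 100, 80], size=(2000, 3))
    blocks = partition_blocks(pts, n_blocks=8)
    assert len(blocks) == 8
    assert sum(len(b.points) for b in blocks) == 2000
    joined = np.concatenate([b.to_global() for b in blocks])
    np.testing.assert_allclose(np.sort(joined, axis=0), np.sort(pts, axis=0),
                               atol=1e-9)


def test_partition_long_axis_gets_four_windows():
    rng = np.random.default_rng(5)
    pts = rng.uniform([0, 0, 0], [100, 200, 10], size=(500, 3))  # y is long
    blocks = partition_blocks(pts, n_blocks=8)
    xs = {b.window[0] for b in blocks}
    ys = {b.window[1] for b in blocks}
    assert len(ys) == 4 and len(xs) == 2


def test_partition_with_overlap_covers_everything():
    rng = np.random.default_rng(6)
    pts = rng.uniform(0, 100, size=(800, 3))
    blocks = partition_blocks(pts, n_blocks=8, overlap_fraction=0.25)
    seen = np.zeros(800, dtype=bool)
    for b in blocks:
        seen[b.source_indices] = True
    assert seen.all()


def test_partition_degenerate_cloud():
    pts = np.tile([[3.0, 4.0, 5.0]], (10, 1))
    blocks = partition_blocks(pts, n_blocks=8)
    sizes = sorted(len(b.points) for b in blocks)
    assert sizes == [0] * 7 + [10]


def test_partition_shared_windows_cut_second_cloud():
    rng = np.random.default_rng(7)
    surface = rng.uniform(0, 100, size=(400, 3))
    target = rng.uniform(0, 100, size=(300, 3))
    sblocks = partition_blocks(surface, n_blocks=4)
    tblocks = partition_blocks(target, n_blocks=4,
                               windows=[b.window for b in sblocks])
    for sb, tb in zip(sblocks, tblocks):
        assert sb.window == tb.window
        np.testing.assert_array_equal(sb.origin_transform, tb.origin_transform)
    assert sum(len(b.points) for b in tblocks) == 300


def test_resample_block_contracts(rng):
    big = Block(points=rng.normal(size=(1000, 3)),
                origin_transform=np.zeros(3), block_index=0)
    out = resample_block(big, n_target=256, seed=0)
    assert out.points.shape == (256, 3)
    # FPS downsample keeps members of the original set
    assert all(any(np.allclose(p, q) for q in big.points[:1000]) for p in out.points[:5])

    exact = Block(points=rng.normal(size=(64, 3)),
                  origin_transform=np.zeros(3), block_index=1)
    np.testing.assert_array_equal(resample_block(exact, 64, 0).points, exact.points)

    small = Block(points=rng.normal(size=(10, 3)) * 100,
                  origin_transform=np.zeros(3), block_index=2)
    padded = resample_block(small, n_target=64, seed=1)
    assert padded.points.shape == (64, 3)
    np.testing.assert_array_equal(padded.points[:10], small.points)
    assert len(np.unique(padded.points, axis=0)) >= 10


def test_merge_round_trip_and_sizes(rng):
    pts = rng.uniform([0, 0, 0], [150, 80, 60], size=(4096, 3))
    blocks = partition_blocks(pts, n_blocks=8)
    merged = merge_completed([b.points for b in blocks],
                             [np.empty((0, 3))] * 8,
                             [b.origin_transform for b in blocks])
    np.testing.assert_allclose(np.sort(merged, axis=0), np.sort(pts, axis=0),
                               atol=1e-9)
    preds = [rng.normal(size=(8192, 3)) for _ in range(8)]
    inputs = [rng.normal(size=(8192, 3)) for _ in range(8)]
    full = merge_completed(inputs, preds, [b.origin_transform for b in blocks])
    assert len(full) == 131072  # 8 x (8192 input + 8192 predicted)


def test_merge_validates_inputs():
    with pytest.raises(ValueError):
        merge_completed([np.zeros((1, 3))], [], [])
    with pytest.raises(ValueError):
        merge_completed([np.zeros((1, 3))], [np.zeros((1, 3))],
                        [np.zeros((2, 2))])
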