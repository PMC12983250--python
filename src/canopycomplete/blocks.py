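"""Spatial block partitioning of plot clouds, farthest point sampling and
fixed-size resampling with recorded transforms.

Plot clouds are split by a sliding window over the horizontal bounding
rectangle into eight blocks (4 along the long axis x 2), each translated
to a local origin before entering the network; the recorded translation
maps completed blocks back into plot coordinates exactly.  Coordinates are
never normalized to a unit sphere, so distances stay in physical cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_GRID_SHAPES = {1: (1, 1), 2: (2, 1), 4: (2, 2), 8: (4, 2)}


@dataclass
class Block:
    points: np.ndarray            # (n, 3) local coordinates, cm
    origin_transform: np.ndarray  # (3,) translation subtracted from the source
    block_index: int
    source_indices: np.ndarray | None = None  # indices into the source cloud
    window: tuple | None = None   # ((x0,x1), (y0,y1), (z0,z1)) source coords

    def to_global(self, points: np.ndarray | None = None) -> np.ndarray:
        pts = self.points if points is None else points
        return pts + self.origin_transform


def farthest_point_sample(points: np.ndarray, m: int,
                          start_index: int = 0) -> np.ndarray:
    """Greedy iterative farthest point sampling.

    The first pick is ``start_index``; every subsequent pick maximizes the
    minimum distance to the already-selected set, ties broken by lowest
    index.  Deterministic.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not (1 <= m <= n):
        raise ValueError(f"need 1 <= m <= n, got m={m}, n={n}")
    if not (0 <= start_index < n):
        raise ValueError("start_index out of range")
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start_index
    dist = np.einsum("ij,ij->i", points - points[start_index],
                     points - points[start_index])
    for i in range(1, m):
        pick = int(np.argmax(dist))  # argmax returns the lowest tied index
        selected[i] = pick
        d = points - points[pick]
        np.minimum(dist, np.einsum("ij,ij->i", d, d), out=dist)
    return selected


def _windows(points: np.ndarray, n_blocks: int, overlap_fraction: float):
    lo = points[:, :2].min(axis=0)
    hi = points[:, :2].max(axis=0)
    extent = hi - lo
    shape = _GRID_SHAPES[n_blocks]
    # long horizontal axis gets the finer split
    if extent[1] > extent[0]:
        nx, ny = shape[1], shape[0]
    else:
        nx, ny = shape
    wx = extent[0] / nx if extent[0] > 0 else 1.0
    wy = extent[1] / ny if extent[1] > 0 else 1.0
    z0, z1 = points[:, 2].min(), points[:, 2].max()
    wins = []
    for iy in range(ny):
        for ix in range(nx):
            x0 = lo[0] + ix * wx - overlap_fraction * wx
            x1 = lo[0] + (ix + 1) * wx + overlap_fraction * wx
            y0 = lo[1] + iy * wy - overlap_fraction * wy
            y1 = lo[1] + (iy + 1) * wy + overlap_fraction * wy
            wins.append(((x0, x1), (y0, y1), (z0, z1)))
    return wins, (lo, hi, wx, wy, nx, ny)


def partition_blocks(cloud: np.ndarray, n_blocks: int = 8,
                     overlap_fraction: float = 0.0,
                     windows: list | None = None) -> list[Block]:
    """Split a cloud into grid-window blocks over its horizontal bbox.

    With ``overlap_fraction`` 0 each point lands in exactly one block
    (half-open bins; the last bin is closed so boundary points are kept).
    Pass ``windows`` from another cloud's partition to cut a second cloud
    (e.g. the occluded targets) with identical geometry.
    """
    cloud = np.asarray(cloud, dtype=float)
    if len(cloud) == 0:
        raise ValueError("cannot partition an empty cloud")
    if n_blocks not in _GRID_SHAPES:
        raise ValueError(f"n_blocks must be one of {sorted(_GRID_SHAPES)}")
    if overlap_fraction < 0:
        raise ValueError("overlap_fraction must be >= 0")

    if windows is None:
        windows, _ = _windows(cloud, n_blocks, overlap_fraction)

    blocks = []
    if overlap_fraction == 0:
        # exact assignment by binning: every point in exactly one window
        n_win = len(windows)
        assign = np.full(len(cloud), -1, dtype=np.int64)
        for w_idx, ((x0, x1), (y0, y1), _z) in enumerate(windows):
            inside = ((cloud[:, 0] >= x0) & (cloud[:, 1] >= y0)
                      & (cloud[:, 0] <= x1) & (cloud[:, 1] <= y1))
            fresh = inside & (assign < 0)
            assign[fresh] = w_idx
        assign[assign < 0] = n_win - 1  # numerical stragglers -> last window
        for w_idx, win in enumerate(windows):
            idx = np.flatnonzero(assign == w_idx)
            blocks.append(_make_block(cloud, idx, w_idx, win))
    else:
        for w_idx, win in enumerate(windows):
            (x0, x1), (y0, y1), _z = win
            idx = np.flatnonzero((cloud[:, 0] >= x0) & (cloud[:, 0] <= x1)
                                 & (cloud[:, 1] >= y0) & (cloud[:, 1] <= y1))
            blocks.append(_make_block(cloud, idx, w_idx, win))
    return blocks


def _make_block(cloud, idx, w_idx, win) -> Block:
    (x0, x1), (y0, y1), (z0, z1) = win
    transform = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0, (z0 + z1) / 2.0])
    return Block(points=cloud[idx] - transform, origin_transform=transform,
                 block_index=w_idx, source_indices=idx, window=win)


def resample_block(block: Block, n_target: int = 8192,
                   seed: int = 0, jitter_sigma: float = 0.05) -> Block:
    """Return a copy of ``block`` with exactly ``n_target`` points.

    Oversized blocks are reduced by farthest point sampling; undersized
    blocks keep every original point and pad by re-drawing existing points
    with Gaussian jitter (sigma ``jitter_sigma`` cm).  Metric scale is
    preserved.
    """
    n = len(block.points)
    if n == 0:
        raise ValueError("cannot resample an empty block")
    if n == n_target:
        pts = block.points
    elif n > n_target:
        pts = block.points[farthest_point_sample(block.points, n_target)]
    else:
        rng = np.random.default_rng(seed)
        extra = block.points[rng.integers(0, n, size=n_target - n)]
        extra = extra + rng.normal(0.0, jitter_sigma, size=extra.shape)
        pts = np.concatenate([block.points, extra])
    return Block(points=pts, origin_transform=block.origin_transform,
                 block_index=block.block_index, source_indices=None,
                 window=block.window)


def merge_completed(blocks_inputs: list[np.ndarray],
                    blocks_predictions: list[np.ndarray],
                    transforms: list[np.ndarray]) -> np.ndarray:
    """Map block inputs and predictions back to plot coordinates and merge.

    Output size is the sum of all input and prediction sizes.
    """
    if not (len(blocks_inputs) == len(blocks_predictions) == len(transforms)):
        raise ValueError("inputs, predictions and transforms must have equal length")
    parts = []
    for inp, pred, t in zip(blocks_inputs, blocks_predictions, transforms):
        t = np.asarray(t, dtype=float)
        if t.shape != (3,):
            raise ValueError("each transform must be a 3-vector translation")
        if len(inp):
            parts.append(np.asarray(inp) + t)
        if len(pred):
            parts.append(np.asarray(pred) + t)
    if not parts:
        return np.empty((0, 3))
    return np.concatenate(parts)
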