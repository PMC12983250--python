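"""Chamfer distance, multi-stage/adversarial/total losses and SSIM3D."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from canopycomplete.metrics import (LossConfig, Ssim3dConfig,
                                    adversarial_loss, chamfer_distance,
                                    chamfer_distance_cm, multi_stage_loss,
                                    ssim3d, total_loss)


def _cd_oracle(a, b):
    """O(n^2) double loop over both directions."""
    t1 = np.mean([min(np.sum((x - y) ** 2) for y in b) for x in a])
    t2 = np.mean([min(np.sum((y - x) ** 2) for x in a) for y in b])
    return t1 + t2


def test_chamfer_identity_and_forced_value():
    pts = np.random.default_rng(0).normal(size=(40, 3))
    assert chamfer_distance(pts, pts) == 0.0
    a = np.array([[0.0, 0, 0]])
    b = np.array([[3.0, 4, 0]])
    assert chamfer_distance(a, b) == pytest.approx(50.0)   # 25 + 25
    assert chamfer_distance_cm(a, b) == pytest.approx(10.0)


def test_chamfer_matches_double_loop_oracle(rng):
    for n, m in ((30, 50), (200, 120), (300, 300)):
        a = rng.normal(size=(n, 3)) * 10
        b = rng.normal(size=(m, 3)) * 10
        got = chamfer_distance(a, b)
        want = _cd_oracle(a, b)
        assert got == pytest.approx(want, rel=1e-9)
        assert chamfer_distance(b, a) == pytest.approx(got, rel=1e-12)


def test_chamfer_grows_when_translating_apart(rng):
    a = rng.normal(size=(60, 3))
    vals = [chamfer_distance(a, a + [dx, 0, 0]) for dx in (0.0, 0.5, 1.0, 2.0)]
    assert all(x < y for x, y in zip(vals, vals[1:]))


def test_chamfer_rejects_empty():
    with pytest.raises(ValueError):
        chamfer_distance(np.empty((0, 3)), np.ones((2, 3)))


def test_multi_stage_loss_arithmetic():
    # craft single-point sets with CD exactly 2, 1, 1
    fine, gt_f = np.array([[1.0, 0, 0]]), np.array([[0.0, 0, 0]])   # CD = 2
    mid = np.array([[np.sqrt(0.5), 0, 0]])                          # CD = 1
    coarse = mid.copy()
    got = multi_stage_loss(fine, mid, coarse, gt_f, gt_f, gt_f, alpha=0.1)
    assert got == pytest.approx(2 + 0.1 * 1 + 0.2 * 1, rel=1e-6)
    # alpha = 0 reduces to the fine term
    assert multi_stage_loss(fine, mid, coarse, gt_f, gt_f, gt_f, 0.0) == \
        pytest.approx(2.0, rel=1e-6)


def test_multi_stage_loss_zero_at_perfect_prediction(rng):
    f = rng.normal(size=(32, 3))
    m = rng.normal(size=(16, 3))
    c = rng.normal(size=(8, 3))
    assert multi_stage_loss(f, m, c, f, m, c, alpha=0.1) == 0.0
    assert multi_stage_loss(f, m, c, f, m, c, alpha=0.5) >= 0.0


def test_adversarial_loss_closed_forms():
    half = np.array([0.5])
    assert adversarial_loss(half, half) == pytest.approx(2 * np.log(0.5))
    near = np.array([1 - 1e-12])
    low = np.array([1e-12])
    assert adversarial_loss(near, low) == pytest.approx(0.0, abs=1e-9)
    a = adversarial_loss(np.array([0.3, 0.3]), np.array([0.6, 0.6]))
    assert a == pytest.approx(2 * adversarial_loss(np.array([0.3]),
                                                   np.array([0.6])))
    with pytest.raises(ValueError):
        adversarial_loss(np.array([0.0]), np.array([0.5]))
    with pytest.raises(ValueError):
        adversarial_loss(np.array([0.5]), np.array([1.0]))


def test_total_loss_weighting_and_linearity():
    assert total_loss(1.0, -1.0) == pytest.approx(0.8)
    cfg = LossConfig(lambda_com=1.0, lambda_adv=0.0)
    assert total_loss(3.0, 99.0, cfg) == pytest.approx(3.0)
    assert total_loss(2.0, 4.0) == pytest.approx(
        2 * total_loss(1.0, 2.0), rel=1e-12)


def _ssim_oracle(x, y, radius, eps):
    fx = np.array([np.sum(np.linalg.norm(x - p, axis=1) <= radius) - 1
                   for p in x], dtype=float)
    fy = np.array([np.sum(np.linalg.norm(y - p, axis=1) <= radius) - 1
                   for p in y], dtype=float)
    raws = []
    for i, q in enumerate(x):
        j = np.argmin(np.linalg.norm(y - q, axis=1))
        raws.append(abs(fx[i] - fy[j]) / (max(abs(fx[i]), abs(fy[j])) + eps))
    return 1.0 - np.mean(raws)


def test_ssim3d_identical_clouds_score_one(rng):
    pts = rng.normal(size=(100, 3)) * 5
    assert ssim3d(pts, pts) == pytest.approx(1.0)
    assert ssim3d(pts, pts, Ssim3dConfig(feature="height")) == pytest.approx(1.0)


def test_ssim3d_maximal_feature_difference_scores_zero():
    # paired clouds whose height features are 1 vs 0 everywhere
    xy = np.mgrid[0:5, 0:5].reshape(2, -1).T.astype(float)
    x = np.column_stack([xy, np.ones(len(xy))])
    y = np.column_stack([xy, np.zeros(len(xy))])
    cfg = Ssim3dConfig(feature="height", epsilon=1e-12)
    assert ssim3d(x, y, cfg) == pytest.approx(0.0, abs=1e-9)


def test_ssim3d_matches_bruteforce_oracle(rng):
    x = rng.normal(size=(200, 3)) * 3
    y = x + rng.normal(size=(200, 3)) * 0.5
    cfg = Ssim3dConfig(radius=2.0, epsilon=1e-8)
    got = ssim3d(x, y, cfg)
    want = _ssim_oracle(x, y, 2.0, 1e-8)
    assert got == pytest.approx(want, rel=1e-9)
    assert 0.0 <= got <= 1.0


def test_ssim3d_translation_invariance_with_density_feature(rng):
    x = rng.normal(size=(150, 3))
    y = rng.normal(size=(150, 3))
    base = ssim3d(x, y)
    shifted = ssim3d(x + [10, -4, 2], y + [10, -4, 2])
    assert shifted == pytest.approx(base, rel=1e-9)


def test_ssim3d_validation():
    with pytest.raises(ValueError):
        ssim3d(np.empty((0, 3)), np.ones((3, 3)))
    with pytest.raises(ValueError):
        Ssim3dConfig(feature="curvature").validate()
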