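"""Point-cloud losses and similarity metrics.

Chamfer distance is the symmetric mean nearest-neighbor *squared* distance

    d_CD(S1, S2) = 1/|S1| sum_x min_y ||x-y||^2 + 1/|S2| sum_y min_x ||y-x||^2

computed on raw cm coordinates.  Because squared distances are not in cm,
an unsquared variant (mean nearest-neighbor Euclidean distance, reported
in cm) is exposed as well; logs and reports always say which one is used.

The multi-stage completion loss combines Chamfer terms at the three
decoder resolutions, L = CD(fine) + alpha*CD(middle) + 2*alpha*CD(coarse).

SSIM3D compares two clouds through a per-point feature F (local density by
default, height optionally): each query point q of X is paired with its
nearest neighbor p in Y and the normalized absolute feature difference
|F_X(q)-F_Y(p)| / (max(|F_X(q)|,|F_Y(p)|)+eps) is averaged.  The raw mean
is 0 for identical clouds, so the reported similarity is 1 - raw (clamped
to [0, 1]); the raw value is also available.  Note the feature choice and
the one-directional nearest-neighbor pairing are conventions of this
package — both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.01          # multi-stage weight, scheduled during training
    lambda_com: float = 0.9
    lambda_adv: float = 0.1
    batch_size: int = 8

    def validate(self) -> None:
        if self.alpha < 0 or self.lambda_com < 0 or self.lambda_adv < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class Ssim3dConfig:
    feature: str = "local_density"   # or "height"
    radius: float = 2.0              # cm, density neighborhood
    epsilon: float = 1e-8

    def validate(self) -> None:
        if self.feature not in ("local_density", "height"):
            raise ValueError(f"unknown SSIM3D feature {self.feature!r}")
        if self.radius <= 0 or self.epsilon <= 0:
            raise ValueError("radius and epsilon must be > 0")


def _check_cloud(arr, name) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or len(arr) == 0:
        raise ValueError(f"{name} must be a non-empty (n, 3) array")
    return arr


def chamfer_distance(s1: np.ndarray, s2: np.ndarray, squared: bool = True) -> float:
    """Symmetric Chamfer distance; squared (default) or Euclidean variant."""
    s1 = _check_cloud(s1, "S1")
    s2 = _check_cloud(s2, "S2")
    d12, _ = cKDTree(s2).query(s1, k=1)
    d21, _ = cKDTree(s1).query(s2, k=1)
    if squared:
        return float(np.mean(d12 ** 2) + np.mean(d21 ** 2))
    return float(np.mean(d12) + np.mean(d21))


def chamfer_distance_cm(s1: np.ndarray, s2: np.ndarray) -> float:
    """Unsquared Chamfer variant: sum of mean NN Euclidean distances, cm."""
    return chamfer_distance(s1, s2, squared=False)


def multi_stage_loss(fine, middle, coarse, gt_fine, gt_middle, gt_coarse,
                     alpha: float) -> float:
    """CD(fine, GT) + alpha*CD(middle, GT') + 2*alpha*CD(coarse, GT'')."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    for pred, gt, name in ((fine, gt_fine, "fine"), (middle, gt_middle, "middle"),
                           (coarse, gt_coarse, "coarse")):
        if np.asarray(pred).shape[1:] != (3,) or np.asarray(gt).shape[1:] != (3,):
            raise ValueError(f"{name} prediction/target must be (n, 3)")
    return (chamfer_distance(fine, gt_fine)
            + alpha * chamfer_distance(middle, gt_middle)
            + 2 * alpha * chamfer_distance(coarse, gt_coarse))


def adversarial_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """GAN value sum(log D(y_i)) + sum(log(1 - D(F(x_i)))).

    This is the classic minimax objective the discriminator maximizes; the
    training loop uses the non-saturating surrogate for generator
    gradients but reports this literal value.
    """
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    if d_real.shape != d_fake.shape:
        raise ValueError("d_real and d_fake must have equal length")
    for arr, name in ((d_real, "d_real"), (d_fake, "d_fake")):
        if np.any(arr <= 0) or np.any(arr >= 1):
            raise ValueError(f"{name} probabilities must lie in the open interval (0, 1)")
    return float(np.sum(np.log(d_real)) + np.sum(np.log(1.0 - d_fake)))


def total_loss(l_com: float, l_adv: float, config: LossConfig = LossConfig()) -> float:
    """lambda_com * L_com + lambda_adv * L_adv (defaults 0.9 / 0.1)."""
    config.validate()
    if not (np.isfinite(l_com) and np.isfinite(l_adv)):
        raise ValueError("loss terms must be finite")
    return config.lambda_com * l_com + config.lambda_adv * l_adv


def _feature(points: np.ndarray, config: Ssim3dConfig) -> np.ndarray:
    if config.feature == "height":
        return points[:, 2].astype(float)
    tree = cKDTree(points)
    # neighbor count within radius, excluding the point itself
    counts = tree.query_ball_point(points, config.radius, return_length=True)
    return np.asarray(counts, dtype=float) - 1.0


def ssim3d(x: np.ndarray, y: np.ndarray,
           config: Ssim3dConfig = Ssim3dConfig(),
           return_raw: bool = False) -> float:
    """Structural similarity between clouds X and Y in [0, 1] (1 = identical)."""
    config.validate()
    x = _check_cloud(x, "X")
    y = _check_cloud(y, "Y")
    fx = _feature(x, config)
    fy = _feature(y, config)
    _, pair = cKDTree(y).query(x, k=1)
    fy_paired = fy[pair]
    raw = float(np.mean(np.abs(fx - fy_paired)
                        / (np.maximum(np.abs(fx), np.abs(fy_paired)) + config.epsilon)))
    if return_raw:
        return raw
    return float(np.clip(1.0 - raw, 0.0, 1.0))
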