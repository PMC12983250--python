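"""The population canopy completion network: a GAN whose generator pairs a
multi-resolution dynamic-graph encoder with a point pyramid decoder.

Encoder (MRDG).  The input block (8192 points by default) is down-sampled
twice by iterative farthest point sampling to 4096 and 2048 points.  At
each of the three resolutions a stack of five dynamic graph convolution
layers (DGCFE) with channels {64, 128, 256, 512, 1024} extracts features;
a DGCFE layer rebuilds the k-nearest-neighbor graph in the *current*
feature space (layer 1 uses coordinate space), forms per-edge features
concat(center, neighbor - center), applies a shared linear + batchnorm +
ReLU transform and aggregates edges by per-dimension max.  The per-point
outputs of layers 2-5 are global-max-pooled and concatenated across the
three resolutions into a latent vector of 3 x (128+256+512+1024) = 5760
dimensions at the default width — the only pooling of the stated channel
list over three resolutions that yields the stated latent size, so the
64-channel first layer feeds later layers but is not pooled.

Decoder (PPD).  Fully connected stages map the latent vector to a coarse
cloud (2048 x 3); each finer stage emits two children per parent point as
parent + learned offset, giving 4096 then 8192 points.  Output layers are
linear (no activation) and the decoder uses no batch normalization.

Discriminator.  A per-point shared MLP (64 -> 128 -> 256, batchnorm+ReLU)
followed by global max pooling and a dense head (256 -> 128 -> 1) with a
sigmoid, judging whether a cloud of missing-region points looks real.

The completed cloud is the union of the input block and the fine
prediction (8192 + 8192 = 16384 points at defaults).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .blocks import farthest_point_sample
from .nn import Adam, BatchNorm, Linear, Module, Tensor, no_grad
from .nn.layers import edge_features_op, kmax_aggregate_op


@dataclass(frozen=True)
class EncoderConfig:
    k_neighbors: int = 20
    layer_channels: tuple = (64, 128, 256, 512, 1024)
    resolutions: tuple = (8192, 4096, 2048)
    width_scale: float = 1.0
    #: ablation toggle: "dgcfe" (dynamic graph layers) or "mlp" (per-point
    #: shared MLP layers, no neighborhood graph)
    feature_extractor: str = "dgcfe"

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if len(self.resolutions) not in (1, 3) or list(self.resolutions) != sorted(
                set(self.resolutions), reverse=True):
            raise ValueError("resolutions must be three strictly decreasing sizes "
                             "(or a single size for the single-resolution ablation)")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        if self.resolutions[-1] <= self.k_neighbors:
            raise ValueError("smallest resolution must exceed k_neighbors")
        if self.feature_extractor not in ("dgcfe", "mlp"):
            raise ValueError("feature_extractor must be 'dgcfe' or 'mlp'")

    @property
    def scaled_channels(self) -> tuple:
        return tuple(max(1, int(round(c * self.width_scale)))
                     for c in self.layer_channels)

    @property
    def latent_dim(self) -> int:
        return len(self.resolutions) * sum(self.scaled_channels[1:])


@dataclass(frozen=True)
class DecoderConfig:
    n_coarse: int = 2048
    n_middle: int = 4096
    n_fine: int = 8192
    width_scale: float = 1.0
    #: fixed gains (cm) on the linear output heads: the coarse stage and
    #: the middle/fine child offsets.  Hidden activations are O(1) while
    #: canopy offsets span centimeters, so a constant physical gain keeps
    #: the head weights O(1); all distances remain in cm.
    output_gain: tuple = (5.0, 2.0, 1.0)
    #: ablation toggle: collapse the pyramid into one fully connected head
    #: that emits the fine cloud directly (coarse/middle become slices)
    single_stage: bool = False

    def validate(self) -> None:
        if not (self.n_coarse * 2 == self.n_middle and self.n_middle * 2 == self.n_fine):
            raise ValueError("decoder sizes must double per stage (coarse*2=middle, middle*2=fine)")
        if len(self.output_gain) != 3 or any(g <= 0 for g in self.output_gain):
            raise ValueError("output_gain must be three positive factors")

    @property
    def hidden(self) -> int:
        return max(32, int(round(1024 * self.width_scale)))


@dataclass
class DecoderOutputs:
    """Coarse/middle/fine predictions, stored flat as (B*n, 3) Tensors."""

    coarse: Tensor
    middle: Tensor
    fine: Tensor
    batch: int
    sizes: tuple

    def numpy(self, stage: str = "fine") -> np.ndarray:
        t = getattr(self, stage)
        n = {"coarse": self.sizes[0], "middle": self.sizes[1],
             "fine": self.sizes[2]}[stage]
        return t.data.reshape(self.batch, n, 3)


def knn_indices(x: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors (self excluded) of each row of (n, c) ``x``."""
    n = len(x)
    if n <= k:
        raise ValueError(f"need more points than neighbors, got n={n}, k={k}")
    sq = np.einsum("ij,ij->i", x, x)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d, np.inf)
    idx = np.argpartition(d, k - 1, axis=1)[:, :k]
    # canonical order inside the neighborhood (distance, then index)
    part = np.take_along_axis(d, idx, axis=1)
    order = np.lexsort((idx, part), axis=1)
    return np.take_along_axis(idx, order, axis=1)


class DGCFELayer(Module):
    """One dynamic graph convolution: shared edge transform + max aggregation.

    The shared per-edge linear map is applied to concat(center, neighbor -
    center); edges are aggregated per point by channel-wise max, then
    batch-normalized and rectified.  (ReLU commutes with the max, and the
    edge bias is absorbed by the batchnorm, so normalizing after
    aggregation computes the same activations at an eighth of the memory
    traffic of normalizing every edge.)
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.linear = Linear(2 * c_in, c_out, rng, bias=False)
        self.bn = BatchNorm(c_out)

    def __call__(self, x: Tensor, batch: int, n: int) -> Tensor:
        """x is (batch*n, c_in); returns (batch*n, c_out)."""
        if n <= self.k:
            raise ValueError(f"layer needs n > k, got n={n}, k={self.k}")
        c = x.data.shape[1]
        feats = x.data.reshape(batch, n, c)
        nbr_idx = np.empty((batch, n, self.k), dtype=np.int64)
        for b in range(batch):
            nbr_idx[b] = knn_indices(feats[b], self.k) + b * n
        edge = edge_features_op(x, nbr_idx.reshape(-1), self.k)
        h = kmax_aggregate_op(self.linear(edge), batch * n, self.k)
        return self.bn(h).relu()


class PointMLPLayer(Module):
    """Ablation stand-in for a DGCFE layer: per-point linear + BN + ReLU."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.linear = Linear(c_in, c_out, rng, bias=False)
        self.bn = BatchNorm(c_out)

    def __call__(self, x: Tensor, batch: int, n: int) -> Tensor:
        return self.bn(self.linear(x)).relu()


class MRDGEncoder(Module):
    """Multi-resolution dynamic graph encoder producing the latent vector."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        channels = config.scaled_channels
        layer_cls = DGCFELayer if config.feature_extractor == "dgcfe" else PointMLPLayer
        self.stacks = []
        for _ in config.resolutions:
            layers, c_prev = [], 3
            for c_out in channels:
                layers.append(layer_cls(c_prev, c_out, config.k_neighbors, rng))
                c_prev = c_out
            self.stacks.append(layers)

    @staticmethod
    def _fps_start(points: np.ndarray) -> int:
        # permutation-invariant start: the point farthest from the centroid
        d = points - points.mean(axis=0)
        return int(np.argmax(np.einsum("ij,ij->i", d, d)))

    def multiresolution_points(self, points: np.ndarray) -> list[np.ndarray]:
        """Nested FPS subsets of one (n, 3) cloud at the configured resolutions."""
        levels = [points]
        for r in self.config.resolutions[1:]:
            prev = levels[-1]
            levels.append(prev[farthest_point_sample(prev, r, self._fps_start(prev))])
        return levels

    def __call__(self, points: np.ndarray, multires: list | None = None,
                 return_point_features: bool = False):
        """points: (batch, n, 3) numpy, n = resolutions[0]; returns (batch, latent).

        ``multires`` optionally supplies precomputed per-sample
        multiresolution subsets (as from :meth:`multiresolution_points`),
        so repeated passes over a fixed dataset skip the FPS cost.  With
        ``return_point_features`` the per-point features of the final layer
        at the coarsest resolution are returned alongside the latent (the
        decoder uses them to condition offsets on local geometry).
        """
        points = np.asarray(points, dtype=np.float32)
        if points.ndim != 3 or points.shape[2] != 3:
            raise ValueError("encoder input must be (batch, n, 3)")
        batch, n, _ = points.shape
        if n != self.config.resolutions[0]:
            raise ValueError(
                f"encoder expects blocks of {self.config.resolutions[0]} points, got {n}")
        per_sample = (multires if multires is not None
                      else [self.multiresolution_points(points[b]) for b in range(batch)])
        pooled = []
        coarse_feats = None
        for level, n_level in enumerate(self.config.resolutions):
            coords = np.stack([per_sample[b][level] for b in range(batch)])
            x = Tensor(coords.reshape(batch * n_level, 3))
            for i, layer in enumerate(self.stacks[level]):
                x = layer(x, batch, n_level)
                if i >= 1:  # layers 2..5 contribute to the latent
                    pooled.append(x.reshape(batch, n_level, -1).max(axis=1))
            if level == len(self.config.resolutions) - 1:
                coarse_feats = x  # (batch*n3, channels[-1])
        latent = Tensor.concat(pooled, axis=1)
        if return_point_features:
            return latent, coarse_feats
        return latent


class PPDDecoder(Module):
    """Point pyramid decoder: latent -> coarse -> middle -> fine."""

    def __init__(self, config: DecoderConfig, latent_dim: int,
                 rng: np.random.Generator, anchor_feat_dim: int | None = None):
        config.validate()
        self.config = config
        h = config.hidden
        self.fc1 = Linear(latent_dim, h, rng)
        self.fc2 = Linear(h, h, rng)
        self.head_coarse = Linear(h, config.n_coarse * 3, rng)
        self.head_middle = Linear(h, config.n_coarse * 2 * 3, rng)
        self.head_fine = Linear(h, config.n_middle * 2 * 3, rng)
        if config.single_stage:
            self.head_single = Linear(h, config.n_fine * 3, rng)
        # per-anchor heads: shared MLPs over concat(local feature, global h)
        self.anchor_feat_dim = anchor_feat_dim
        if anchor_feat_dim is not None:
            g = anchor_feat_dim + h
            hidden_a = max(32, anchor_feat_dim // 2)
            self.anchor_hidden = Linear(g, hidden_a, rng)
            self.anchor_coarse = Linear(hidden_a, 3, rng)
            self.anchor_middle = Linear(hidden_a, 2 * 3, rng)
            self.anchor_fine = Linear(hidden_a, 4 * 3, rng)

    @staticmethod
    def _children(parent: Tensor, offsets: Tensor, batch: int, n_parent: int) -> Tensor:
        """Two children per parent: parent coordinates + learned offsets."""
        parent_idx = np.repeat(np.arange(batch * n_parent), 2)
        return parent.gather_rows(parent_idx) + offsets

    def __call__(self, latent: Tensor,
                 anchors: np.ndarray | None = None) -> DecoderOutputs:
        """Decode a latent batch; optionally seed the coarse stage.

        Without ``anchors`` the coarse cloud is regressed directly from the
        latent vector.  With ``anchors`` — an (batch, n_coarse, 3) array of
        observed surface points (the generator passes the encoder's
        coarsest FPS subset) — the coarse stage predicts *offsets from the
        observed surface* instead of absolute coordinates, which keeps the
        regression local to where canopy structure already exists.
        """
        if not np.all(np.isfinite(latent.data)):
            raise ValueError("latent vector contains non-finite values")
        batch = latent.data.shape[0]
        cfg = self.config
        g_c, g_m, g_f = cfg.output_gain
        h = self.fc2(self.fc1(latent).relu()).relu()
        if cfg.single_stage:
            return self._single_stage(h, batch, anchors)
        coarse = (self.head_coarse(h) * g_c).reshape(batch * cfg.n_coarse, 3)
        if anchors is not None:
            anchors = np.asarray(anchors, dtype=np.float32)
            if anchors.shape != (batch, cfg.n_coarse, 3):
                raise ValueError("anchors must be (batch, n_coarse, 3)")
            coarse = coarse + Tensor(anchors.reshape(batch * cfg.n_coarse, 3))
        off_m = (self.head_middle(h) * g_m).reshape(batch * cfg.n_middle, 3)
        middle = self._children(coarse, off_m, batch, cfg.n_coarse)
        off_f = (self.head_fine(h) * g_f).reshape(batch * cfg.n_fine, 3)
        fine = self._children(middle, off_f, batch, cfg.n_middle)
        return DecoderOutputs(coarse=coarse, middle=middle, fine=fine,
                              batch=batch,
                              sizes=(cfg.n_coarse, cfg.n_middle, cfg.n_fine))

    def _single_stage(self, h: Tensor, batch: int,
                      anchors: np.ndarray | None) -> DecoderOutputs:
        """Ablation path: one fully connected head emits the fine cloud;
        the coarse and middle outputs are leading slices of it so the
        multi-stage interfaces keep working."""
        cfg = self.config
        fine = (self.head_single(h) * cfg.output_gain[0]).reshape(
            batch * cfg.n_fine, 3)
        def sl(n):
            idx = (np.arange(batch)[:, None] * cfg.n_fine + np.arange(n)).ravel()
            return fine.gather_rows(idx)
        return DecoderOutputs(coarse=sl(cfg.n_coarse), middle=sl(cfg.n_middle),
                              fine=fine, batch=batch,
                              sizes=(cfg.n_coarse, cfg.n_middle, cfg.n_fine))

    def anchored(self, latent: Tensor, anchors: np.ndarray,
                 anchor_features: Tensor) -> DecoderOutputs:
        """Decode offsets around observed anchor points.

        ``anchors`` is (batch, n_coarse, 3); ``anchor_features`` is the
        encoder's per-point feature tensor at the coarsest resolution,
        flat (batch*n_coarse, c).  Every output point is an anchor plus a
        learned offset predicted by a shared per-anchor MLP from the
        anchor's local features concatenated with the global code, so the
        same local completion rule applies wherever similar geometry
        occurs.  The two-children-per-parent pyramid structure of the
        plain path is preserved.
        """
        if self.anchor_feat_dim is None:
            raise ValueError("decoder was built without anchor heads")
        if not np.all(np.isfinite(latent.data)):
            raise ValueError("latent vector contains non-finite values")
        batch = latent.data.shape[0]
        cfg = self.config
        if cfg.single_stage:
            h = self.fc2(self.fc1(latent).relu()).relu()
            return self._single_stage(h, batch, anchors)
        g_c, g_m, g_f = cfg.output_gain
        anchors = np.asarray(anchors, dtype=np.float32)
        if anchors.shape != (batch, cfg.n_coarse, 3):
            raise ValueError("anchors must be (batch, n_coarse, 3)")
        h = self.fc2(self.fc1(latent).relu()).relu()
        hb = h.gather_rows(np.repeat(np.arange(batch), cfg.n_coarse))
        g = self.anchor_hidden(Tensor.concat([anchor_features, hb], axis=1)).relu()
        coarse = Tensor(anchors.reshape(-1, 3)) + self.anchor_coarse(g) * g_c
        off_m = (self.anchor_middle(g) * g_m).reshape(batch * cfg.n_middle, 3)
        middle = self._children(coarse, off_m, batch, cfg.n_coarse)
        off_f = (self.anchor_fine(g) * g_f).reshape(batch * cfg.n_fine, 3)
        fine = self._children(middle, off_f, batch, cfg.n_middle)
        return DecoderOutputs(coarse=coarse, middle=middle, fine=fine,
                              batch=batch,
                              sizes=(cfg.n_coarse, cfg.n_middle, cfg.n_fine))


class Discriminator(Module):
    """Point-cloud realism score in the open interval (0, 1)."""

    def __init__(self, rng: np.random.Generator, width_scale: float = 1.0):
        def s(c):
            return max(4, int(round(c * width_scale)))
        self.lin1 = Linear(3, s(64), rng)
        self.bn1 = BatchNorm(s(64))
        self.lin2 = Linear(s(64), s(128), rng)
        self.bn2 = BatchNorm(s(128))
        self.lin3 = Linear(s(128), s(256), rng)
        self.bn3 = BatchNorm(s(256))
        self.head1 = Linear(s(256), s(128), rng)
        self.head2 = Linear(s(128), 1, rng)

    def __call__(self, clouds) -> Tensor:
        """clouds: (batch, m, 3) numpy array or flat (batch*m, 3) Tensor."""
        if isinstance(clouds, Tensor):
            raise TypeError("pass (x, batch, m) via score() for Tensor input")
        clouds = np.asarray(clouds, dtype=np.float32)
        batch, m, _ = clouds.shape
        return self.score(Tensor(clouds.reshape(batch * m, 3)), batch, m)

    def score(self, x: Tensor, batch: int, m: int) -> Tensor:
        if m < 8:
            raise ValueError("discriminator needs clouds of at least 8 points")
        h = self.bn1(self.lin1(x)).relu()
        h = self.bn2(self.lin2(h)).relu()
        h = self.bn3(self.lin3(h)).relu()
        g = h.reshape(batch, m, -1).max(axis=1)
        g = self.head1(g).relu()
        logits = self.head2(g).reshape(batch)
        return logits.sigmoid()


@dataclass(frozen=True)
class GeneratorConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)

    @staticmethod
    def scaled(n_fine: int = 8192, width_scale: float = 1.0,
               k_neighbors: int = 20) -> "GeneratorConfig":
        """Convenience constructor tying decoder sizes to the block size."""
        return GeneratorConfig(
            encoder=EncoderConfig(
                k_neighbors=k_neighbors,
                resolutions=(n_fine, n_fine // 2, n_fine // 4),
                width_scale=width_scale),
            decoder=DecoderConfig(
                n_coarse=n_fine // 4, n_middle=n_fine // 2, n_fine=n_fine,
                width_scale=width_scale))


class Generator(Module):
    """Encoder + decoder; predicts the missing region of one block."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = MRDGEncoder(config.encoder, rng)
        self.decoder = PPDDecoder(
            config.decoder, config.encoder.latent_dim, rng,
            anchor_feat_dim=config.encoder.scaled_channels[-1])
        self._trained = False

    def __call__(self, points: np.ndarray,
                 multires: list | None = None) -> DecoderOutputs:
        """Forward pass: encode, then decode offsets around surface anchors.

        The coarse stage is seeded on the encoder's coarsest FPS subset of
        the observed block, so the decoder refines geometry where the
        canopy actually is.
        """
        points = np.asarray(points, dtype=np.float32)
        if multires is None and points.ndim == 3:
            multires = [self.encoder.multiresolution_points(points[b])
                        for b in range(points.shape[0])]
        latent, feats = self.encoder(points, multires=multires,
                                     return_point_features=True)
        n_coarse = self.config.decoder.n_coarse
        if len(multires[0][-1]) != n_coarse:
            # ablation configurations without a matching coarsest level
            # fall back to the plain latent-only decoding path
            return self.decoder(latent)
        anchors = np.stack([m[-1] for m in multires])
        return self.decoder.anchored(latent, anchors, feats)

    def complete_block(self, block_points: np.ndarray) -> np.ndarray:
        """Input block union fine prediction (size 2x block at defaults)."""
        block_points = np.asarray(block_points, dtype=np.float32)
        if block_points.ndim != 2 or block_points.shape[1] != 3:
            raise ValueError("block must be (n, 3)")
        if len(block_points) != self.config.encoder.resolutions[0]:
            raise ValueError("block size does not match the configured input size; "
                             "completing an already-completed cloud is undefined")
        if not self._trained:
            warnings.warn("generator weights are untrained; predictions are arbitrary",
                          stacklevel=2)
        self.train_mode(False)
        with no_grad():
            outputs = self(block_points[None])
        return np.concatenate([block_points, outputs.numpy("fine")[0]])


def chamfer_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Differentiable symmetric squared Chamfer distance.

    ``pred`` is a flat (n, 3) Tensor, ``target`` a (m, 3) array.  Nearest
    neighbors are matched on current values; gradients flow through the
    matched pairs (the standard subgradient of the min).
    """
    target = np.asarray(target, dtype=np.float32)
    _, idx1 = cKDTree(target).query(pred.data, k=1)
    diff1 = pred - Tensor(target[idx1])
    t1 = (diff1 ** 2.0).sum(axis=1).mean()
    _, idx2 = cKDTree(pred.data).query(target, k=1)
    diff2 = pred.gather_rows(idx2) - Tensor(target)
    t2 = (diff2 ** 2.0).sum(axis=1).mean()
    return t1 + t2


def multi_stage_loss_tensor(outputs: DecoderOutputs,
                            gt_fine: np.ndarray, gt_middle: np.ndarray,
                            gt_coarse: np.ndarray, alpha: float,
                            sample: int = 0) -> Tensor:
    """Differentiable multi-stage loss for one sample of a batch."""
    nc, nm, nf = outputs.sizes
    sl = lambda t, n: t.gather_rows(np.arange(sample * n, (sample + 1) * n))
    loss = chamfer_loss(sl(outputs.fine, nf), gt_fine)
    loss = loss + alpha * chamfer_loss(sl(outputs.middle, nm), gt_middle)
    loss = loss + (2 * alpha) * chamfer_loss(sl(outputs.coarse, nc), gt_coarse)
    return loss
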