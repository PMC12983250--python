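"""GAN training loop for the completion network.

Each optimization step runs the generator on a batch of surface blocks,
updates the discriminator (real = ground-truth occluded clouds resampled
to the fine size, fake = fine predictions), then updates the generator on
the weighted total loss  L = lambda_com * L_com + lambda_adv * L_adv
(0.9 / 0.1 by default).  The multi-resolution weight alpha follows the
schedule 0.01 for epochs [0, 30), 0.05 for [30, 80), 0.1 afterwards.
Adam, learning rate 1e-4, batch size 8.  The validation completion loss
is evaluated every 10 epochs and the checkpoint is persisted only when it
improves; training stops at max_epochs or once the training loss drops
below ``stop_loss``.

The generator's adversarial gradient uses the non-saturating form
-log D(F(x)); the logged L_adv value is the literal GAN objective
sum log D(y) + sum log(1 - D(F(x))).
"""

from __future__ import annotations

import csv
import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .blocks import farthest_point_sample
from .metrics import adversarial_loss, chamfer_distance
from .model import (Discriminator, Generator, GeneratorConfig, chamfer_loss,
                    multi_stage_loss_tensor)
from .nn import Adam, Tensor, no_grad

_PROB_EPS = 1e-6


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 200
    stop_loss: float = 0.1
    alpha_schedule: tuple = ((0, 0.01), (30, 0.05), (80, 0.1))
    val_every: int = 10
    lambda_com: float = 0.9
    lambda_adv: float = 0.1
    lr_gamma: float = 1.0        # per-epoch multiplicative lr decay
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        epochs = [e for e, _ in self.alpha_schedule]
        if epochs != sorted(epochs):
            raise ValueError("alpha schedule breakpoints must be ordered")
        if self.batch_size < 1 or self.max_epochs < 1 or self.val_every < 1:
            raise ValueError("batch_size, max_epochs, val_every must be >= 1")

    def alpha_for_epoch(self, epoch: int) -> float:
        """Half-open schedule intervals: [0,30) -> 0.01, [30,80) -> 0.05, ..."""
        alpha = self.alpha_schedule[0][1]
        for start, value in self.alpha_schedule:
            if epoch >= start:
                alpha = value
        return alpha


def resample_points(points: np.ndarray, n_target: int, seed: int = 0,
                    jitter_sigma: float = 0.05) -> np.ndarray:
    """Fixed-size resampling: FPS down, or pad with jittered re-draws."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        raise ValueError("cannot resample an empty cloud")
    if n == n_target:
        return points
    if n > n_target:
        return points[farthest_point_sample(points, n_target)]
    rng = np.random.default_rng(seed)
    extra = points[rng.integers(0, n, size=n_target - n)]
    extra = extra + rng.normal(0.0, jitter_sigma, size=extra.shape)
    return np.concatenate([points, extra])


def build_targets(target_points: np.ndarray, sizes: tuple, seed: int = 0):
    """Fine/middle/coarse ground truths; middle and coarse are nested FPS
    index subsets of the fine target."""
    nc, nm, nf = sizes
    gt_fine = resample_points(target_points, nf, seed=seed)
    idx_m = farthest_point_sample(gt_fine, nm)
    gt_middle = gt_fine[idx_m]
    gt_coarse = gt_middle[farthest_point_sample(gt_middle, nc)]
    return gt_fine, gt_middle, gt_coarse


def _clamped_log(p: Tensor) -> Tensor:
    # keep probabilities strictly inside (0, 1) so log stays finite in f32
    return (p * (1.0 - 2.0 * _PROB_EPS) + _PROB_EPS).log()


@dataclass
class TrainResult:
    history: list
    checkpoint_best: Path | None
    checkpoint_last: Path | None
    generator: Generator
    discriminator: Discriminator
    best_val_loss: float


def train(train_samples, val_samples, gen_config: GeneratorConfig,
          config: TrainConfig = TrainConfig(),
          out_dir: str | Path | None = None) -> TrainResult:
    """Train the completion GAN; see the module docstring for the scheme.

    ``train_samples``/``val_samples`` are sequences of objects with
    ``input_points`` (block-size surface points, local cm coordinates) and
    ``target_points`` (occluded points, same frame).
    """
    config.validate()
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("both train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed)
    gen = Generator(gen_config, seed=int(rng.integers(2**31 - 1)))
    disc = Discriminator(np.random.default_rng(int(rng.integers(2**31 - 1))),
                         width_scale=gen_config.encoder.width_scale)
    opt_g = Adam(gen.parameters(), lr=config.learning_rate)
    opt_d = Adam(disc.parameters(), lr=config.learning_rate)

    sizes = (gen_config.decoder.n_coarse, gen_config.decoder.n_middle,
             gen_config.decoder.n_fine)
    nf = sizes[2]
    inputs = np.stack([np.asarray(s.input_points, np.float32) for s in train_samples])
    targets = [build_targets(s.target_points, sizes, seed=config.seed + 17 * i)
               for i, s in enumerate(train_samples)]
    # FPS subsets of fixed inputs never change: compute once, reuse per epoch
    multires_cache = [gen.encoder.multiresolution_points(inp) for inp in inputs]

    out_dir = Path(out_dir) if out_dir is not None else None
    best_path = last_path = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        best_path = out_dir / "best.ckpt"
        last_path = out_dir / "last.ckpt"

    history = []
    best_val = np.inf
    n_train = len(train_samples)
    for epoch in range(config.max_epochs):
        alpha = config.alpha_for_epoch(epoch)
        if epoch > 0 and config.lr_gamma != 1.0:
            opt_g.lr *= config.lr_gamma
            opt_d.lr *= config.lr_gamma
        order = rng.permutation(n_train)
        ep_com, ep_adv, ep_total, n_batches = 0.0, 0.0, 0.0, 0
        gen.train_mode(True)
        disc.train_mode(True)
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_in = inputs[idx]
            outputs = gen(batch_in, multires=[multires_cache[i] for i in idx])
            fake_np = outputs.numpy("fine")
            real_np = np.stack([targets[i][0] for i in idx]).astype(np.float32)

            # discriminator step (maximize the GAN value)
            opt_d.zero_grad()
            d_real = disc(real_np)
            d_fake = disc(fake_np)
            loss_d = -( _clamped_log(d_real).mean() + _clamped_log(1.0 - d_fake).mean())
            loss_d.backward()
            opt_d.step()

            # generator step: completion loss + non-saturating adversarial term
            opt_g.zero_grad()
            opt_d.zero_grad()
            l_com = None
            for j, i in enumerate(idx):
                term = multi_stage_loss_tensor(outputs, *targets[i], alpha, sample=j)
                l_com = term if l_com is None else l_com + term
            l_com = l_com * (1.0 / len(idx))
            d_fake_g = disc.score(outputs.fine, len(idx), nf)
            l_adv_g = -_clamped_log(d_fake_g).mean()
            loss_g = config.lambda_com * l_com + config.lambda_adv * l_adv_g
            loss_g.backward()
            opt_g.step()
            opt_d.zero_grad()  # discard discriminator grads from the G pass

            adv_literal = adversarial_loss(
                np.clip(d_real.data, _PROB_EPS, 1 - _PROB_EPS),
                np.clip(d_fake.data, _PROB_EPS, 1 - _PROB_EPS))
            total = config.lambda_com * l_com.item() + config.lambda_adv * adv_literal
            if not np.isfinite(total):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss is not finite")
            ep_com += l_com.item()
            ep_adv += adv_literal
            ep_total += total
            n_batches += 1

        row = {"epoch": epoch, "l_com": ep_com / n_batches,
               "l_adv": ep_adv / n_batches, "l_total": ep_total / n_batches,
               "val_loss": ""}
        if (epoch + 1) % config.val_every == 0 or epoch == config.max_epochs - 1:
            val = validate(gen, val_samples, alpha, sizes, seed=config.seed)
            row["val_loss"] = val["completion_loss"]
            if val["completion_loss"] < best_val:
                best_val = val["completion_loss"]
                if best_path is not None:
                    save_checkpoint(best_path, gen, disc, config, epoch, best_val)
        history.append(row)
        if row["l_com"] < config.stop_loss:
            break

    if last_path is not None:
        save_checkpoint(last_path, gen, disc, config, epoch, best_val)
        with open(out_dir / "train_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    gen._trained = True
    return TrainResult(history=history, checkpoint_best=best_path,
                       checkpoint_last=last_path, generator=gen,
                       discriminator=disc, best_val_loss=float(best_val))


def validate(gen: Generator, val_samples, alpha: float,
             sizes: tuple | None = None, seed: int = 0) -> dict:
    """Evaluation-mode metrics on a validation split.

    Returns per-sample and mean completion loss, plus the Chamfer distance
    of the completed cloud (input union fine prediction) and of the bare
    input against the complete ground truth — the block's full-resolution
    surface cloud (falling back to the network input when a sample does
    not carry one) union the occluded target.
    """
    if sizes is None:
        sizes = (gen.config.decoder.n_coarse, gen.config.decoder.n_middle,
                 gen.config.decoder.n_fine)
    gen.train_mode(False)
    per_loss, per_cd, per_cd_input = [], [], []
    with no_grad():
        for i, s in enumerate(val_samples):
            inp = np.asarray(s.input_points, np.float32)
            gt = build_targets(s.target_points, sizes, seed=seed + 31 * i)
            outputs = gen(inp[None])
            loss = multi_stage_loss_tensor(outputs, *gt, alpha, sample=0)
            per_loss.append(loss.item())
            surface = getattr(s, "surface_full", None)
            if surface is None:
                surface = inp
            complete_gt = np.concatenate([np.asarray(surface),
                                          np.asarray(s.target_points)])
            completed = np.concatenate([inp, outputs.numpy("fine")[0]])
            per_cd.append(chamfer_distance(completed, complete_gt))
            per_cd_input.append(chamfer_distance(inp, complete_gt))
    gen.train_mode(True)
    return {
        "completion_loss": float(np.mean(per_loss)),
        "cd_completed": float(np.mean(per_cd)),
        "cd_input": float(np.mean(per_cd_input)),
        "per_sample_loss": per_loss,
        "per_sample_cd_completed": per_cd,
        "per_sample_cd_input": per_cd_input,
    }


# ---------------------------------------------------------------------------
# checkpoints: an .npz container with a JSON config echo and weight arrays
# ---------------------------------------------------------------------------

def _config_json(gen_config: GeneratorConfig, train_config: TrainConfig) -> str:
    return json.dumps({
        "encoder": dataclasses.asdict(gen_config.encoder),
        "decoder": dataclasses.asdict(gen_config.decoder),
        "train": dataclasses.asdict(train_config),
    })


def save_checkpoint(path, gen: Generator, disc: Discriminator,
                    train_config: TrainConfig, epoch: int, best_val: float):
    arrays = {f"gen:{k}": v for k, v in gen.state_dict().items()}
    arrays.update({f"disc:{k}": v for k, v in disc.state_dict().items()})
    arrays["meta"] = np.frombuffer(json.dumps({
        "config": json.loads(_config_json(gen.config, train_config)),
        "epoch": int(epoch), "best_val": float(best_val),
    }).encode(), dtype=np.uint8)
    tmp = Path(str(path) + ".tmp.npz")
    np.savez(tmp, **arrays)
    tmp.replace(path)


def load_checkpoint(path) -> tuple[Generator, Discriminator, dict]:
    from .model import DecoderConfig, EncoderConfig  # local to avoid cycle noise
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = meta["config"]
        enc = {**cfg["encoder"]}
        enc["layer_channels"] = tuple(enc["layer_channels"])
        enc["resolutions"] = tuple(enc["resolutions"])
        gen_config = GeneratorConfig(encoder=EncoderConfig(**enc),
                                     decoder=DecoderConfig(**cfg["decoder"]))
        gen = Generator(gen_config, seed=0)
        gen.load_state_dict({k[4:]: data[k] for k in data.files if k.startswith("gen:")})
        gen._trained = True
        disc = Discriminator(np.random.default_rng(0),
                             width_scale=gen_config.encoder.width_scale)
        disc.load_state_dict({k[5:]: data[k] for k in data.files if k.startswith("disc:")})
    return gen, disc, meta
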