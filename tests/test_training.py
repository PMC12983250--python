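"""Training loop: schedules, smoke convergence, determinism, checkpoints."""

import numpy as np
import pytest

from canopycomplete.archive import AnnotatedSample
from canopycomplete.model import (DecoderConfig, DecoderOutputs,
                                  EncoderConfig, Generator, GeneratorConfig)
from canopycomplete.nn import Tensor
from canopycomplete.training import (TrainConfig, build_targets,
                                     load_checkpoint, resample_points, train,
                                     validate)

TINY = GeneratorConfig(
    encoder=EncoderConfig(k_neighbors=5, resolutions=(64, 32, 16),
                          width_scale=0.125),
    decoder=DecoderConfig(n_coarse=16, n_middle=32, n_fine=64,
                          width_scale=0.125))


def _samples(n, rng, n_in=64, n_tgt=40):
    out = []
    for i in range(n):
        center = rng.normal(0, 5, size=3)
        out.append(AnnotatedSample(
            input_points=center + rng.normal(0, 8, size=(n_in, 3)),
            target_points=center + rng.normal(0, 4, size=(n_tgt, 3)),
            stage="bolting", scene_id=f"s{i}", block_index=0,
            transform=np.zeros(3)))
    return out


@pytest.mark.parametrize("epoch,alpha", [(0, 0.01), (10, 0.01), (29, 0.01),
                                         (30, 0.05), (50, 0.05), (79, 0.05),
                                         (80, 0.1), (100, 0.1), (199, 0.1)])
def test_alpha_schedule_half_open_intervals(epoch, alpha):
    assert TrainConfig().alpha_for_epoch(epoch) == alpha


def test_resample_points_both_directions(rng):
    pts = rng.normal(size=(30, 3))
    up = resample_points(pts, 50, seed=1)
    assert up.shape == (50, 3)
    np.testing.assert_array_equal(up[:30], pts)
    down = resample_points(pts, 10)
    assert down.shape == (10, 3)
    assert all(any(np.array_equal(p, q) for q in pts) for p in down)


def test_build_targets_are_nested_subsets(rng):
    gt_f, gt_m, gt_c = build_targets(rng.normal(size=(100, 3)), (16, 32, 64))
    assert gt_f.shape == (64, 3)
    fine_set = {tuple(p) for p in gt_f}
    assert all(tuple(p) in fine_set for p in gt_m)
    mid_set = {tuple(p) for p in gt_m}
    assert all(tuple(p) in mid_set for p in gt_c)


def test_training_smoke_produces_checkpoints_and_logs(tmp_path, rng):
    cfg = TrainConfig(max_epochs=4, batch_size=4, val_every=2, seed=1,
                      stop_loss=1e-9)
    result = train(_samples(8, rng), _samples(2, rng), TINY, cfg,
                   out_dir=tmp_path)
    assert len(result.history) == 4
    for row in result.history:
        assert np.isfinite(row["l_com"]) and np.isfinite(row["l_total"])
    assert (tmp_path / "best.ckpt").exists()
    assert (tmp_path / "last.ckpt").exists()
    assert (tmp_path / "train_log.csv").read_text().startswith("epoch,")

    gen, disc, meta = load_checkpoint(tmp_path / "last.ckpt")
    assert meta["config"]["encoder"]["resolutions"] == [64, 32, 16]
    val_a = validate(result.generator, _samples(2, np.random.default_rng(9)), 0.01)
    val_b = validate(gen, _samples(2, np.random.default_rng(9)), 0.01)
    assert val_a["completion_loss"] == pytest.approx(val_b["completion_loss"],
                                                     rel=1e-5)


def test_training_is_deterministic_under_seed(rng):
    cfg = TrainConfig(max_epochs=3, batch_size=4, val_every=10, seed=7,
                      stop_loss=1e-9)
    tr = _samples(6, np.random.default_rng(5))
    va = _samples(2, np.random.default_rng(6))
    h1 = train(tr, va, TINY, cfg).history
    h2 = train(tr, va, TINY, cfg).history
    for a, b in zip(h1, h2):
        assert a["l_com"] == pytest.approx(b["l_com"], abs=1e-6)
        assert a["l_total"] == pytest.approx(b["l_total"], abs=1e-6)


def test_best_validation_sequence_is_monotone(tmp_path, rng):
    cfg = TrainConfig(max_epochs=6, batch_size=4, val_every=2, seed=3,
                      stop_loss=1e-9)
    result = train(_samples(8, rng), _samples(2, rng), TINY, cfg,
                   out_dir=tmp_path)
    vals = [row["val_loss"] for row in result.history if row["val_loss"] != ""]
    best_seq = np.minimum.accumulate(vals)
    assert np.all(np.diff(best_seq) <= 0 + 1e-12)
    assert result.best_val_loss == pytest.approx(min(vals))


class _EchoGenerator:
    """Stub generator that returns each sample's own targets."""

    def __init__(self, samples, sizes, seed):
        self.config = GeneratorConfig(
            encoder=TINY.encoder,
            decoder=DecoderConfig(*sizes, width_scale=0.125))
        self._gts = [build_targets(s.target_points, sizes, seed=seed + 31 * i)
                     for i, s in enumerate(samples)]
        self._cursor = 0

    def train_mode(self, flag=True):
        pass

    def __call__(self, points, multires=None):
        gt_f, gt_m, gt_c = self._gts[self._cursor]
        self._cursor += 1
        return DecoderOutputs(coarse=Tensor(gt_c), middle=Tensor(gt_m),
                              fine=Tensor(gt_f), batch=1,
                              sizes=(len(gt_c), len(gt_m), len(gt_f)))


def test_validate_perfect_generator_scores_zero_loss(rng):
    samples = _samples(3, rng)
    sizes = (16, 32, 64)
    gen = _EchoGenerator(samples, sizes, seed=0)
    out = validate(gen, samples, alpha=0.1, sizes=sizes, seed=0)
    assert out["completion_loss"] == pytest.approx(0.0, abs=1e-9)
    assert out["completion_loss"] == pytest.approx(
        np.mean(out["per_sample_loss"]))
    assert len(out["per_sample_cd_completed"]) == 3


def test_train_rejects_empty_splits(rng):
    with pytest.raises(ValueError):
        train([], _samples(1, rng), TINY, TrainConfig())
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0).validate()
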