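"""Structural and symmetry properties of the completion network."""

import warnings

import numpy as np
import pytest

from canopycomplete.model import (DGCFELayer, DecoderConfig, Discriminator,
                                  EncoderConfig, Generator, GeneratorConfig,
                                  MRDGEncoder, PPDDecoder, knn_indices,
                                  multi_stage_loss_tensor)
from canopycomplete.nn import Adam, Tensor, no_grad
from canopycomplete.training import build_targets

TINY = GeneratorConfig(
    encoder=EncoderConfig(k_neighbors=5, resolutions=(64, 32, 16),
                          width_scale=0.125),
    decoder=DecoderConfig(n_coarse=16, n_middle=32, n_fine=64,
                          width_scale=0.125))


def test_knn_excludes_self_and_orders_by_distance(rng):
    x = rng.normal(size=(30, 3))
    idx = knn_indices(x, 4)
    for i in range(30):
        assert i not in idx[i]
        d = np.linalg.norm(x[idx[i]] - x[i], axis=1)
        assert np.all(np.diff(d) >= -1e-12)
    with pytest.raises(ValueError):
        knn_indices(x, 30)


def test_dgcfe_permutation_equivariance(rng):
    layer = DGCFELayer(5, 7, k=4, rng=np.random.default_rng(3))
    x = rng.normal(size=(40, 5)).astype(np.float32)
    out = layer(Tensor(x), batch=1, n=40).data
    perm = rng.permutation(40)
    out_p = layer(Tensor(x[perm]), batch=1, n=40).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-5)


def test_dgcfe_duplicate_points_share_features(rng):
    base = rng.normal(size=(12, 4)).astype(np.float32)
    x = np.repeat(base, 2, axis=0)  # exact duplicate of every point
    layer = DGCFELayer(4, 6, k=3, rng=np.random.default_rng(1))
    out = layer(Tensor(x), batch=1, n=24).data
    np.testing.assert_allclose(out[0::2], out[1::2], atol=1e-6)


def test_dgcfe_deterministic_and_validates(rng):
    layer = DGCFELayer(3, 4, k=5, rng=np.random.default_rng(0))
    x = rng.normal(size=(20, 3)).astype(np.float32)
    a = layer(Tensor(x), batch=1, n=20).data
    b = layer(Tensor(x), batch=1, n=20).data
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        layer(Tensor(x[:5]), batch=1, n=5)


@pytest.mark.parametrize("scale,expected", [(1.0, 5760), (0.5, 2880),
                                            (0.25, 1440)])
def test_latent_dimension_law_under_width_scaling(scale, expected):
    cfg = EncoderConfig(k_neighbors=5, resolutions=(64, 32, 16),
                        width_scale=scale)
    assert cfg.latent_dim == expected
    assert cfg.latent_dim == 3 * sum(cfg.scaled_channels[1:])


def test_encoder_forward_shape_and_permutation_invariance(rng):
    enc = MRDGEncoder(TINY.encoder, np.random.default_rng(0))
    enc.train_mode(False)
    pts = rng.normal(0, 10, size=(1, 64, 3)).astype(np.float32)
    lat = enc(pts).data
    assert lat.shape == (1, TINY.encoder.latent_dim)
    perm = rng.permutation(64)
    lat_p = enc(pts[:, perm]).data
    scale = np.abs(lat).max()
    np.testing.assert_allclose(lat_p, lat, atol=1e-5 * max(scale, 1.0))


def test_encoder_rejects_wrong_block_size(rng):
    enc = MRDGEncoder(TINY.encoder, np.random.default_rng(0))
    with pytest.raises(ValueError):
        enc(rng.normal(size=(1, 60, 3)))
    with pytest.raises(ValueError):
        EncoderConfig(resolutions=(64, 64, 16)).validate()
    with pytest.raises(ValueError):
        EncoderConfig(k_neighbors=20, resolutions=(64, 32, 16)).validate()


def test_decoder_output_sizes_and_child_structure(rng):
    dec = PPDDecoder(TINY.decoder, latent_dim=TINY.encoder.latent_dim,
                     rng=np.random.default_rng(2))
    latent = Tensor(rng.normal(size=(2, TINY.encoder.latent_dim)))
    # zero offsets expose the two-children-per-parent construction
    dec.head_middle.zero_()
    dec.head_fine.zero_()
    out = dec(latent)
    coarse, middle, fine = (out.numpy("coarse"), out.numpy("middle"),
                            out.numpy("fine"))
    assert coarse.shape == (2, 16, 3)
    assert middle.shape == (2, 32, 3)
    assert fine.shape == (2, 64, 3)
    np.testing.assert_allclose(middle, np.repeat(coarse, 2, axis=1), atol=1e-7)
    np.testing.assert_allclose(fine, np.repeat(middle, 2, axis=1), atol=1e-7)


def test_decoder_zero_latent_zero_heads_yields_origin():
    dec = PPDDecoder(TINY.decoder, latent_dim=TINY.encoder.latent_dim,
                     rng=np.random.default_rng(0))
    for head in (dec.head_coarse, dec.head_middle, dec.head_fine):
        head.zero_()
    out = dec(Tensor(np.zeros((1, TINY.encoder.latent_dim))))
    assert np.all(out.fine.data == 0)
    assert np.all(out.coarse.data == 0)
    with pytest.raises(ValueError):
        dec(Tensor(np.full((1, TINY.encoder.latent_dim), np.nan)))


def test_discriminator_range_and_permutation_invariance(rng):
    disc = Discriminator(np.random.default_rng(4), width_scale=0.25)
    clouds = rng.normal(size=(3, 40, 3)).astype(np.float32)
    disc.train_mode(False)
    p = disc(clouds).data
    assert np.all((p > 0) & (p < 1))
    perm = rng.permutation(40)
    p2 = disc(clouds[:, perm]).data
    np.testing.assert_allclose(p2, p, atol=1e-5)
    np.testing.assert_array_equal(disc(clouds).data, p)  # eval determinism
    with pytest.raises(ValueError):
        disc(clouds[:, :4])


def test_complete_block_unions_input_with_prediction(rng):
    gen = Generator(TINY, seed=0)
    block = rng.normal(0, 10, size=(64, 3)).astype(np.float32)
    with pytest.warns(UserWarning, match="untrained"):
        completed = gen.complete_block(block)
    assert completed.shape == (128, 3)
    np.testing.assert_array_equal(completed[:64], block)
    assert np.all(np.isfinite(completed))
    with pytest.raises(ValueError):
        gen.complete_block(completed)  # re-completing is undefined


def test_single_optimizer_step_decreases_loss_majority_of_seeds(rng):
    """One Adam step at lr 1e-4 on one sample lowers its multi-stage loss."""
    wins = 0
    for seed in range(5):
        gen = Generator(TINY, seed=seed)
        sample_rng = np.random.default_rng(100 + seed)
        block = sample_rng.normal(0, 10, size=(1, 64, 3)).astype(np.float32)
        gts = build_targets(sample_rng.normal(0, 10, size=(80, 3)),
                            (16, 32, 64), seed=seed)
        opt = Adam(gen.parameters(), lr=1e-4)
        out = gen(block)
        loss = multi_stage_loss_tensor(out, *gts, alpha=0.01)
        before = loss.item()
        loss.backward()
        opt.step()
        after = multi_stage_loss_tensor(gen(block), *gts, alpha=0.01).item()
        wins += after < before
    assert wins >= 3
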