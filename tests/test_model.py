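"""Architecture contracts: shapes, fusion order, heads, loss, gradients."""

import numpy as np
import pytest

from bcrfusion import nn
from bcrfusion.model import (
    ClinicalMLP,
    FusionNet,
    ModelConfig,
    PatientInput,
    adapt_first_conv,
    add_axial_embedding,
    aggregate_patient,
    bce_loss,
    expand_clinical,
    forward_patient,
    fuse,
    slice_encode,
    transformer_slice_head,
)
from bcrfusion.nn import Tensor
from bcrfusion.preprocessing import ClinicalVector, SlicePair

rng = np.random.default_rng(21)

TINY = ModelConfig(backbone="tiny", input_size=64, n_slices=4, regions=("ITR",),
                   transformer_layers=1, transformer_heads=2, model_dim=32,
                   d_emb=4, freeze_prefix=0)


def _slice(size=64, fill=None):
    px = rng.standard_normal((size, size, 2)).astype(np.float32) if fill is None \
        else np.full((size, size, 2), fill, dtype=np.float32)
    return SlicePair(px, axial_index=0, region="ITR")


# -- adapt_first_conv -------------------------------------------------------

def test_adapt_first_conv_mean_duplication_and_bias_passthrough():
    k = rng.standard_normal((4, 1, 3, 3))
    rgb = np.repeat(k, 3, axis=1)
    bias = rng.standard_normal(4)
    w2, b2 = adapt_first_conv(rgb, bias)
    assert w2.shape == (4, 2, 3, 3)
    assert np.allclose(w2[:, 0], k[:, 0]) and np.allclose(w2[:, 1], k[:, 0])
    assert b2 is bias
    with pytest.raises(ValueError):
        adapt_first_conv(rng.standard_normal((4, 2, 3, 3)))


def test_adapt_first_conv_two_thirds_response_identity():
    """Duplicated-channel response equals 2/3 of the RGB-replicated response
    (pre-bias), a direct consequence of channel averaging."""
    from bcrfusion.nn import autodiff as ad
    w_rgb = rng.standard_normal((6, 3, 7, 7)).astype(np.float64)
    w2, _ = adapt_first_conv(w_rgb)
    img = rng.standard_normal((1, 28, 28, 1))
    r3 = ad.conv2d(Tensor(np.repeat(img, 3, axis=3)), Tensor(w_rgb), None, 2, 3).data
    r2 = ad.conv2d(Tensor(np.repeat(img, 2, axis=3)), Tensor(w2), None, 2, 3).data
    assert np.abs(r2 - (2.0 / 3.0) * r3).max() < 1e-5


# -- encoders ---------------------------------------------------------------

def test_tiny_encoder_output_shape_and_determinism():
    net = FusionNet(TINY, seed=0)
    f = slice_encode(_slice(64), net)
    assert f.shape == (4, 4, 64)
    f2 = slice_encode(_slice(64), net)  # different slice -> same shape
    assert f2.shape == (4, 4, 64)
    sp = _slice(64)
    a, b = slice_encode(sp, net), slice_encode(sp, net)
    assert np.array_equal(a, b)  # eval-mode repeatability
    with pytest.raises(ValueError, match="slice shape"):
        slice_encode(_slice(32), net)


def test_resnet18_encoder_maps_224_to_7x7x512():
    cfg = ModelConfig(backbone="resnet18", input_size=224, regions=("ITR",),
                      n_slices=4)
    net = FusionNet(cfg, seed=0)
    f = slice_encode(_slice(224), net)
    assert f.shape == (7, 7, 512)
    assert cfg.n_tokens == 49


# -- axial embedding --------------------------------------------------------

def test_add_axial_embedding_contracts():
    f = rng.standard_normal((4, 4, 8))
    zero_table = np.zeros((6, 4, 4))
    assert np.array_equal(add_axial_embedding(f, 2, zero_table), f)
    const_table = np.full((6, 4, 4), 1.5)
    out = add_axial_embedding(f, 1, const_table)
    assert np.allclose(out - f, 1.5)
    table = rng.standard_normal((6, 4, 4))
    o1 = add_axial_embedding(f, 0, table)
    o2 = add_axial_embedding(f, 3, table)
    assert not np.allclose(o1, o2)
    with pytest.raises(IndexError):
        add_axial_embedding(f, 6, table)


# -- clinical expansion -----------------------------------------------------

def test_expand_clinical_replication_and_linear_map():
    cv = ClinicalVector(np.array([0.2, 0.8]), ["a", "b"])
    out = expand_clinical(cv, 3, 3, np.eye(2))
    assert out.shape == (3, 3, 2)
    assert np.allclose(out[..., 0], 0.2) and np.allclose(out[..., 1], 0.8)
    M = rng.standard_normal((5, 2))
    out = expand_clinical(cv, 4, 4, M)
    assert np.allclose(out[0, 0], M @ cv.values)
    assert np.allclose(out[2, 3], out[1, 1])  # spatially constant per channel
    with pytest.raises(ValueError):
        expand_clinical(cv, 3, 3, rng.standard_normal((5, 3)))


# -- fusion -----------------------------------------------------------------

def test_fuse_channel_arithmetic_and_order():
    maps = {r: rng.standard_normal((7, 7, 512)) for r in ("ITR", "PTR", "PPR")}
    clin = rng.standard_normal((7, 7, 16))
    out = fuse(maps, clin)
    assert out.shape[-1] == 3 * 512 + 16 == 1552
    assert np.array_equal(out[..., :512], maps["ITR"])
    single = fuse({"ITR": maps["ITR"]}, None, regions=("ITR",))
    assert np.array_equal(single, maps["ITR"])
    with pytest.raises(ValueError, match="spatial"):
        fuse({**maps, "PPR": rng.standard_normal((6, 6, 512))}, None)
    with pytest.raises(KeyError):
        fuse({"ITR": maps["ITR"]}, None)


# -- transformer head -------------------------------------------------------

def test_transformer_head_token_count_and_constant_input():
    cfg = ModelConfig(backbone="resnet18", input_size=224)
    assert cfg.n_tokens == 49  # S = W_I * H_I
    net = FusionNet(TINY, seed=1)
    assert net.head.pos.shape[0] == TINY.n_tokens == 16
    z = np.zeros((4, 4, TINY.fused_channels))
    r1 = transformer_slice_head(z, net.head)
    r2 = transformer_slice_head(z, net.head)
    assert r1 == r2  # bias-propagated constant, identical across slices


def test_transformer_head_token_permutation_equivariance():
    """Permuting tokens together with the positional-embedding rows leaves
    the pooled slice score unchanged (attention is permutation-equivariant)."""
    net = FusionNet(TINY, seed=2)
    net.eval()
    head = net.head
    f = rng.standard_normal((4, 4, TINY.fused_channels)).astype(np.float32)
    r_orig = transformer_slice_head(f, head)
    perm = np.random.default_rng(0).permutation(16)
    f_tokens = f.reshape(16, -1)[perm].reshape(4, 4, -1)
    pos_backup = head.pos.data.copy()
    head.pos.data = pos_backup[perm]
    r_perm = transformer_slice_head(f_tokens, head)
    head.pos.data = pos_backup
    assert r_perm == pytest.approx(r_orig, abs=1e-4)


# -- aggregation and loss ---------------------------------------------------

def test_aggregate_patient_sigmoid_fc():
    r = rng.standard_normal(8)
    w = rng.standard_normal(8)
    pad = np.zeros(8, dtype=bool)
    y = aggregate_patient(r, pad, w, 0.3)
    assert 0 < y < 1
    assert y == pytest.approx(1 / (1 + np.exp(-(w @ r + 0.3))))
    assert aggregate_patient(r, pad, np.zeros(8), 0.0) == 0.5
    pad2 = np.array([False] * 6 + [True] * 2)
    y2 = aggregate_patient(r, pad2, w, 0.3)
    masked = r.copy(); masked[6:] = 0
    assert y2 == pytest.approx(1 / (1 + np.exp(-(w @ masked + 0.3))))
    with pytest.raises(ValueError):
        aggregate_patient(r, pad, np.zeros(5), 0.0)


def test_bce_loss_values_and_symmetry():
    assert bce_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(0.0, abs=1e-6)
    assert bce_loss(np.array([0.5]), np.array([0.0])) == pytest.approx(np.log(2))
    p = np.array([0.2, 0.7, 0.9])
    y = np.array([0.0, 1.0, 1.0])
    assert bce_loss(p, y) == pytest.approx(bce_loss(1 - p, 1 - y))
    with pytest.raises(ValueError):
        bce_loss(np.array([0.5, 0.5]), np.array([1.0]))


# -- full patient forward ---------------------------------------------------

def _patient(cfg, seed=0, with_clinical=False):
    r = np.random.default_rng(seed)
    slices = {}
    for reg in cfg.regions:
        sps = []
        for k in range(cfg.n_slices):
            px = r.standard_normal((cfg.input_size, cfg.input_size, 2)).astype(np.float32)
            sps.append(SlicePair(px, axial_index=k, region=reg))
        slices[reg] = sps
    clin = ClinicalVector(r.random(6), [f"f{i}" for i in range(6)]) if with_clinical else None
    return PatientInput(patient_id=f"P{seed}", slices=slices, clinical=clin)


def test_forward_patient_shapes_and_determinism():
    net = FusionNet(TINY, seed=3)
    pat = _patient(TINY, seed=1)
    res1 = forward_patient(net, pat)
    res2 = forward_patient(net, pat)
    assert len(res1.slice_scores) == TINY.n_slices
    assert 0.0 <= res1.patient_prob <= 1.0
    assert res1.patient_prob == res2.patient_prob
    assert np.array_equal(res1.slice_scores, res2.slice_scores)


def test_clinical_branch_changes_prediction():
    cfg = ModelConfig(backbone="tiny", input_size=64, n_slices=4, regions=("ITR",),
                      use_clinical=True, d_cli=6, d_emb=4, transformer_layers=1,
                      transformer_heads=2, model_dim=32, freeze_prefix=0)
    net = FusionNet(cfg, seed=4)
    pat_a = _patient(cfg, seed=1, with_clinical=True)
    pat_b = _patient(cfg, seed=1, with_clinical=True)
    pat_b.clinical = ClinicalVector(1.0 - pat_a.clinical.values,
                                    pat_a.clinical.field_names)
    ya = forward_patient(net, pat_a).patient_prob
    yb = forward_patient(net, pat_b).patient_prob
    assert ya != yb
    pat_none = _patient(cfg, seed=1, with_clinical=False)
    with pytest.raises(ValueError, match="clinical"):
        forward_patient(net, pat_none)


def test_missing_region_input_is_an_error():
    cfg = ModelConfig(backbone="tiny", input_size=64, n_slices=2,
                      regions=("ITR", "PTR"), transformer_layers=1,
                      transformer_heads=2, model_dim=32, freeze_prefix=0)
    net = FusionNet(cfg, seed=0)
    pat = _patient(TINY, seed=0)  # has only ITR
    with pytest.raises(KeyError, match="PTR"):
        forward_patient(net, pat)


def test_frozen_prefix_blocks_gradients():
    cfg = ModelConfig(backbone="tiny", input_size=64, n_slices=2, regions=("ITR",),
                      transformer_layers=1, transformer_heads=2, model_dim=32,
                      d_emb=4, freeze_prefix=2)
    net = FusionNet(cfg, seed=5)
    net.train()
    x = Tensor(rng.standard_normal((2, 1, 2, 64, 64, 2)).astype(np.float32))
    pad = np.zeros((2, 2), dtype=bool)
    loss = bce_loss(net(x, pad), np.array([1.0, 0.0], dtype=np.float32))
    loss.backward()
    for stage in net.encoder.stages[:2]:
        for p in stage.parameters():
            assert p.grad is None or not p.grad.any()
    for stage in net.encoder.stages[2:]:
        for p in stage.parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0
    assert net.head.proj.weight.grad is not None


def test_loss_decreases_on_separable_toy_batch():
    """20 optimisation steps on a linearly separable batch cut the loss by
    half or more."""
    cfg = ModelConfig(backbone="tiny", input_size=64, n_slices=2, regions=("ITR",),
                      transformer_layers=1, transformer_heads=2, model_dim=32,
                      d_emb=4, dropout=0.0, freeze_prefix=0)
    net = FusionNet(cfg, seed=6)
    net.train()
    r = np.random.default_rng(0)
    x = np.zeros((6, 1, 2, 64, 64, 2), dtype=np.float32)
    y = np.array([1, 1, 1, 0, 0, 0], dtype=np.float32)
    x[:3] += 1.0
    x += 0.1 * r.standard_normal(x.shape).astype(np.float32)
    pad = np.zeros((6, 2), dtype=bool)
    opt = nn.AdamW(net.parameters(), lr=3e-3, weight_decay=0.0)
    losses = []
    for _ in range(20):
        loss = bce_loss(net(Tensor(x), pad), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    assert losses[-1] <= 0.5 * losses[0]


def test_clinical_mlp_outputs_probabilities():
    mlp = ClinicalMLP(6, seed=0)
    mlp.eval()
    with nn.no_grad():
        out = mlp(Tensor(rng.random((5, 6)).astype(np.float32)))
    assert out.shape == (5,)
    assert ((out.data > 0) & (out.data < 1)).all()


def test_checkpoint_roundtrip_restores_predictions(tmp_path):
    from bcrfusion.model import load_checkpoint, save_checkpoint
    net = FusionNet(TINY, seed=8)
    pat = _patient(TINY, seed=2)
    before = forward_patient(net, pat)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(net, path)
    restored = load_checkpoint(path)
    assert restored.cfg.to_dict() == TINY.to_dict()
    after = forward_patient(restored, pat)
    assert after.patient_prob == pytest.approx(before.patient_prob, abs=1e-6)
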