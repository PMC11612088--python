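"""Architecture probes: gate saturation, down-sampling factors, dense-ASPP
bookkeeping and impulse response, axial-attention normalisation, reverse
gating, rank contracts and gradient coverage."""

import numpy as np
import pytest

from nodeseg.losses import LossConfig, total_loss
from nodeseg.networks import (AttentionGate, AttentionalUNet, AxialAttention,
                              DenseASPP, ReverseAxialAttention, SNet,
                              build_model)
from nodeseg.nn import Conv, Tensor


# ---------------------------------------------------------------------------
# attention gate
# ---------------------------------------------------------------------------

def test_attention_gate_single_channel_gate_and_saturation(rng):
    gate = AttentionGate(2, c_d=8, c_e=8, p=4, rng=np.random.default_rng(0))
    xd = Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32))
    xe = Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32))
    _, h = gate(xd, xe, return_gate=True)
    assert h.shape == (2, 1, 8, 8)
    assert (h.data > 0).all() and (h.data < 1).all()
    # drive the psi bias to saturation: open gate passes x_e through exactly
    gate.psi.weight.data[:] = 0
    gate.psi.bias.data[:] = 40.0
    _, h_open = gate(xd, xe, return_gate=True)
    assert np.allclose(h_open.data, 1.0)
    assert np.allclose((h_open * xe).data, xe.data, atol=1e-6)
    gate.psi.bias.data[:] = -40.0
    _, h_closed = gate(xd, xe, return_gate=True)
    assert np.allclose((h_closed * xe).data, 0.0, atol=1e-6)


def test_attention_gate_rejects_wide_projection():
    with pytest.raises(ValueError):
        AttentionGate(2, c_d=8, c_e=8, p=8)


# ---------------------------------------------------------------------------
# down-sampling factors
# ---------------------------------------------------------------------------

def test_unet_bottleneck_is_sixteenth_of_input(rng):
    net = AttentionalUNet(ndim=2, base=4, seed=0)
    x = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
    _, bottleneck = net.encode(Tensor(x))
    assert bottleneck.shape[2:] == (4, 4)
    out = net(x)
    assert out.final_prob.shape == (1, 1, 64, 64)
    assert out.partial_heatmaps == []
    with pytest.raises(ValueError, match="16"):
        net(rng.normal(size=(1, 1, 24, 24)).astype(np.float32))


def test_snet_deepest_feature_is_quarter_resolution(rng):
    net = SNet(ndim=2, base=4, seed=0)
    for size in (96, 64):
        e1, e2, e4 = net.encode(Tensor(
            rng.normal(size=(1, 1, size, size)).astype(np.float32)))
        assert e1.shape[2:] == (size, size)
        assert e2.shape[2:] == (size // 2, size // 2)
        assert e4.shape[2:] == (size // 4, size // 4)
        assert e4.shape[1] > e2.shape[1]        # depth increase after pooling
    with pytest.raises(ValueError, match="4"):
        net(rng.normal(size=(1, 1, 30, 30)).astype(np.float32))


def test_unet_forward_deterministic(rng):
    net = AttentionalUNet(ndim=2, base=4, seed=3)
    net.eval()
    x = np.zeros((1, 1, 32, 32), dtype=np.float32)
    a = net(x).final_prob.data
    b = net(x).final_prob.data
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# dense ASPP
# ---------------------------------------------------------------------------

def test_dense_aspp_shape_and_channel_bookkeeping(rng):
    aspp = DenseASPP(2, c_in=16, growth=4, c_out=8, rng=np.random.default_rng(0))
    assert aspp.dilations == (3, 6, 9, 12)
    assert aspp.stage_input_channels == [16, 20, 24, 28]
    for i, stage in enumerate(aspp.stages):
        assert stage.conv.weight.shape[1] == aspp.stage_input_channels[i]
    out = aspp(Tensor(rng.normal(size=(1, 16, 24, 24)).astype(np.float32)))
    assert out.shape == (1, 8, 24, 24)
    with pytest.raises(ValueError):
        DenseASPP(2, 16, 4, 8, dilations=(3, 6, 9))
    with pytest.raises(ValueError):
        DenseASPP(2, 16, 4, 8, dilations=(3, 6, 9, -1))


def test_dilated_conv_impulse_response_hits_dilation_spaced_taps():
    conv = Conv(2, 1, 1, k=3, dilation=3, rng=np.random.default_rng(0))
    conv.weight.data[:] = 1.0
    conv.bias.data[:] = 0.0
    x = np.zeros((1, 1, 15, 15), dtype=np.float32)
    x[0, 0, 7, 7] = 1.0
    out = conv(Tensor(x)).data[0, 0]
    nz = np.argwhere(out != 0) - 7
    assert len(nz) == 9
    assert set(map(tuple, nz)) == {(dy, dx) for dy in (-3, 0, 3)
                                   for dx in (-3, 0, 3)}


# ---------------------------------------------------------------------------
# axial attention
# ---------------------------------------------------------------------------

def test_axial_attention_rows_sum_to_one(rng):
    att = AxialAttention(2, channels=8, rng=np.random.default_rng(0))
    x = Tensor(rng.normal(size=(2, 8, 6, 5)).astype(np.float32))
    out, weights = att(x, return_weights=True)
    assert out.shape == x.shape
    assert len(weights) == 2                      # one pass per spatial axis
    for a in weights:
        assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-5)


def test_axial_attention_single_pixel_returns_value_projection(rng):
    att = AxialAttention(2, channels=4, rng=np.random.default_rng(1))
    x = Tensor(rng.normal(size=(1, 4, 1, 1)).astype(np.float32))
    out, weights = att(x, return_weights=True)
    for a in weights:
        assert np.allclose(a, 1.0)                # softmax of a single logit
    v = att.v_convs[1](att.v_convs[0](x))         # sequential value path
    assert np.allclose(out.data, v.data, atol=1e-6)


def test_axial_attention_zero_query_averages_values(rng):
    att = AxialAttention(2, channels=4, rng=np.random.default_rng(2))
    for qc in att.q_convs:
        qc.weight.data[:] = 0
        qc.bias.data[:] = 0
    x = Tensor(rng.normal(size=(1, 4, 5, 3)).astype(np.float32))
    # probe the first (height) pass in isolation
    q, k, v = att.q_convs[0](x), att.k_convs[0](x), att.v_convs[0](x)
    out = AxialAttention._attend_axis(q, k, v, axis=2)
    expected = np.broadcast_to(v.data.mean(axis=2, keepdims=True), v.shape)
    assert np.allclose(out.data, expected, atol=1e-5)


# ---------------------------------------------------------------------------
# reverse axial attention
# ---------------------------------------------------------------------------

def test_reverse_gate_half_for_zero_decoder_logits(rng):
    raa = ReverseAxialAttention(2, c_e=4, c_d=4, c_out=4,
                                rng=np.random.default_rng(0))
    raa.gate_conv.weight.data[:] = 0
    raa.gate_conv.bias.data[:] = 0
    d = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
    e = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
    _, heat, gate = raa(d, e, return_gate=True)
    assert np.allclose(gate.data, 0.5)
    filtered_expected = 0.5 * raa.attention(e).data
    assert np.allclose((gate * raa.attention(e)).data, filtered_expected)
    assert heat.shape == (1, 1, 8, 8)
    # saturated decoder logits close the gate entirely
    raa.gate_conv.bias.data[:] = 40.0
    _, _, gate_closed = raa(d, e, return_gate=True)
    assert np.allclose(gate_closed.data, 0.0, atol=1e-6)
    with pytest.raises(ValueError):
        raa(d, Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32)))


# ---------------------------------------------------------------------------
# full networks
# ---------------------------------------------------------------------------

def test_snet_outputs_final_prob_and_two_heatmaps(rng):
    net = SNet(ndim=2, base=4, seed=0)
    out = net(rng.normal(size=(1, 1, 96, 96)).astype(np.float32))
    assert out.final_prob.shape == (1, 1, 96, 96)
    assert len(out.partial_heatmaps) == 2
    assert all(h.shape == (1, 1, 96, 96) for h in out.partial_heatmaps)
    assert (out.final_prob.data >= 0).all() and (out.final_prob.data <= 1).all()


def test_snet_constant_bias_when_weights_zeroed(rng):
    net = SNet(ndim=2, base=4, seed=0)
    net.eval()
    net.head.weight.data[:] = 0
    net.head.bias.data[:] = 1.3
    out = net(rng.normal(size=(1, 1, 16, 16)).astype(np.float32))
    assert np.allclose(out.final_prob.data, 1 / (1 + np.exp(-1.3)), atol=1e-6)


@pytest.mark.parametrize("arch", ["snet", "attention_unet"])
@pytest.mark.parametrize("ndim,in_ch,shape", [
    (2, 1, (16, 16)), (2, 15, (16, 16)), (3, 1, (16, 16, 16))])
def test_rank_and_channel_contracts(arch, ndim, in_ch, shape, rng):
    net = build_model({"arch": arch, "ndim": ndim, "in_channels": in_ch,
                       "base": 4, "seed": 0})
    x = rng.normal(size=(1, in_ch) + shape).astype(np.float32)
    out = net(x)
    assert out.final_prob.shape == (1, 1) + shape


def test_heads_are_optional_and_do_not_change_segmentation(rng):
    x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
    plain = SNet(ndim=2, base=4, seed=5)
    headed = SNet(ndim=2, base=4, with_heads=True, seed=5)
    plain.eval(); headed.eval()
    a = plain(x).final_prob.data
    out = headed(x, with_heads=True)
    assert np.allclose(out.final_prob.data, a)
    assert out.class_logit.shape == (2, 1)
    assert out.loc_heatmap.shape == (2, 1, 4, 4)
    assert headed(x, with_heads=False).class_logit is None


def test_gradient_reaches_every_parameter(rng):
    net = SNet(ndim=2, base=4, seed=1)
    x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
    g = (rng.uniform(size=(2, 1, 16, 16)) < 0.1).astype(np.float32)
    terms = total_loss(net(x), g, LossConfig(pool_k=5))
    terms.total.backward()
    dead = [name for name, p in net.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert dead == []
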