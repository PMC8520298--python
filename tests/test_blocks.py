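"""Behavioral contracts of the MSRB / MSAM / AASPP / RASM blocks."""

import numpy as np
import pytest

from msaunet.autograd import Tensor
from msaunet.blocks import AASPP, BlockConfig, MSAM, MSRB, RASM
from msaunet.nn import Conv2d


def make_rng(seed=0):
    return np.random.default_rng(seed)


def zero_weights(module):
    for p in module.parameters():
        p.data[...] = 0.0


# ----------------------------------------------------------------------
# shape contracts
# ----------------------------------------------------------------------

@pytest.mark.parametrize("h,w", [(16, 16), (16, 32), (32, 16), (48, 24)])
@pytest.mark.parametrize("c", [1, 3, 8])
def test_block_shape_contracts(h, w, c):
    x = Tensor(make_rng(1).normal(size=(1, h, w, c)).astype(np.float32))
    out_c = max(1, 2 * c)

    msrb = MSRB(c, out_c, rng=make_rng(2))
    msrb.eval()
    assert msrb(x).shape == (1, h, w, out_c)

    msam = MSAM(c, rng=make_rng(3))
    msam.eval()
    assert msam(x).shape == (1, h, w, c)

    aaspp = AASPP(c, out_c, rng=make_rng(4))
    aaspp.eval()
    assert aaspp(x).shape == (1, h, w, out_c)

    high = Tensor(make_rng(5).normal(size=(1, h // 2, w // 2, out_c)).astype(np.float32))
    rasm = RASM(c, out_c, out_c, rng=make_rng(6))
    rasm.eval()
    assert rasm(x, high).shape == (1, h, w, out_c)


# ----------------------------------------------------------------------
# MSRB
# ----------------------------------------------------------------------

def test_msrb_zero_input_gives_zero_output():
    """Zero input, zero biases, identity inference normalization -> zero."""
    msrb = MSRB(4, 8, rng=make_rng(0))
    msrb.eval()
    out = msrb(Tensor(np.zeros((1, 16, 16, 4), dtype=np.float32)))
    np.testing.assert_array_equal(out.data, 0.0)


def test_msrb_serial_branch_cheaper_than_5x5():
    """Two serial 3x3 convs at width C (18 C^2 weights) beat one 5x5 (25 C^2)."""
    for c in (1, 4, 16):
        msrb = MSRB(c, c, rng=make_rng(0))  # C -> C -> C branch
        branch_b = (msrb.branch_b1.conv.weight.data.size
                    + msrb.branch_b2.conv.weight.data.size)
        assert branch_b == 2 * 9 * c * c < 25 * c * c


def test_msrb_rejects_nonfinite_input():
    msrb = MSRB(2, 2, rng=make_rng(0))
    bad = np.zeros((1, 16, 16, 2))
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        msrb(Tensor(bad))


def test_msrb_rejects_bad_out_channels():
    with pytest.raises(ValueError, match="out_channels"):
        MSRB(2, 0, rng=make_rng(0))


def test_msrb_dropblock_rate0_deterministic_rate_pos_seeded():
    x = np.abs(make_rng(1).normal(size=(2, 16, 16, 3))).astype(np.float32)

    msrb = MSRB(3, 4, BlockConfig(dropblock_rate=0.0), rng=make_rng(0))
    msrb.train()
    a = msrb(Tensor(x)).data
    b = msrb(Tensor(x)).data
    np.testing.assert_array_equal(a, b)

    def run_with_seed(seed):
        m = MSRB(3, 4, BlockConfig(dropblock_rate=0.4, dropblock_size=5),
                 rng=make_rng(9))
        m.dropblock.rng = np.random.default_rng(seed)
        m.train()
        return m(Tensor(x)).data

    np.testing.assert_array_equal(run_with_seed(5), run_with_seed(5))
    assert not np.array_equal(run_with_seed(5), run_with_seed(6))


# ----------------------------------------------------------------------
# MSAM
# ----------------------------------------------------------------------

def test_msam_attention_strictly_in_unit_interval_and_contractive():
    x = make_rng(3).normal(scale=3.0, size=(2, 32, 32, 4)).astype(np.float32)
    msam = MSAM(4, rng=make_rng(1))
    msam.eval()
    att = msam.attention(Tensor(x)).data
    assert np.all(att > 0.0) and np.all(att < 1.0)
    out = msam(Tensor(x)).data
    assert np.all(np.abs(out) <= np.abs(x) + 1e-7)


def test_msam_zero_input_attention_is_half_output_zero():
    msam = MSAM(3, rng=make_rng(2))
    msam.eval()
    x = Tensor(np.zeros((1, 16, 16, 3), dtype=np.float32))
    np.testing.assert_allclose(msam.attention(x).data, 0.5, atol=1e-7)
    np.testing.assert_array_equal(msam(x).data, 0.0)


def test_msam_rejects_indivisible_dims_naming_axis():
    msam = MSAM(2, rng=make_rng(0))
    with pytest.raises(ValueError, match="height 12"):
        msam(Tensor(np.zeros((1, 12, 16, 2))))
    with pytest.raises(ValueError, match="width 20"):
        msam(Tensor(np.zeros((1, 16, 20, 2))))


def test_msam_batch_independence():
    """Duplicating a sample in the batch yields identical per-sample output."""
    msam = MSAM(3, rng=make_rng(4))
    msam.eval()
    x = make_rng(5).normal(size=(1, 16, 16, 3)).astype(np.float32)
    doubled = np.concatenate([x, x], axis=0)
    out = msam(Tensor(doubled)).data
    np.testing.assert_array_equal(out[0], out[1])


# ----------------------------------------------------------------------
# AASPP
# ----------------------------------------------------------------------

def test_aaspp_branch_rates_and_kernels():
    aaspp = AASPP(2, 4, rng=make_rng(0))
    kernels = [b.conv.kernel_size for b in aaspp.branches]
    rates = [b.conv.dilation for b in aaspp.branches]
    assert kernels == [1, 3, 3, 3]
    assert rates == [1, 2, 4, 8]


def test_aaspp_preserves_spatial_resolution():
    aaspp = AASPP(3, 6, rng=make_rng(1))
    aaspp.eval()
    out = aaspp(Tensor(make_rng(2).normal(size=(1, 32, 32, 3)).astype(np.float32)))
    assert out.shape == (1, 32, 32, 6)


# ----------------------------------------------------------------------
# RASM
# ----------------------------------------------------------------------

def test_rasm_zero_weights_zero_output():
    """All-zero conv weights make all three summands vanish."""
    rasm = RASM(3, 5, 4, rng=make_rng(0))
    rasm.eval()
    zero_weights(rasm)
    low = Tensor(make_rng(1).normal(size=(1, 16, 16, 3)).astype(np.float32))
    high = Tensor(make_rng(2).normal(size=(1, 8, 8, 5)).astype(np.float32))
    np.testing.assert_array_equal(rasm(low, high).data, 0.0)


def test_rasm_upsample_of_constant_high_is_constant():
    from msaunet.autograd import resize_bilinear

    high = Tensor(np.full((1, 8, 8, 2), 1.5, dtype=np.float32))
    up = resize_bilinear(high, 16, 16)
    np.testing.assert_allclose(up.data, 1.5, rtol=1e-6)


def test_rasm_rejects_spatial_mismatch():
    rasm = RASM(2, 2, 2, rng=make_rng(0))
    low = Tensor(np.zeros((1, 16, 16, 2)))
    high_bad = Tensor(np.zeros((1, 6, 8, 2)))
    with pytest.raises(ValueError, match="half"):
        rasm(low, high_bad)


# ----------------------------------------------------------------------
# differentiability (finite differences at 8x8)
# ----------------------------------------------------------------------

@pytest.mark.parametrize("block_name", ["msrb", "msam", "aaspp", "rasm"])
def test_blocks_differentiable_end_to_end(block_name):
    rng = make_rng(11)
    x_data = rng.normal(size=(1, 8, 8, 3))
    cfg = BlockConfig(dropblock_rate=0.0)
    high_data = rng.normal(size=(1, 4, 4, 5))

    if block_name == "msrb":
        blk = MSRB(3, 4, cfg, rng=make_rng(1), dtype=np.float64)
        fn = lambda t: blk(t)
    elif block_name == "msam":
        blk = MSAM(3, rng=make_rng(2), dtype=np.float64)
        fn = lambda t: blk(t)
    elif block_name == "aaspp":
        blk = AASPP(3, 4, rng=make_rng(3), dtype=np.float64)
        fn = lambda t: blk(t)
    else:
        blk = RASM(3, 5, 4, cfg, rng=make_rng(4), dtype=np.float64)
        fn = lambda t: blk(t, Tensor(high_data))
    blk.eval()

    proj = rng.normal(size=fn(Tensor(x_data)).shape)
    xt = Tensor(x_data.copy(), requires_grad=True)
    (fn(xt) * Tensor(proj)).sum().backward()

    from conftest import finite_difference_grad

    numeric = finite_difference_grad(
        lambda arr: float((fn(Tensor(arr)).data * proj).sum()), x_data)
    rel = np.abs(xt.grad - numeric) / np.maximum(
        np.abs(xt.grad) + np.abs(numeric), 1e-8)
    assert rel.max() < 1e-3
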