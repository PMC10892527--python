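"""Network builders, parameter accounting and instantiation contracts."""

import numpy as np
import pytest

import hsiclass as h
from hsiclass import nn
from hsiclass.exceptions import SizeError
from hsiclass.networks import (block_parameters, instantiate, layer_table,
                               load_weights, save_weights, spec_from_yaml,
                               spec_to_yaml)

SMALL = dict(widths=(4, 8, 16, 16), stem_kernel=(3, 3, 3),
             pool_window=(2, 2, 2), default_input=(8, 5, 5))


def test_dgrnet34_published_parameter_count():
    """The 2-D 34-layer baseline at 30 input channels / 3 classes."""
    spec = h.build_dgrnet(34, in_channels=30, n_classes=3)
    assert h.count_parameters(spec) == 21_370_883


def test_dgrnet34_closed_form_decomposition():
    """Count = 3-channel standard 34-layer net + widened-stem correction."""
    base = h.count_parameters(h.build_dgrnet(34, in_channels=3, n_classes=3))
    assert base == 21_286_211
    for c in (10, 30, 64):
        widened = h.count_parameters(h.build_dgrnet(34, in_channels=c))
        assert widened == base + 64 * 7 * 7 * (c - 3)


def test_3d_dgrnet34_published_parameter_count():
    """The straightforward 3-D analogue reproduces the published total."""
    assert h.count_parameters(h.build_3d_dgrnet(34)) == 63_471_171


def test_parameter_monotonicity():
    assert (h.count_parameters(h.build_dgrnet(34, 30))
            > h.count_parameters(h.build_dgrnet(18, 30)))
    small = h.count_parameters(h.build_3d_rnet_o(widths=(64, 128, 256, 512)))
    large = h.count_parameters(h.build_3d_rnet_o(widths=(128, 256, 512, 1024)))
    assert large > small
    a3 = h.count_parameters(h.build_3d_rnet_o(widths=(8, 16, 32, 64), a=3))
    a5 = h.count_parameters(h.build_3d_rnet_o(widths=(8, 16, 32, 64), a=5))
    assert a5 > a3


@pytest.mark.parametrize("builder", [
    lambda: h.build_dgrnet(18, 30),
    lambda: h.build_dgrnet(34, 12),
    lambda: h.build_dgrnet(50, 30),
    lambda: h.build_3d_dgrnet(18),
    lambda: h.build_3d_rnet_o(**SMALL),
    lambda: h.build_3d_rnet_o(branches=(True, False), **SMALL),
    lambda: h.build_3d_rnet_o(branches=(False, True), **SMALL),
    lambda: h.build_3d_rnet_o(branches=(False, False), **SMALL),
    lambda: h.build_3d_rnet_o(a=5, **SMALL),
])
def test_count_equals_instantiated_enumeration(builder):
    """Analytic accounting == walk of the realized model's trainable scalars."""
    spec = builder()
    net = instantiate(spec, seed=3)
    assert h.count_parameters(spec) == net.n_parameters()


def test_dual_block_parameter_formula():
    """Hand enumeration of one dual block: 2*(3*64*64 + 9*64*64) branch convs,
    four branch BNs, 128->64 fusion conv + BN; identity shortcut."""
    blk = h.dual_branch_block(64, 64, a=3, stride=(1, 1, 1))
    expected = (2 * (3 * 64 * 64 + 9 * 64 * 64)  # branch convs
                + 4 * (2 * 64)                   # BN after each branch conv
                + (2 * 64) * 64 + 2 * 64)        # fusion conv + BN
    assert block_parameters(blk) == expected


def test_dual_block_degenerates_to_basic():
    blk = h.dual_branch_block(16, 32, a=3, stride=(2, 2, 2),
                              branches=(False, False))
    assert blk.kind == "basic"
    assert blk.kernel == (3, 3, 3)
    # block-for-block degeneracy against the plain 3-D network
    deg = h.build_3d_rnet_o(widths=(64, 128, 256, 512), a=3,
                            stem_kernel=(7, 7, 7), pool_window=(3, 3, 3),
                            branches=(False, False))
    ref = h.build_3d_dgrnet(34)
    assert deg.stages == ref.stages


def test_dual_block_kernels_in_both_orders():
    """Each dual block carries a x 1 x 1 and 1 x a x a kernels, both orders."""
    spec = h.build_3d_rnet_o(**SMALL)
    table = layer_table(spec)
    b1 = table[table.name.str.contains("stage1.block1.b1", regex=False)]
    b2 = table[table.name.str.contains("stage1.block1.b2", regex=False)]
    assert list(b1[b1.kernel != "-"].kernel) == ["3x1x1", "1x3x3"]
    assert list(b2[b2.kernel != "-"].kernel) == ["1x3x3", "3x1x1"]


def test_single_branch_has_no_fusion():
    spec = h.build_3d_rnet_o(branches=(True, False), **SMALL)
    table = layer_table(spec)
    assert not table.name.str.contains("fuse").any()
    assert not table.name.str.contains("b2").any()


def test_builder_validation():
    with pytest.raises(SizeError):
        h.build_dgrnet(26, 30)
    with pytest.raises(SizeError):
        h.build_3d_rnet_o(widths=(8, 16, 32))
    with pytest.raises(SizeError):
        h.build_3d_rnet_o(a=4)
    with pytest.raises(SizeError):
        h.dual_branch_block(8, 8, a=2)


def test_instantiate_softmax_simplex_and_batching():
    spec = h.build_3d_rnet_o(n_classes=3, **SMALL)
    net = instantiate(spec, seed=0)
    rng = np.random.default_rng(0)
    one = rng.normal(size=(1, 5, 5, 8)).astype(np.float32)
    p = net.predict_proba(one)
    assert p.shape == (1, 3)
    assert p.sum() == pytest.approx(1.0, abs=1e-6)
    batch = rng.normal(size=(7, 5, 5, 8)).astype(np.float32)
    pb = net.predict_proba(batch)
    assert pb.shape == (7, 3)
    np.testing.assert_allclose(pb.sum(axis=1), 1.0, atol=1e-6)
    with pytest.raises(SizeError):
        net.predict_proba(rng.normal(size=(2, 5, 5)))


def test_instantiate_seed_determinism():
    spec = h.build_3d_rnet_o(**SMALL)
    w1 = [p.value.copy() for p in instantiate(spec, seed=9).params()]
    w2 = [p.value.copy() for p in instantiate(spec, seed=9).params()]
    w3 = [p.value.copy() for p in instantiate(spec, seed=10).params()]
    for a, b in zip(w1, w2):
        np.testing.assert_array_equal(a, b)
    assert any(not np.array_equal(a, c) for a, c in zip(w1, w3))


@pytest.mark.parametrize("make_spec,patch_shape", [
    (lambda: h.build_3d_rnet_o(**SMALL), (2, 5, 5, 8)),
    (lambda: h.build_3d_dgrnet(18, default_input=(8, 5, 5)), (2, 5, 5, 8)),
    (lambda: h.build_dgrnet(18, in_channels=8), (2, 5, 5, 8)),
])
def test_shape_trace_matches_declared_widths(make_spec, patch_shape):
    """Realized channel widths after every residual block match the spec."""
    spec = make_spec()
    net = instantiate(spec, seed=1)
    x = net.patches_to_input(
        np.random.default_rng(0).normal(size=patch_shape).astype(np.float32))
    declared = [blk.out_width for _, _, blk in spec.blocks()]
    seen = []
    for layer in net.layers:
        x = layer.forward(x, train=False)
        if isinstance(layer, nn.Residual):
            seen.append(x.shape[1])
    assert seen == declared
    assert x.shape == (2, spec.head.n_classes)


def test_spec_yaml_round_trip():
    spec = h.build_3d_rnet_o(**SMALL)
    assert spec_from_yaml(spec_to_yaml(spec)) == spec


def test_weights_round_trip(tmp_path):
    spec = h.build_3d_rnet_o(**SMALL)
    net = instantiate(spec, seed=4)
    x = np.random.default_rng(2).normal(size=(3, 5, 5, 8)).astype(np.float32)
    before = net.predict_proba(x)
    save_weights(net, str(tmp_path / "w.npz"))
    other = load_weights(instantiate(spec, seed=99), str(tmp_path / "w.npz"))
    np.testing.assert_array_equal(other.predict_proba(x), before)
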