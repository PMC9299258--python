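"""Architecture contracts: pyramid sizes, inception block shapes,
receptive fields, head flattening order, fused forward pass."""

import numpy as np
import pytest

from rgbdssd import anchors, network
from rgbdssd.autodiff import Tensor

WIDTH = 0.0625  # desk-scale width used throughout these tests


@pytest.fixture(scope="module")
def fused_model():
    return network.build_model("fused", width_multiplier=WIDTH, seed=3)


def test_branch_pyramid_sizes_rgb():
    branch = network.build_branch(3, WIDTH,
                                  rng=np.random.default_rng(0))
    x = np.random.default_rng(1).normal(size=(1, 3, 300, 300)) \
        .astype(np.float32)
    pyr = branch(Tensor(x))
    assert pyr.spatial_sizes == (38, 19, 10, 5, 3, 1)
    assert pyr.branch == "rgb"


def test_depth_branch_accepts_single_channel():
    branch = network.build_branch(1, WIDTH,
                                  rng=np.random.default_rng(0))
    x = np.random.default_rng(1).normal(size=(1, 1, 300, 300)) \
        .astype(np.float32)
    assert branch(Tensor(x)).spatial_sizes == (38, 19, 10, 5, 3, 1)


def test_width_multiplier_changes_channels_not_sizes():
    wide = network.build_branch(3, 0.125, rng=np.random.default_rng(0))
    narrow = network.build_branch(3, WIDTH, rng=np.random.default_rng(0))
    assert wide.source_channels != narrow.source_channels
    x = np.random.default_rng(1).normal(size=(1, 3, 300, 300)) \
        .astype(np.float32)
    assert wide(Tensor(x)).spatial_sizes == narrow(Tensor(x)).spatial_sizes


def test_invalid_channel_count_rejected():
    with pytest.raises(ValueError):
        network.build_branch(2, WIDTH)
    with pytest.raises(ValueError):
        network.build_branch(3, 0.0)


class TestInceptionBlock:
    def test_shape_preserved_and_channels_concatenated(self):
        cfg = network.InceptionBlockConfig(4, 4, 4, dilation_3x3=2,
                                           width_pool=4)
        block = network.InceptionBlock(8, cfg,
                                       rng=np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 8, 13, 17)) \
            .astype(np.float32)
        out = block(Tensor(x))
        assert out.shape == (2, cfg.out_channels, 13, 17)

    def test_factorized_path_receptive_field_is_three(self):
        # 1x3 then 3x1 covers the same 3x3 support as one 3x3 kernel:
        # probe the gradient support of the factorized path
        cfg = network.InceptionBlockConfig(2, 2, 2)
        block = network.InceptionBlock(1, cfg,
                                       rng=np.random.default_rng(0))
        for conv in (block.path2a, block.path2b, block.path2c):
            conv.weight.data = np.abs(conv.weight.data) + 0.1
        x = Tensor(np.zeros((1, 1, 9, 9), dtype=np.float64),
                   requires_grad=True)
        y = block.path2c(block.path2b(block.path2a(x)))
        g = np.zeros(y.shape)
        g[0, 0, 4, 4] = 1.0
        y.backward(g)
        ys, xs = np.nonzero(np.abs(x.grad[0, 0]) > 1e-12)
        assert ys.max() - ys.min() + 1 == network.receptive_field([(3, 1, 1)])
        assert xs.max() - xs.min() + 1 == network.receptive_field([(3, 1, 1)])

    def test_invalid_dilation_rejected(self):
        with pytest.raises(ValueError):
            network.InceptionBlockConfig(2, 2, 2, dilation_3x3=3)


class TestReceptiveField:
    @pytest.mark.parametrize("stack,expected", [
        ([(3, 1, 1), (3, 1, 1)], 5),      # two plain 3x3
        ([(3, 1, 1), (3, 1, 2)], 7),      # 3x3 then dilated-2 3x3
        ([(1, 1, 1)], 1),
        ([(3, 2, 1), (3, 1, 1)], 7),      # stride grows the jump
    ])
    def test_analytic_values(self, stack, expected):
        assert network.receptive_field(stack) == expected

    @pytest.mark.parametrize("stack", [
        [(3, 1, 1), (3, 1, 1)],
        [(3, 1, 1), (3, 1, 2)],
        [(3, 1, 1), (3, 1, 1), (3, 1, 1)],
    ])
    def test_agrees_with_gradient_support_probe(self, stack):
        from rgbdssd.autodiff import Conv2d
        rng = np.random.default_rng(0)
        n = 31
        convs = []
        for k, s, d in stack:
            conv = Conv2d(1, 1, k, stride=s, padding=0, dilation=d,
                          rng=rng, dtype=np.float64)
            conv.weight.data = np.abs(conv.weight.data) + 0.1
            convs.append(conv)
        x = Tensor(np.zeros((1, 1, n, n)), requires_grad=True)
        y = x
        for conv in convs:
            y = conv(y)
        g = np.zeros(y.shape)
        g[0, 0, y.shape[2] // 2, y.shape[3] // 2] = 1.0
        y.backward(g)
        ys, xs = np.nonzero(np.abs(x.grad[0, 0]) > 1e-12)
        side = ys.max() - ys.min() + 1
        assert side == network.receptive_field(stack)


class TestHeadsAndForward:
    def test_single_branch_row_count(self):
        branch = network.build_branch(3, WIDTH,
                                      rng=np.random.default_rng(0))
        heads = network.DetectionHeads(
            branch.source_channels, (4, 6, 6, 6, 4, 4),
            rng=np.random.default_rng(1))
        x = np.random.default_rng(2).normal(size=(1, 3, 300, 300)) \
            .astype(np.float32)
        loc, conf = heads(branch(Tensor(x)))
        assert loc.shape == (1, 8732, 4)
        assert conf.shape == (1, 8732, 7)

    def test_flattening_order_matches_priors(self):
        # inject a one-hot spatial marker through an identity-like head
        # and find it at the predicted flat position
        specs = [anchors.LayerSpec(4, 30, 60), anchors.LayerSpec(2, 60, 111)]
        priors = anchors.generate_priors(specs)
        from rgbdssd.network import DetectionHeads, FeaturePyramid
        heads = DetectionHeads((1, 1), (4, 4),
                               rng=np.random.default_rng(0))
        for h in heads.loc_heads:       # delta kernel: output = input value
            h.weight.data[:] = 0.0
            h.weight.data[:, 0, 1, 1] = 1.0
            h.bias.data[:] = 0.0
        for cell_row, cell_col, layer in [(0, 0, 0), (2, 3, 0), (1, 0, 1)]:
            maps = [Tensor(np.zeros((1, 1, 4, 4), dtype=np.float32)),
                    Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32))]
            maps[layer].data[0, 0, cell_row, cell_col] = 1.0
            pyr = FeaturePyramid.__new__(FeaturePyramid)
            pyr.maps = maps
            pyr.branch = "rgb"
            loc, _ = heads(pyr)
            hot = np.flatnonzero(loc.data[0].sum(axis=1) != 0)
            grid = specs[layer].grid
            base = 0 if layer == 0 else 4 * 4 * 4
            start = base + (cell_row * grid + cell_col) * 4
            assert hot.tolist() == list(range(start, start + 4))
            # and those flat rows carry the priors of that very cell
            expect_center = ((cell_col + 0.5) / grid, (cell_row + 0.5) / grid)
            np.testing.assert_allclose(priors.boxes[start][:2],
                                       expect_center)

    def test_fused_forward_row_count_and_finiteness(self, fused_model):
        rng = np.random.default_rng(0)
        rgb = rng.normal(size=(2, 3, 300, 300)).astype(np.float32)
        depth = rng.normal(size=(2, 1, 300, 300)).astype(np.float32)
        det = fused_model.rd_ssd_forward(rgb, depth)
        assert det.loc.shape == (2, 17464, 4)
        assert det.conf.shape == (2, 17464, 7)
        assert len(det.priors) == 17464
        assert np.isfinite(det.loc.data).all()
        assert np.isfinite(det.conf.data).all()

    def test_zero_inputs_finite(self, fused_model):
        det = fused_model.forward(np.zeros((1, 3, 300, 300), np.float32),
                                  np.zeros((1, 1, 300, 300), np.float32))
        assert np.isfinite(det.loc.data).all()
        assert np.isfinite(det.conf.data).all()

    def test_batch_equivariance(self, fused_model):
        rng = np.random.default_rng(4)
        rgb = rng.normal(size=(2, 3, 300, 300)).astype(np.float32)
        depth = rng.normal(size=(2, 1, 300, 300)).astype(np.float32)
        det = fused_model.forward(rgb, depth)
        det_swapped = fused_model.forward(rgb[::-1].copy(),
                                          depth[::-1].copy())
        np.testing.assert_allclose(det.loc.data[::-1],
                                   det_swapped.loc.data, atol=1e-5)

    def test_shape_mismatch_rejected(self, fused_model):
        with pytest.raises(ValueError):
            fused_model.forward(np.zeros((1, 3, 200, 200), np.float32),
                                np.zeros((1, 1, 300, 300), np.float32))
        with pytest.raises(ValueError):
            fused_model.forward(np.zeros((1, 3, 300, 300), np.float32),
                                None)
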