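import numpy as np
import pytest

from spotspray.detector import (DepthwiseSeparableConv, MNv3Bottleneck, SEBlock,
                                mac_ratio, separable_macs, standard_macs)
from spotspray.detector.autograd import Tensor
from spotspray.detector.blocks import ConfigurationError
from spotspray.detector.nn import HSwish


class TestSEBlock:
    def test_zero_input_gives_zero_output(self):
        se = SEBlock(8, reduction=4)
        out = se(Tensor(np.zeros((1, 8, 5, 5))))
        assert np.all(out.data == 0)

    def test_channel_weights_strictly_inside_unit_interval(self):
        se = SEBlock(8, reduction=4, rng=np.random.default_rng(1))
        w = se.channel_weights(Tensor(np.random.default_rng(2).normal(size=(2, 8, 7, 7))))
        assert np.all(w.data > 0) and np.all(w.data < 1)

    def test_shape_preserved_and_unit_weights_recover_input(self):
        rng = np.random.default_rng(3)
        se = SEBlock(4, reduction=2, rng=rng)
        x = rng.normal(size=(2, 4, 6, 6))
        out = se(Tensor(x))
        assert out.shape == x.shape
        # force the gate wide open: huge positive bias on the second FC
        se.fc2.bias.data[:] = 1e3
        recovered = se(Tensor(x))
        assert np.allclose(recovered.data, x)

    def test_hand_computed_two_channel_case(self):
        """1x1 input, identity FC weights, zero biases: the SE weight is
        sigmoid of the channel mean itself, applied multiplicatively."""
        se = SEBlock(2, reduction=1)
        se.fc1.weight.data = np.eye(2).reshape(2, 2, 1, 1)
        se.fc1.bias.data[:] = 0
        se.fc2.weight.data = np.eye(2).reshape(2, 2, 1, 1)
        se.fc2.bias.data[:] = 0
        x = np.array([[[[2.0]], [[-1.0]]]])  # (1, 2, 1, 1)
        relu = np.maximum(x[0, :, 0, 0], 0)
        expected = x[0, :, 0, 0] / (1 + np.exp(-relu))
        out = se(Tensor(x))
        assert np.allclose(out.data[0, :, 0, 0], expected)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ConfigurationError):
            SEBlock(6, reduction=4)


class TestDepthwiseSeparable:
    def test_mac_ratio_closed_form(self):
        assert mac_ratio(64, 3) == pytest.approx(1 / 64 + 1 / 9)
        assert mac_ratio(64, 3) == pytest.approx(0.1267, abs=5e-4)

    @pytest.mark.parametrize("c_in,c_out,k,h,w", [
        (16, 64, 3, 20, 20), (8, 8, 5, 7, 9), (3, 32, 3, 64, 64)])
    def test_direct_mac_counting_matches_ratio(self, c_in, c_out, k, h, w):
        sep = separable_macs(c_in, c_out, k, h, w)
        std = standard_macs(c_in, c_out, k, h, w)
        assert sep / std == pytest.approx(mac_ratio(c_out, k))
        assert sep == c_in * k * k * h * w + c_in * c_out * h * w

    def test_separable_cheaper_for_all_nontrivial_shapes(self):
        for k in range(2, 8):
            for c_out in range(2, 130, 7):
                assert mac_ratio(c_out, k) < 1

    def test_stride_two_halves_spatial_dims(self):
        conv = DepthwiseSeparableConv(4, 8, k=3, stride=2,
                                      rng=np.random.default_rng(0))
        out = conv(Tensor(np.random.default_rng(1).normal(size=(1, 4, 16, 16))))
        assert out.shape == (1, 8, 8, 8)


class TestBottleneck:
    def test_zero_weights_shortcut_is_identity(self):
        block = MNv3Bottleneck(8, 16, 8, k=3, stride=1, use_se=False, act=HSwish,
                               rng=np.random.default_rng(0))
        for p in block.parameters():
            if p.data.ndim >= 2 or p.data.ndim == 3:
                p.data[:] = 0
        # zero out conv kernels only; BN of an all-zero map is its beta (=0)
        x = np.random.default_rng(1).normal(size=(2, 8, 6, 6))
        out = block(Tensor(x))
        assert np.allclose(out.data, x)

    def test_stride_two_has_no_shortcut_and_halves_dims(self):
        block = MNv3Bottleneck(8, 16, 8, k=3, stride=2, use_se=True, act=HSwish,
                               rng=np.random.default_rng(0))
        assert not block.use_shortcut
        out = block(Tensor(np.random.default_rng(1).normal(size=(1, 8, 12, 12))))
        assert out.shape == (1, 8, 6, 6)

    def test_parameter_count_matches_closed_form(self):
        c_in, expand, c_out, k = 8, 24, 12, 5
        block = MNv3Bottleneck(c_in, expand, c_out, k, stride=1, use_se=False,
                               act=HSwish, rng=np.random.default_rng(0))
        expected = (c_in * expand + 2 * expand          # expand 1x1 + BN
                    + expand * k * k + 2 * expand       # depthwise + BN
                    + expand * c_out + 2 * c_out)       # project 1x1 + BN
        assert sum(p.data.size for p in block.parameters()) == expected
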