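"""MERCA block: scale adapters, edge refiner, aggregation."""

import numpy as np
import pytest

from lmtb import functional as F
from lmtb import nn
from lmtb.blocks.merca import MERCA, EdgeRefiner, MercaConfig, ScaleAdapter
from lmtb.tensor import Tensor

from conftest import zero_biases


def conv_param_count(c_in, c_out, k, groups=1, bias=False, bn=True):
    n = k * k * (c_in // groups) * c_out
    if bias:
        n += c_out
    if bn:
        n += 2 * c_out
    return n


class TestScaleAdapter:
    def test_default_scale_set_is_3k(self):
        cfg = MercaConfig(64, 64)
        assert cfg.scales == (3, 6, 9, 12)
        assert len(cfg.scales) == 4

    def test_output_grid_size(self, rng):
        ad = ScaleAdapter(64, 16, 3, groups=16)
        x = Tensor(rng.normal(size=(1, 64, 32, 32)).astype(np.float32))
        assert ad(x).shape == (1, 16, 3, 3)

    def test_linear_mean_preserving_path_keeps_constants(self):
        """Pool + mean-preserving convs keep a constant field constant."""
        ad = ScaleAdapter(8, 4, 3, groups=4)
        ad.reduce.act = nn.Identity()
        ad.mix.act = nn.Identity()
        for conv in (ad.reduce, ad.mix):
            conv.bn.eval()  # identity normalisation (fresh running stats)
            conv.bn.eps = 0.0
        ad.reduce.conv.weight.data[:] = 1.0 / 8.0  # 1x1 average over channels
        ad.mix.conv.weight.data[:] = 0.0
        ad.mix.conv.weight.data[:, :, 1, 1] = 1.0  # Dirac
        c = 2.75
        x = Tensor(np.full((1, 8, 12, 12), c, dtype=np.float32))
        out = ad(x).data
        np.testing.assert_allclose(out, c, atol=1e-5)

    def test_adaptive_pool_matches_window_mean_oracle(self, rng):
        for H in (4, 9, 16):
            for g in range(1, 13):
                if g > H:
                    continue
                x = rng.normal(size=(1, 3, H, H))
                out = F.adaptive_avg_pool2d(Tensor(x), g).data
                for i in range(g):
                    h0, h1 = i * H // g, -(-(i + 1) * H // g)
                    for j in range(g):
                        w0, w1 = j * H // g, -(-(j + 1) * H // g)
                        np.testing.assert_allclose(
                            out[:, :, i, j],
                            x[:, :, h0:h1, w0:w1].mean(axis=(2, 3)),
                            atol=1e-12,
                        )

    def test_invalid_configs_raise(self):
        with pytest.raises(ValueError):
            ScaleAdapter(8, 4, 0, groups=4)  # non-positive pooled size
        with pytest.raises(ValueError):
            ScaleAdapter(8, 6, 3, groups=4)  # width not divisible by groups
        with pytest.raises(ValueError):
            MercaConfig(32, 64, scales=(6, 3, 9, 12))  # not increasing


class TestEdgeRefiner:
    def test_identity_on_constants(self):
        er = EdgeRefiner(3)
        er.conv.bias.data[:] = 0.0
        x = Tensor(np.full((1, 3, 8, 8), 4.25, dtype=np.float32))
        np.testing.assert_array_equal(er(x).data, x.data)

    def test_zero_conv_passes_input_exactly(self, rng):
        er = EdgeRefiner(2)
        er.conv.weight.data[:] = 0.0
        er.conv.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32))
        np.testing.assert_array_equal(er(x).data, x.data)

    def test_hand_computed_center_spike(self):
        """Dirac conv: centre 9 + (9 - mean 1) = 17 per the worked example."""
        er = EdgeRefiner(1)
        er.conv.weight.data[:] = 0.0
        er.conv.weight.data[0, 0, 1, 1] = 1.0
        er.conv.bias.data[:] = 0.0
        x = np.zeros((1, 1, 3, 3), dtype=np.float32)
        x[0, 0, 1, 1] = 9.0
        out = er(Tensor(x)).data
        assert out[0, 0, 1, 1] == pytest.approx(17.0)

    def test_output_minus_input_is_conv_of_highfreq_residual(self, rng):
        """ER(X) - X equals Conv applied to the box-filter residual X - P_avg(X)."""
        x = rng.normal(size=(1, 1, 12, 12)).astype(np.float32)
        hf = x - F.avg_pool2d(Tensor(x), 3, 1, 1, count_include_pad=False).data
        er = EdgeRefiner(1)
        out = er(Tensor(x)).data
        conv_of_hf = F.conv2d(
            Tensor(hf), Tensor(er.conv.weight.data), Tensor(er.conv.bias.data), 1, 1, 1
        ).data
        np.testing.assert_allclose(out - x, conv_of_hf, atol=1e-5)


class TestMercaForward:
    @pytest.mark.parametrize("hw", [(32, 32), (20, 20), (17, 23)])
    def test_shape_preservation(self, rng, hw):
        m = MERCA(32, 64)
        x = Tensor(rng.normal(size=(1, 32, *hw)).astype(np.float32))
        assert m(x).shape == (1, 64, *hw)

    def test_small_inputs_clamp_pool_sizes(self, rng):
        m = MERCA(32, 64)
        x = Tensor(rng.normal(size=(1, 32, 5, 5)).astype(np.float32))
        assert m(x).shape == (1, 64, 5, 5)

    def test_zero_input_zero_biases_gives_zero_output(self):
        m = zero_biases(MERCA(32, 64))
        m.eval()
        x = Tensor(np.zeros((1, 32, 16, 16), dtype=np.float32))
        np.testing.assert_allclose(m(x).data, 0.0, atol=1e-7)

    def test_param_count_matches_closed_form(self):
        c1, c2, N, g = 64, 128, 4, 16
        m = MERCA(c1, c2, groups=g)
        cb = c2 // N
        expected = (
            conv_param_count(c1, c2, 1)              # local
            + conv_param_count(2 * c2, c2, 1)        # aggregation
            + N * (
                conv_param_count(c1, cb, 1)          # 1x1 reduce
                + conv_param_count(cb, cb, 3, groups=g)  # grouped 3x3
                + 9 * cb + cb                        # depthwise 3x3 edge conv + bias
            )
        )
        assert m.num_params() == expected

    def test_gradients_reach_every_parameter(self, rng):
        m = MERCA(16, 32, groups=8)
        x = Tensor(rng.normal(size=(2, 16, 14, 14)).astype(np.float32))
        out = m(x)
        (out * out).mean().backward()
        for name, p in m.named_parameters():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
            assert np.any(p.grad != 0), name
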