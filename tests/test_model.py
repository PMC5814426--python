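"""Architecture spec, parameter-count oracle, forward/backward passes."""

import numpy as np
import pytest

import eegsex as e
from eegsex.model import ArchSpec, ConvSpec, DenseSpec, PoolSpec, DropoutSpec


class TestDefaultArchSpec:
    def test_six_conv_layers(self):
        spec = e.default_archspec()
        convs = [sp for sp in spec.layers if isinstance(sp, ConvSpec)]
        assert len(convs) == 6
        assert [c.n_filters for c in convs] == [100, 100, 300, 300, 100, 100]
        assert [(c.kh, c.kw) for c in convs] == [(3, 3), (3, 3), (2, 3),
                                                (1, 7), (1, 3), (1, 3)]

    def test_pooling_stack(self):
        spec = e.default_archspec()
        pools = [sp for sp in spec.layers if isinstance(sp, PoolSpec)]
        assert [(p.ph, p.pw) for p in pools] == [(2, 2), (2, 2), (2, 2),
                                                (1, 2)]

    def test_dropout_positions(self):
        spec = e.default_archspec()
        drops = [sp for sp in spec.layers if isinstance(sp, DropoutSpec)]
        assert len(drops) == 4
        assert all(d.rate == 0.25 for d in drops)

    def test_shape_arithmetic(self):
        """Channel axis 24-12-6-3-3, time axis 256-128-64-32-16."""
        spec = e.default_archspec()
        shapes = spec.shape_walk()
        pool_shapes = [s for sp, s in zip(spec.layers, shapes)
                       if isinstance(sp, PoolSpec)]
        assert [(h, w) for _, h, w in pool_shapes] == [
            (12, 128), (6, 64), (3, 32), (3, 16)]
        # feature block before the dense head: 100 x 3 x 16 = 4800
        c, h, w = shapes[-2]
        assert c * h * w == 4800

    def test_json_roundtrip(self):
        spec = e.default_archspec(filter_scale=0.5)
        back = ArchSpec.from_json(spec.to_json())
        assert back == spec


class TestCountParameters:
    def test_single_conv_hand_formula(self):
        spec = ArchSpec(input_shape=(24, 256), layers=(
            ConvSpec(100, 3, 3), DenseSpec(2)))
        conv_params = (3 * 3 * 1 + 1) * 100
        dense_params = (100 * 24 * 256 + 1) * 2
        assert e.count_parameters(spec) == conv_params + dense_params
        assert conv_params == 1000

    def test_dense_hand_formula(self):
        # a 4800-input 2-unit head costs (4800+1)*2 = 9602
        spec = e.default_archspec()
        total = e.count_parameters(spec)
        assert total - 1_021_900 == 9602

    def test_table_conv_subtotal(self):
        """Conv-stack subtotal of the reference layer stack is 1,021,900."""
        spec = e.default_archspec()
        dense = 9602
        assert e.count_parameters(spec) - dense == 1_021_900

    @pytest.mark.parametrize("scale,channels", [(1.0, 24), (0.25, 24),
                                                (0.25, 10), (0.1, 24)])
    def test_matches_built_network(self, scale, channels):
        """Hand count equals the sum of actual parameter array sizes."""
        spec = e.default_archspec(n_channels=channels, filter_scale=scale)
        net = e.build_network(spec, seed=0)
        assert net.n_parameters() == e.count_parameters(spec)


class TestBuildNetwork:
    def test_probabilities_sum_to_one(self, tiny_net):
        x = np.random.default_rng(0).normal(size=(5, 32, 8))
        p = tiny_net.predict_proba(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_same_seed_same_init(self):
        spec = e.default_archspec(filter_scale=0.1)
        a, b = e.build_network(spec, 3), e.build_network(spec, 3)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)
        c = e.build_network(spec, 4)
        assert not all(np.array_equal(pa, pc)
                       for (pa, _), (pc, _) in zip(a.parameters(),
                                                   c.parameters()))

    def test_hemisphere_network_builds(self):
        spec = e.default_archspec(n_channels=10, filter_scale=0.25)
        net = e.build_network(spec, 0)
        p = net.predict_proba(np.random.default_rng(1).normal(
            size=(3, 256, 10)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_collapsing_pool_rejected(self):
        spec = ArchSpec(input_shape=(2, 8), layers=(
            ConvSpec(4, 3, 3), PoolSpec(2, 2), PoolSpec(2, 2),
            DenseSpec(2)))
        with pytest.raises(e.ArchitectureError):
            e.build_network(spec, 0)

    def test_inference_deterministic(self, tiny_net):
        x = np.random.default_rng(2).normal(size=(4, 32, 8))
        assert np.array_equal(tiny_net.predict_proba(x),
                              tiny_net.predict_proba(x))

    def test_save_load_roundtrip(self, tmp_path, tiny_net):
        p = tmp_path / "net.npz"
        tiny_net.save(p)
        back = e.Network.load(p)
        x = np.random.default_rng(3).normal(size=(2, 32, 8))
        assert np.allclose(back.predict_proba(x),
                           tiny_net.predict_proba(x))


class TestLayerActivation:
    def test_zero_input_zero_maps(self, tiny_net):
        maps = e.layer_activation(tiny_net, 1, np.zeros((1, 32, 8)))
        assert np.allclose(maps, 0.0)  # zero bias + ReLU

    def test_same_padding_keeps_spatial_size(self):
        spec = e.default_archspec(filter_scale=0.05)
        net = e.build_network(spec, 0)
        maps = e.layer_activation(net, 1, np.zeros((1, 256, 24)))
        assert maps.shape[2:] == (24, 256)

    def test_out_of_range_layer(self, tiny_net):
        with pytest.raises(IndexError):
            e.layer_activation(tiny_net, 99, np.zeros((1, 32, 8)))


def _linear_single_filter_net(kh=3, kw=5, n_ch=6, n_t=24, seed=0):
    spec = ArchSpec(input_shape=(n_ch, n_t), layers=(
        ConvSpec(1, kh, kw, activation="linear"), DenseSpec(2)))
    return e.build_network(spec, seed=seed)


class TestInputGradient:
    def test_linear_net_gradient_is_input_independent(self):
        """For a linear conv the gradient of the mean activation is a
        fixed arrangement of the filter weights."""
        net = _linear_single_filter_net()
        rng = np.random.default_rng(0)
        g1 = e.input_gradient(net, 1, 0, rng.normal(size=(24, 6)))
        g2 = e.input_gradient(net, 1, 0, rng.normal(size=(24, 6)))
        assert np.allclose(g1, g2, atol=1e-6)
        # interior coordinate: gradient = sum of kernel weights / map size
        kernel = net.layers[0].kernel()[..., 0, 0]
        hw = 6 * 24
        assert g1[10, 3] == pytest.approx(kernel.sum() / hw, rel=1e-4)

    def test_matches_finite_differences(self):
        """Central finite differences agree to <= 1e-3 relative error."""
        spec = ArchSpec(input_shape=(8, 32), layers=(
            ConvSpec(4, 3, 3, activation="linear"), PoolSpec(2, 2),
            ConvSpec(6, 2, 3, activation="linear"), DenseSpec(2)))
        net = e.build_network(spec, seed=5)
        x = np.random.default_rng(7).normal(size=(32, 8)).astype(np.float32)
        g = e.input_gradient(net, 2, 2, x)
        rng = np.random.default_rng(8)
        eps = 1e-2
        for _ in range(10):
            i, j = int(rng.integers(0, 32)), int(rng.integers(0, 8))
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            fp = e.layer_activation(net, 2, xp[None])[0, 2].mean()
            fm = e.layer_activation(net, 2, xm[None])[0, 2].mean()
            fd = (fp - fm) / (2 * eps)
            assert abs(fd - g[i, j]) <= 1e-3 * max(abs(fd), 1e-6)

    def test_zero_weight_network(self):
        net = _linear_single_filter_net()
        net.layers[0].W[:] = 0.0
        g = e.input_gradient(net, 1, 0, np.ones((24, 6)))
        assert np.allclose(g, 0.0)

    def test_invalid_filter_index(self, tiny_net):
        with pytest.raises(IndexError):
            e.input_gradient(tiny_net, 1, 99, np.zeros((32, 8)))
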