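"""Edge belts, frequency attention, and the saliency network's contracts."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from echomvp import nn
from echomvp.data import DataError, ValidationError
from echomvp.heatmap import (
    HeatmapModel,
    HeatmapNet,
    HeatmapTrainConfig,
    frequency_attention,
    make_edge_belt,
    train_heatmap,
)


def belt_oracle(mask: np.ndarray, w: int) -> np.ndarray:
    """All-pairs Chebyshev-distance reference for the edge belt."""
    mask = mask.astype(bool)
    h, wd = mask.shape
    ys, xs = np.nonzero(mask)
    boundary = []
    for y, x in zip(ys, xs):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < wd and not mask[ny, nx]:
                    boundary.append((y, x))
                    break
            else:
                continue
            break
    belt = np.zeros_like(mask)
    if not boundary:
        return belt
    yy, xx = np.mgrid[0:h, 0:wd]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    dists = cdist(pts, np.array(boundary), metric="chebyshev").min(axis=1)
    return (dists <= w).reshape(h, wd)


def random_blob_mask(rng, size=48):
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.random((size, size)), 4)
    return noise > np.quantile(noise, 0.8)


class TestMakeEdgeBelt:
    def test_empty_mask_gives_empty_belt(self):
        belt = make_edge_belt(np.zeros((32, 32), bool), w=4)
        assert not belt.mask.any()

    def test_square_perimeter_at_width_zero(self):
        mask = np.zeros((64, 64), bool)
        mask[10:30, 10:30] = True
        belt = make_edge_belt(mask, w=0)
        assert belt.mask.sum() == 4 * 20 - 4  # brute-force perimeter count

    def test_square_belt_matches_distance_oracle(self):
        mask = np.zeros((64, 64), bool)
        mask[10:30, 10:30] = True
        np.testing.assert_array_equal(make_edge_belt(mask, w=2).mask, belt_oracle(mask, 2))

    def test_negative_width_rejected(self):
        with pytest.raises(ValidationError):
            make_edge_belt(np.ones((4, 4), bool), w=-1)

    def test_random_blobs_match_oracle(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng)
            for w in (0, 1, 3):
                np.testing.assert_array_equal(
                    make_edge_belt(mask, w).mask, belt_oracle(mask, w)
                )

    def test_belt_monotone_in_width_and_contains_boundary(self, rng):
        mask = random_blob_mask(rng)
        boundary = make_edge_belt(mask, 0).mask
        prev = boundary
        for w in (1, 2, 3, 5):
            belt = make_edge_belt(mask, w).mask
            assert (prev <= belt).all()  # belt(w) subset of belt(w+1)
            assert (boundary <= belt).all()
            prev = belt


class TestFrequencyAttention:
    def test_unit_weights_double_the_input(self, rng):
        x = rng.normal(size=(2, 16, 16))
        np.testing.assert_allclose(
            frequency_attention(x, np.ones((2, 16, 16))), 2 * x, rtol=1e-10
        )

    def test_zero_weights_are_identity(self, rng):
        x = rng.normal(size=(2, 8, 8))
        np.testing.assert_allclose(
            frequency_attention(x, np.zeros((2, 8, 8))), x, atol=1e-12
        )

    def test_matches_dense_dft_matrix_oracle(self, rng):
        """Direct DFT-matrix evaluation of the spectral gate on 8x8 maps."""
        h = w = 8
        x = rng.normal(size=(1, h, w))
        weights = rng.normal(size=(1, h, w))
        # dense 2-D DFT matrix: F[(ky,kx),(y,x)] = exp(-2i pi (ky y/h + kx x/w))
        ky, kx = np.mgrid[0:h, 0:w].reshape(2, -1)
        y, xpix = np.mgrid[0:h, 0:w].reshape(2, -1)
        F = np.exp(-2j * np.pi * (np.outer(ky, y) / h + np.outer(kx, xpix) / w))
        sym = 0.5 * (
            weights[0]
            + np.roll(weights[0][::-1, ::-1], shift=(1, 1), axis=(0, 1))
        )
        spectrum = F @ x[0].ravel()
        expected = np.real(np.linalg.inv(F) @ (sym.ravel() * spectrum)).reshape(h, w) + x[0]
        got = frequency_attention(x, weights)[0]
        assert np.abs(got - expected).max() / np.abs(expected).max() < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            frequency_attention(rng.normal(size=(2, 8, 8)), np.ones((2, 4, 4)))


class TestNetworkContracts:
    @pytest.fixture()
    def net(self):
        return HeatmapNet(input_size=64, rng=np.random.default_rng(0))

    def _pyramid(self, net, x):
        return net.extract_pyramid(nn.Tensor(x.astype(np.float32)))

    def test_pyramid_strides_and_layer_count(self, net, rng):
        pyr = self._pyramid(net, rng.random((1, 3, 64, 64)))
        sizes = [t.data.shape[-1] for t in pyr.layers]
        assert sizes == [16, 8, 4, 2]  # strides 4/8/16/32

    def test_content_map_is_stride8_single_channel(self, net, rng):
        pyr = self._pyramid(net, rng.random((1, 3, 64, 64)))
        content = net.detect_content(pyr)
        assert content.data.shape == (1, 1, 8, 8)

    def test_edge_map_is_stride4_single_channel(self, net, rng):
        pyr = self._pyramid(net, rng.random((1, 3, 64, 64)))
        edge = net.detect_edge(pyr)
        assert edge.data.shape == (1, 1, 16, 16)

    def test_zero_features_give_constant_maps(self, net):
        zeros = [
            nn.Tensor(np.zeros((1, c, s, s), dtype=np.float32))
            for c, s in zip(HeatmapNet.CHANNELS, (16, 8, 4, 2))
        ]
        from echomvp.heatmap import FeaturePyramid

        pyr = FeaturePyramid(tuple(zeros))
        content = net.detect_content(pyr)
        assert np.allclose(content.data, content.data.flat[0])
        edge = net.detect_edge(pyr)
        assert np.allclose(edge.data, edge.data.flat[0])
        final = net.refine_and_fuse(pyr, content, edge)
        assert np.allclose(final.data, final.data.flat[0])

    def test_detection_heads_are_linear_with_bias_frozen(self, net, rng):
        """Doubling pre-activation features doubles logits when biases are 0."""
        import copy

        probe = copy.deepcopy(net)
        for p in (probe.content_fuse, probe.content_head, probe.edge_fuse, probe.edge_head):
            p.bias.data = np.zeros_like(p.bias.data)
        feats = [
            rng.random((1, c, s, s)).astype(np.float32)
            for c, s in zip(HeatmapNet.CHANNELS, (16, 8, 4, 2))
        ]
        from echomvp.heatmap import FeaturePyramid

        single = FeaturePyramid(tuple(nn.Tensor(f) for f in feats))
        double = FeaturePyramid(tuple(nn.Tensor(2 * f) for f in feats))
        np.testing.assert_allclose(
            2 * probe.detect_content(single).data,
            probe.detect_content(double).data, rtol=1e-4,
        )
        np.testing.assert_allclose(
            2 * probe.detect_edge(single).data, probe.detect_edge(double).data, rtol=1e-4
        )

    def test_saturated_content_gate_reduces_to_plain_fusion(self, net, rng):
        feats = [
            rng.random((1, c, s, s)).astype(np.float32)
            for c, s in zip(HeatmapNet.CHANNELS, (16, 8, 4, 2))
        ]
        from echomvp.heatmap import FeaturePyramid

        pyr = FeaturePyramid(tuple(nn.Tensor(f) for f in feats))
        edge = net.detect_edge(pyr)
        huge = nn.Tensor(np.full((1, 1, 8, 8), 40.0, dtype=np.float32))
        gated = net.refine_and_fuse(pyr, huge, edge)
        # saturated gates = 1: manual ungated fusion through the same convs
        h = nn.upsample_nearest(nn.relu(net.ref4(pyr.layers[3])), 2)
        h = nn.upsample_nearest(nn.relu(net.ref3(h + pyr.layers[2])), 2)
        h = nn.upsample_nearest(nn.relu(net.ref2(h + pyr.layers[1])), 2)
        h = nn.mul(h, nn.sigmoid(edge))
        h = nn.relu(net.ref1(nn.upsample_nearest(h, 2)))
        h = nn.relu(net.ref0(nn.upsample_nearest(h, 2)))
        plain = net.final_head(h)
        np.testing.assert_allclose(gated.data, plain.data, atol=1e-4)
        # a half-open gate (logit 0 -> 0.5) must actually change the output
        mid = nn.Tensor(np.zeros((1, 1, 8, 8), dtype=np.float32))
        assert not np.allclose(net.refine_and_fuse(pyr, mid, edge).data, plain.data)

    def test_forward_preserves_size_and_codomain(self, rng):
        model = HeatmapModel(HeatmapNet(input_size=64, rng=np.random.default_rng(1)), 64)
        for size in (64, 96):
            frame = (rng.random((size, size)) * 255).astype(np.uint8)
            heat = model.predict(frame)
            assert heat.shape == frame.shape
            assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_inference_is_deterministic(self, rng):
        model = HeatmapModel(HeatmapNet(input_size=64, rng=np.random.default_rng(2)), 64)
        frame = (rng.random((64, 64)) * 255).astype(np.uint8)
        np.testing.assert_array_equal(model.predict(frame), model.predict(frame))

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValidationError):
            HeatmapNet(input_size=60)


class TestHeatmapTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train_heatmap([], [])

    def test_frames_without_prolapse_rejected(self, control_case):
        with pytest.raises(DataError):
            train_heatmap(
                [control_case.cine.frames[0]], [np.zeros((192, 192), bool)]
            )

    def test_same_seed_same_first_step_loss(self, mvp_case):
        t = mvp_case.phase_labels.systolic_indices()[0]
        frame, mask = mvp_case.cine.frames[t], mvp_case.masks[t] == 3
        cfg = HeatmapTrainConfig(max_steps=1, input_size=64, seed=9)
        _, la = train_heatmap([frame], [mask], cfg)
        _, lb = train_heatmap([frame], [mask], cfg)
        assert la[0] == pytest.approx(lb[0], rel=1e-9)

    def test_save_load_roundtrip(self, tmp_path, mvp_case):
        t = mvp_case.phase_labels.systolic_indices()[0]
        frame, mask = mvp_case.cine.frames[t], mvp_case.masks[t] == 3
        model, _ = train_heatmap(
            [frame], [mask], HeatmapTrainConfig(max_steps=2, input_size=64, seed=0)
        )
        model.save(tmp_path / "h.npz")
        loaded = HeatmapModel.load(tmp_path / "h.npz")
        np.testing.assert_allclose(model.predict(frame), loaded.predict(frame), rtol=1e-6)
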