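"""Edge-belt-guided saliency segmentation of the prolapse region.

The heatmap model turns a systolic frame into a per-pixel prolapse saliency
map in [0, 1].  A four-level convolutional pyramid (strides 4/8/16/32)
extracts features; learnable frequency-domain attention refines the two
shallow levels; a content-detection head fuses levels 2–4 into a coarse
content map and an edge-detection head reads level 1, which carries the
most edge information.  Levels 2–4 are then modulated by the sigmoid of the
content map and fused top-down, progressively, under the guidance of the
edge map, to produce the refined saliency map.

Edge supervision does not target the one-pixel boundary but an *edge belt*:
all pixels within Chebyshev distance ``w`` of the mask boundary.  The belt
thickness tolerates small annotation bias at the prolapse rim while still
concentrating learning on the boundary region.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy import ndimage
from skimage import transform as _sktransform

from . import nn
from .data import DataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeBelt", "FeaturePyramid", "HeatmapTrainConfig", "HeatmapModel",
    "make_edge_belt", "frequency_attention", "train_heatmap", "predict_heatmap",
    "write_heatmap_png",
]

DEFAULT_BELT_WIDTH = 3
_CHEBYSHEV = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Edge-belt generation


@dataclass
class EdgeBelt:
    mask: np.ndarray  # boolean belt support
    belt_width: int


def make_edge_belt(mask: np.ndarray, w: int = DEFAULT_BELT_WIDTH) -> EdgeBelt:
    """Thickened boundary of a binary mask.

    Boundary pixels are mask pixels 8-adjacent to background (within the
    image; the frame border itself does not create boundary).  The belt is
    every pixel within Chebyshev distance <= w of a boundary pixel; an
    empty mask yields an empty belt.  Deterministic.
    """
    if w < 0:
        raise ValidationError("belt width must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return EdgeBelt(np.zeros_like(mask), w)
    interior = ndimage.binary_erosion(mask, _CHEBYSHEV, border_value=1)
    boundary = mask & ~interior
    belt = boundary
    if w > 0:
        belt = ndimage.binary_dilation(boundary, _CHEBYSHEV, iterations=w)
    return EdgeBelt(belt, w)


# ---------------------------------------------------------------------------
# Frequency-domain attention (functional form)


def _symmetrize(weights: np.ndarray) -> np.ndarray:
    mirror = np.roll(weights[..., ::-1, ::-1], shift=(1, 1), axis=(-2, -1))
    return 0.5 * (weights + mirror)


def frequency_attention(features: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Residual spectral gating: Re(ifft2(sym(W) . fft2(x))) + x.

    ``weights`` is one real map per channel, shaped like the feature map's
    2-D spectrum; symmetrising it across mirrored frequency pairs makes the
    spectral symbol conjugate-symmetric, so the output is exactly real.
    All-ones weights give y = 2x (round-trip identity plus residual);
    all-zero weights give y = x (pure residual).
    """
    features = np.asarray(features, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != features.shape[-3:]:
        raise ValidationError(
            f"spectral weights {weights.shape} must match per-channel feature "
            f"shape {features.shape[-3:]}"
        )
    sym = _symmetrize(weights)
    return np.real(np.fft.ifft2(sym * np.fft.fft2(features))) + features


# ---------------------------------------------------------------------------
# The saliency network


@dataclass
class FeaturePyramid:
    """Four feature maps at strides 4/8/16/32."""

    layers: tuple  # of nn.Tensor, shallow to deep

    def __post_init__(self) -> None:
        if len(self.layers) != 4:
            raise ValidationError("a feature pyramid has exactly four layers")
        for a, b in zip(self.layers, self.layers[1:]):
            ha, wa = a.data.shape[-2:]
            hb, wb = b.data.shape[-2:]
            if (ha, wa) != (2 * hb, 2 * wb):
                raise ValidationError("pyramid spatial sizes must halve per layer")


class HeatmapNet(nn.Module):
    """Pyramid encoder + content/edge detection + gated progressive fusion."""

    CHANNELS = (8, 16, 24, 32)

    def __init__(self, input_size: int = 128, rng: np.random.Generator | None = None):
        if input_size % 32:
            raise ValidationError("heatmap input size must be divisible by 32")
        rng = rng or np.random.default_rng(0)
        c1, c2, c3, c4 = self.CHANNELS
        self.input_size = input_size
        self.stem_a = nn.Conv2d(3, c1, stride=2, rng=rng)
        self.stem_b = nn.Conv2d(c1, c1, stride=2, rng=rng)
        self.down2 = nn.Conv2d(c1, c2, stride=2, rng=rng)
        self.down3 = nn.Conv2d(c2, c3, stride=2, rng=rng)
        self.down4 = nn.Conv2d(c3, c4, stride=2, rng=rng)
        self.gate1 = nn.SpectralGate(c1, input_size // 4, input_size // 4)
        self.gate2 = nn.SpectralGate(c2, input_size // 8, input_size // 8)
        # content detection: layers 2-4 fused at stride 8
        self.content_fuse = nn.Conv2d(c2 + c3 + c4, 16, rng=rng)
        self.content_head = nn.Conv2d(16, 1, k=1, rng=rng)
        # edge detection from layer 1 (stride 4)
        self.edge_fuse = nn.Conv2d(c1, c1, rng=rng)
        self.edge_head = nn.Conv2d(c1, 1, k=1, rng=rng)
        # progressive top-down refinement
        self.ref4 = nn.Conv2d(c4, c3, rng=rng)
        self.ref3 = nn.Conv2d(c3, c2, rng=rng)
        self.ref2 = nn.Conv2d(c2, c1, rng=rng)
        self.ref1 = nn.Conv2d(c1, c1, rng=rng)
        self.ref0 = nn.Conv2d(c1, c1, rng=rng)
        self.final_head = nn.Conv2d(c1, 1, k=1, rng=rng)

    def _spectral(self, gate: nn.SpectralGate, x: nn.Tensor) -> nn.Tensor:
        if gate.weight.data.shape[-2:] == x.data.shape[-2:]:
            return gate(x)
        # inference at an off-design size: resample the learned spectrum
        resized = _sktransform.resize(
            gate.weight.data.astype(np.float64),
            (gate.weight.data.shape[0], *x.data.shape[-2:]),
            order=1, preserve_range=True, anti_aliasing=False,
        ).astype(np.float32)
        return nn.spectral_gate(x, nn.Tensor(resized))

    def extract_pyramid(self, x: nn.Tensor) -> FeaturePyramid:
        l1 = nn.relu(self.stem_b(nn.relu(self.stem_a(x))))
        l1 = self._spectral(self.gate1, l1)
        l2 = nn.relu(self.down2(l1))
        l2 = self._spectral(self.gate2, l2)
        l3 = nn.relu(self.down3(l2))
        l4 = nn.relu(self.down4(l3))
        return FeaturePyramid((l1, l2, l3, l4))

    def detect_content(self, pyramid: FeaturePyramid) -> nn.Tensor:
        """Coarse single-channel content logits at stride 8 from layers 2-4."""
        _, l2, l3, l4 = pyramid.layers
        fused = nn.concat([l2, nn.upsample_nearest(l3, 2), nn.upsample_nearest(l4, 4)])
        return self.content_head(nn.relu(self.content_fuse(fused)))

    def detect_edge(self, pyramid: FeaturePyramid) -> nn.Tensor:
        """Single-channel edge-belt logits at stride 4 from layer 1."""
        l1 = pyramid.layers[0]
        return self.edge_head(nn.relu(self.edge_fuse(l1)))

    def refine_and_fuse(
        self, pyramid: FeaturePyramid, content: nn.Tensor, edge: nn.Tensor
    ) -> nn.Tensor:
        """Content-gated, edge-guided progressive fusion to full-res logits."""
        _, l2, l3, l4 = pyramid.layers
        g8 = nn.sigmoid(content)
        g16 = nn.avg_pool2d(g8, 2)
        g32 = nn.avg_pool2d(g16, 2)
        r2 = nn.mul(l2, g8)
        r3 = nn.mul(l3, g16)
        r4 = nn.mul(l4, g32)
        h = nn.upsample_nearest(nn.relu(self.ref4(r4)), 2)
        h = nn.upsample_nearest(nn.relu(self.ref3(h + r3)), 2)
        h = nn.upsample_nearest(nn.relu(self.ref2(h + r2)), 2)  # stride 4
        h = nn.mul(h, nn.sigmoid(edge))
        # learned upsampling to full resolution sharpens the blob boundary
        h = nn.relu(self.ref1(nn.upsample_nearest(h, 2)))  # stride 2
        h = nn.relu(self.ref0(nn.upsample_nearest(h, 2)))  # stride 1
        return self.final_head(h)

    def forward(self, x: nn.Tensor):
        pyr = self.extract_pyramid(x)
        content = self.detect_content(pyr)
        edge = self.detect_edge(pyr)
        final = self.refine_and_fuse(pyr, content, edge)
        return final, content, edge


# ---------------------------------------------------------------------------
# Model wrapper, training, prediction


def _coord_channels(h: int, w: int) -> np.ndarray:
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float32)
    return np.stack([xs / max(w - 1, 1), ys / max(h - 1, 1)])


class HeatmapModel:
    def __init__(self, net: HeatmapNet, input_size: int):
        self.net = net
        self.input_size = input_size

    def _prepare(self, frame: np.ndarray) -> np.ndarray:
        s = self.input_size
        img = _sktransform.resize(
            np.asarray(frame, dtype=np.float32) / 255.0, (s, s),
            order=1, preserve_range=True, anti_aliasing=False,
        ).astype(np.float32)
        return np.concatenate([img[None], _coord_channels(s, s)])

    def predict(self, frame: np.ndarray) -> np.ndarray:
        """Saliency heatmap in [0, 1] at the frame's own resolution."""
        frame = np.asarray(frame)
        logits, _, _ = self.net(nn.Tensor(self._prepare(frame)[None]))
        heat = 1.0 / (1.0 + np.exp(-np.clip(logits.data[0, 0], -60, 60)))
        if heat.shape != frame.shape:
            heat = _sktransform.resize(
                heat, frame.shape, order=1, preserve_range=True, anti_aliasing=False
            )
        return np.clip(heat, 0.0, 1.0)

    def save(self, path) -> None:
        state = self.net.state_dict()
        meta = {"kind": "heatmap", "input_size": self.input_size}
        np.savez(Path(path), __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path) -> "HeatmapModel":
        with np.load(path, allow_pickle=False) as zf:
            meta = json.loads(str(zf["__meta__"]))
            state = {k: zf[k] for k in zf.files if k != "__meta__"}
        net = HeatmapNet(input_size=meta["input_size"])
        net.load_state_dict(state)
        return cls(net, meta["input_size"])


def predict_heatmap(model: HeatmapModel, frame: np.ndarray) -> np.ndarray:
    return model.predict(frame)


@dataclass
class HeatmapTrainConfig:
    epochs: int = 15
    max_steps: int | None = None  # overrides epochs when set
    lr: float = 3e-3
    batch_size: int = 8
    input_size: int = 128
    belt_width: int = DEFAULT_BELT_WIDTH
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 2.0)  # content, edge, final
    augment_flip: bool = True
    seed: int = 0


def _content_target(mask: np.ndarray, stride: int) -> np.ndarray:
    """Area-averaged then 0.5-thresholded down-sampling of the mask."""
    down = _sktransform.downscale_local_mean(mask.astype(np.float64), (stride, stride))
    return (down >= 0.5).astype(np.float64)


def train_heatmap(
    frames, masks, config: HeatmapTrainConfig | None = None
) -> tuple[HeatmapModel, list[float]]:
    """Train the saliency model on prolapse frames with binary MVP masks.

    Joint loss = w_c * BCE(content, down-sampled mask)
               + w_e * BCE(edge, edge-belt target)
               + w_f * (BCE + soft-IoU)(final map, mask).
    Every training frame must contain prolapse pixels, mirroring a protocol
    in which only frames with clearly annotated prolapse are supervised.
    """
    cfg = config or HeatmapTrainConfig()
    frames = list(frames)
    masks = [np.asarray(m).astype(bool) for m in masks]
    if not frames or len(frames) != len(masks):
        raise DataError("heatmap training needs aligned, nonempty (frame, mask) pairs")
    if any(not m.any() for m in masks):
        raise DataError("every heatmap training frame must contain prolapse pixels")

    rng = np.random.default_rng(cfg.seed)
    net = HeatmapNet(input_size=cfg.input_size, rng=rng)
    model = HeatmapModel(net, cfg.input_size)
    s = cfg.input_size

    x = np.stack([model._prepare(f) for f in frames])
    y = np.stack([
        _sktransform.resize(m.astype(np.float64), (s, s), order=0,
                            preserve_range=True, anti_aliasing=False) >= 0.5
        for m in masks
    ]).astype(np.float64)
    y_content = np.stack([_content_target(m, 8) for m in y])[:, None]
    y_edge = np.stack([
        make_edge_belt(m, cfg.belt_width).mask[::4, ::4] for m in y  # nearest to stride 4
    ]).astype(np.float64)[:, None]
    y = y[:, None]

    opt = nn.Adam(net.parameters(), lr=cfg.lr)
    w_c, w_e, w_f = cfg.loss_weights
    n = len(x)
    losses: list[float] = []
    step = 0
    max_steps = cfg.max_steps if cfg.max_steps is not None else cfg.epochs * max(1, -(-n // cfg.batch_size))
    while step < max_steps:
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            if step >= max_steps:
                break
            idx = order[start : start + cfg.batch_size]
            xb, yb, ycb, yeb = x[idx], y[idx], y_content[idx], y_edge[idx]
            if cfg.augment_flip:
                flip = rng.random(len(idx)) < 0.5
                xb, yb, ycb, yeb = (a.copy() for a in (xb, yb, ycb, yeb))
                xb[flip] = xb[flip, :, :, ::-1]
                xb[flip, 1] = 1.0 - xb[flip, 1]
                yb[flip] = yb[flip, :, :, ::-1]
                ycb[flip] = ycb[flip, :, :, ::-1]
                yeb[flip] = yeb[flip, :, :, ::-1]
            opt.zero_grad()
            final, content, edge = net(nn.Tensor(xb))
            loss = (
                nn.bce_with_logits(content, ycb) * w_c
                + nn.bce_with_logits(edge, yeb) * w_e
                + (nn.bce_with_logits(final, yb) + nn.soft_iou_loss(final, yb)) * w_f
            )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
        logger.info("heatmap step %d/%d loss %.4f", step, max_steps, losses[-1])
    return model, losses


def write_heatmap_png(
    heat: np.ndarray, path, frame: np.ndarray | None = None, cmap: str = "jet"
) -> None:
    """Write an 8-bit grayscale saliency PNG; with a frame, also an RGB overlay."""
    path = Path(path)
    gray = np.round(np.clip(heat, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(gray, mode="L").save(path)
    if frame is not None:
        colors = colormaps[cmap](np.clip(heat, 0, 1))[..., :3]
        base = np.repeat(np.asarray(frame, dtype=np.float64)[..., None] / 255.0, 3, axis=2)
        alpha = np.clip(heat, 0, 1)[..., None] * 0.6
        overlay = (1 - alpha) * base + alpha * colors
        Image.fromarray(np.round(overlay * 255).astype(np.uint8), mode="RGB").save(
            path.with_name(path.stem + "_overlay.png")
        )
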