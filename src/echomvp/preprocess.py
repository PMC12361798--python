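"""Imaging-zone ROI extraction and training-time augmentation.

The imaging zone of a rendered 3-D echo view is a bright sector on a black
background; it is located by threshold segmentation (Otsu by default)
followed by largest-connected-component bounding.  Training augmentation
follows the standard recipe for this task: random crop (400x400 -> 224x224
at native scale), horizontal flip with probability 0.5, rotation within
+/-10 degrees and photometric jitter (brightness/hue/contrast factors in
0.5-1.5).  Hue is a no-op on grayscale input.  Masks, when given, receive
the identical geometric transform with nearest-neighbour interpolation so
no new label ever appears.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, transform

from .data import ValidationError

__all__ = ["RoiBox", "AugmentConfig", "EmptyRoiError", "extract_roi", "crop_to_roi", "augment"]


class EmptyRoiError(ValueError):
    """No pixel above the ROI threshold; callers may fall back to the full frame."""


@dataclass(frozen=True)
class RoiBox:
    """Half-open pixel box [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValidationError("ROI box must have positive extent")
        if self.x0 < 0 or self.y0 < 0:
            raise ValidationError("ROI box must lie within the frame")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass(frozen=True)
class AugmentConfig:
    crop_from: tuple[int, int] = (400, 400)
    crop_to: tuple[int, int] = (224, 224)
    hflip_prob: float = 0.5
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    photometric_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.crop_to[0] <= self.crop_from[0] and self.crop_to[1] <= self.crop_from[1]):
            raise ValidationError("crop_to must not exceed crop_from")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValidationError("hflip_prob must lie in [0, 1]")


def extract_roi(frame: np.ndarray, intensity_threshold: float | None = None) -> RoiBox:
    """Bounding box of the largest connected component above a threshold.

    ``intensity_threshold`` defaults to Otsu's value on the frame histogram.
    Deterministic; raises :class:`EmptyRoiError` when nothing exceeds the
    threshold (e.g. an all-black frame).
    """
    frame = np.asarray(frame)
    if frame.size == 0 or frame.ndim != 2:
        raise ValidationError("frame must be a nonempty 2-D image")
    if intensity_threshold is None:
        if np.ptp(frame) == 0:
            # Otsu needs >1 gray level: a constant bright frame is all
            # imaging zone, a constant black frame has none
            if float(frame.flat[0]) <= 0:
                raise EmptyRoiError("frame is uniformly black")
            intensity_threshold = float(frame.flat[0]) - 1.0
        else:
            intensity_threshold = float(filters.threshold_otsu(frame))
    fore = frame > intensity_threshold
    if not fore.any():
        raise EmptyRoiError(f"no pixel above threshold {intensity_threshold}")
    labels = measure.label(fore, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    ys, xs = np.nonzero(labels == largest)
    return RoiBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def crop_to_roi(frame: np.ndarray, box: RoiBox) -> np.ndarray:
    return np.asarray(frame)[box.y0 : box.y1, box.x0 : box.x1]


def _resize(img: np.ndarray, shape: tuple[int, int], *, nearest: bool) -> np.ndarray:
    return transform.resize(
        img.astype(np.float64),
        shape,
        order=0 if nearest else 1,
        preserve_range=True,
        anti_aliasing=False,
    )


def augment(
    frame: np.ndarray,
    mask: np.ndarray | None,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply one random crop/flip/rotate/photometric draw to a frame.

    The same geometric transform is applied to ``mask`` (nearest-neighbour);
    photometric jitter touches the image only.  Frames smaller than
    ``crop_from`` are first resized up (bilinear).  Reproducible: with no
    explicit ``rng`` a generator seeded from ``cfg.seed`` is used.

    Returns float32 image in [0, 255] of spatial size ``crop_to`` and the
    transformed mask (or None).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    img = np.asarray(frame, dtype=np.float64)
    msk = None if mask is None else np.asarray(mask)

    cf_w, cf_h = cfg.crop_from
    h, w = img.shape
    if h < cf_h or w < cf_w:
        new_shape = (max(h, cf_h), max(w, cf_w))
        img = _resize(img, new_shape, nearest=False)
        if msk is not None:
            msk = _resize(msk, new_shape, nearest=True).astype(msk.dtype)
        h, w = img.shape

    ct_w, ct_h = cfg.crop_to
    oy = int(rng.integers(0, h - ct_h + 1))
    ox = int(rng.integers(0, w - ct_w + 1))
    img = img[oy : oy + ct_h, ox : ox + ct_w]
    if msk is not None:
        msk = msk[oy : oy + ct_h, ox : ox + ct_w]

    if rng.random() < cfg.hflip_prob:
        img = img[:, ::-1]
        if msk is not None:
            msk = msk[:, ::-1]

    lo, hi = cfg.rotation_range_deg
    angle = float(rng.uniform(lo, hi))
    if angle != 0.0:
        img = transform.rotate(img, angle, order=1, preserve_range=True, mode="constant")
        if msk is not None:
            msk = transform.rotate(
                msk.astype(np.float64), angle, order=0, preserve_range=True, mode="constant"
            ).astype(msk.dtype)

    plo, phi = cfg.photometric_range
    brightness = float(rng.uniform(plo, phi))
    contrast = float(rng.uniform(plo, phi))
    _hue = float(rng.uniform(plo, phi))  # drawn for parity; no-op on grayscale
    img = img * brightness
    img = (img - img.mean()) * contrast + img.mean()
    img = np.clip(img, 0, 255)

    return img.astype(np.float32), (None if msk is None else np.ascontiguousarray(msk))
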