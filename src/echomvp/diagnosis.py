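"""Segmentation-based MVP diagnosis and severe-zone localization.

Systolic frames are segmented into four classes (background, anterior
leaflet AL, posterior leaflet PL, prolapse MVP) by a small FCN-8-style
network: a convolutional encoder with score maps fused across three strides
through upsampling and skip connections.  Diagnosis is rule-based on the
predicted masks:

* frame rule — a systolic frame "has MVP" when its mask contains at least
  ``min_area`` prolapse pixels (default 1: any MVP area counts);
* patient rule — a study is called MVP when strictly more than half of its
  systolic frames have MVP (proportion 0.5 exactly is negative);
* severe zone — on the frame with the largest predicted MVP area, connected
  components are parsed per class (parsing-region step) and the position of
  the largest prolapse component relative to the two leaflets (logical
  judgement step) yields the affected leaflet (SSZ_APL), per-leaflet
  involvement (DSZ_APL) and the clinical sub-zone A1–A3/P1–P3 (SSZ_SSZ),
  by dilated-overlap and centroid-thirds geometry along the annulus axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage import transform as _sktransform
from sklearn import metrics as _skm

from . import nn
from .data import AL, MVP, PL, DataError, ValidationError, validate_seg_mask

logger = logging.getLogger(__name__)

__all__ = [
    "FrameDiagnosis", "PatientDiagnosis", "SevereZoneCall", "Region", "AnnulusAxis",
    "SegTrainConfig", "SegModel", "train_segmenter", "segment_frame",
    "diagnose_frame", "diagnose_patient", "parse_regions", "judge_severe_zone",
    "roc_over_proportion", "RocResult",
]


# ---------------------------------------------------------------------------
# Diagnosis record types


@dataclass
class FrameDiagnosis:
    frame_index: int
    has_mvp: bool
    mvp_area: int


@dataclass
class PatientDiagnosis:
    n_systolic_frames: int
    n_mvp_frames: int
    proportion: float
    is_mvp: bool
    index_frame: int | None  # frame with the largest MVP area, if any

    def as_dict(self) -> dict:
        return {
            "n_systolic_frames": self.n_systolic_frames,
            "n_mvp_frames": self.n_mvp_frames,
            "proportion": self.proportion,
            "is_mvp": self.is_mvp,
            "index_frame": self.index_frame,
        }


@dataclass
class SevereZoneCall:
    ssz_apl: str  # "AL" or "PL"
    dsz_apl: tuple[bool, bool]  # (MVP touches AL, MVP touches PL)
    ssz_ssz: str  # one of A1..A3 / P1..P3

    def __post_init__(self) -> None:
        if self.ssz_apl not in ("AL", "PL"):
            raise ValidationError("ssz_apl must be AL or PL")
        if self.ssz_ssz[0] != self.ssz_apl[0]:
            raise ValidationError("sub-zone leaflet letter must match ssz_apl")

    def as_dict(self) -> dict:
        return {"ssz_apl": self.ssz_apl, "dsz_apl": list(self.dsz_apl), "ssz_ssz": self.ssz_ssz}


# ---------------------------------------------------------------------------
# Frame- and patient-level rules


def diagnose_frame(mask: np.ndarray, frame_index: int = 0, min_area: int = 1) -> FrameDiagnosis:
    """Frame rule: MVP present iff the mask holds >= min_area prolapse pixels."""
    mask = validate_seg_mask(mask)
    area = int((mask == MVP).sum())
    return FrameDiagnosis(frame_index=frame_index, has_mvp=area >= min_area, mvp_area=area)


def diagnose_patient(frame_diagnoses, threshold: float = 0.5) -> PatientDiagnosis:
    """Patient rule over systolic frames: MVP iff proportion > threshold (strict)."""
    diags = list(frame_diagnoses)
    if not diags:
        raise DataError("no systolic frames: patient diagnosis undefined")
    n = len(diags)
    n_mvp = sum(d.has_mvp for d in diags)
    proportion = n_mvp / n
    areas = np.array([d.mvp_area for d in diags])
    index_frame = None
    if areas.max(initial=0) > 0:
        index_frame = diags[int(np.argmax(areas))].frame_index  # argmax: lowest index on ties
    return PatientDiagnosis(
        n_systolic_frames=n,
        n_mvp_frames=n_mvp,
        proportion=proportion,
        is_mvp=proportion > threshold,
        index_frame=index_frame,
    )


# ---------------------------------------------------------------------------
# Region parsing and severe-zone judgement


@dataclass
class Region:
    """One connected component of one mask class."""

    class_id: int
    area: int
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    mask: np.ndarray  # full-size boolean support


def parse_regions(mask: np.ndarray, min_component_area: int = 1) -> list[Region]:
    """8-connected components per foreground class, small ones discarded."""
    mask = validate_seg_mask(mask)
    regions: list[Region] = []
    for class_id in (AL, PL, MVP):
        labelled = measure.label(mask == class_id, connectivity=2)
        for prop in measure.regionprops(labelled):
            if prop.area < min_component_area:
                continue
            y0, x0, y1, x1 = prop.bbox
            regions.append(
                Region(
                    class_id=class_id,
                    area=int(prop.area),
                    centroid=(float(prop.centroid[1]), float(prop.centroid[0])),
                    bbox=(int(x0), int(y0), int(x1), int(y1)),
                    mask=labelled == prop.label,
                )
            )
    return regions


@dataclass(frozen=True)
class AnnulusAxis:
    """The lateral-medial axis along which leaflets are split into thirds."""

    origin: tuple[float, float]  # (x, y)
    direction: tuple[float, float]  # unit vector, x-component >= 0


def estimate_annulus_axis(regions) -> AnnulusAxis:
    """Principal axis of the combined leaflet support (AL union PL)."""
    leaflet = [r for r in regions if r.class_id in (AL, PL)]
    if not leaflet:
        raise DataError("no leaflet pixels: cannot estimate the annulus axis")
    union = np.zeros_like(leaflet[0].mask, dtype=bool)
    for r in leaflet:
        union |= r.mask
    ys, xs = np.nonzero(union)
    pts = np.stack([xs, ys], axis=1).astype(float)
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    eigval, eigvec = np.linalg.eigh(cov)
    direction = eigvec[:, int(np.argmax(eigval))]
    if direction[0] < 0:
        direction = -direction
    return AnnulusAxis(origin=(float(center[0]), float(center[1])),
                       direction=(float(direction[0]), float(direction[1])))


def _project(points_xy: np.ndarray, axis: AnnulusAxis) -> np.ndarray:
    d = np.asarray(axis.direction)
    o = np.asarray(axis.origin)
    return (points_xy - o) @ d


def judge_severe_zone(
    regions, annulus_axis: AnnulusAxis | None = None, dilation_px: int = 3
) -> SevereZoneCall:
    """Locate the severe prolapse zone from parsed regions.

    The largest MVP component is attributed to the leaflet whose
    ``dilation_px``-dilated support overlaps it most (tie -> AL, anterior
    first).  Its centroid, projected on the annulus axis and binned into
    thirds of the chosen leaflet's extent, gives the clinical sub-zone.
    DSZ_APL reports, per leaflet, whether any MVP component touches its
    dilated support.
    """
    regions = list(regions)
    mvp_regions = [r for r in regions if r.class_id == MVP]
    if not mvp_regions:
        raise ValidationError("severe-zone judgement requires at least one MVP component")
    if annulus_axis is None:
        annulus_axis = estimate_annulus_axis(regions)

    struct = np.ones((3, 3), dtype=bool)  # Chebyshev ball
    support = {}
    for leaflet in (AL, PL):
        parts = [r.mask for r in regions if r.class_id == leaflet]
        union = np.logical_or.reduce(parts) if parts else None
        if union is not None and dilation_px > 0:
            union = ndimage.binary_dilation(union, struct, iterations=dilation_px)
        support[leaflet] = union

    mvp_any = np.logical_or.reduce([r.mask for r in mvp_regions])
    in_al = bool(support[AL] is not None and (support[AL] & mvp_any).any())
    in_pl = bool(support[PL] is not None and (support[PL] & mvp_any).any())

    largest = max(mvp_regions, key=lambda r: r.area)
    ov_al = int((support[AL] & largest.mask).sum()) if support[AL] is not None else 0
    ov_pl = int((support[PL] & largest.mask).sum()) if support[PL] is not None else 0
    chosen = AL if ov_al >= ov_pl else PL  # tie -> anterior
    letter = "A" if chosen == AL else "P"

    own = [r.mask for r in regions if r.class_id == chosen]
    if not own:
        raise DataError("chosen leaflet has no support; cannot bin into thirds")
    ys, xs = np.nonzero(np.logical_or.reduce(own))
    t_leaf = _project(np.stack([xs, ys], axis=1).astype(float), annulus_axis)
    t_min, t_max = float(t_leaf.min()), float(t_leaf.max())
    t_c = float(_project(np.asarray(largest.centroid)[None], annulus_axis)[0])
    if t_max <= t_min:
        third = 0
    else:
        third = int(np.clip(np.floor(3.0 * (t_c - t_min) / (t_max - t_min)), 0, 2))
    return SevereZoneCall(
        ssz_apl="AL" if chosen == AL else "PL",
        dsz_apl=(in_al, in_pl),
        ssz_ssz=f"{letter}{third + 1}",
    )


# ---------------------------------------------------------------------------
# ROC over the proportion of systolic frames with MVP


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_over_proportion(patient_records) -> RocResult:
    """ROC/AUC of the patient score = proportion of systolic frames with MVP."""
    records = list(patient_records)
    scores = np.array([float(p) for p, _ in records])
    truth = np.array([bool(t) for _, t in records])
    if truth.all() or not truth.any():
        raise DataError("ROC requires both MVP and control patients")
    fpr, tpr, thresholds = _skm.roc_curve(truth, scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(_skm.auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# FCN-8-style segmenter


def _coord_channels(size: int) -> np.ndarray:
    """Normalised x/y coordinate maps appended to the intensity channel.

    The leaflet-versus-prolapse distinction is positional (which side of the
    annulus tissue lies on), so the dense predictor receives explicit
    normalised coordinates alongside intensity.
    """
    ys, xs = np.mgrid[0:size, 0:size].astype(np.float32)
    return np.stack([xs / (size - 1), ys / (size - 1)])


class FCN8Net(nn.Module):
    """Tiny FCN-8-style dense predictor: 3-stride encoder + skip-fused scores."""

    def __init__(self, n_classes: int = 4, width: int = 12,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = width
        self.enc1 = nn.Conv2d(3, w, rng=rng)
        self.enc2 = nn.Conv2d(w, 2 * w, rng=rng)
        self.enc3a = nn.Conv2d(2 * w, 3 * w, rng=rng)
        self.enc3b = nn.Conv2d(3 * w, 3 * w, rng=rng)
        self.score8 = nn.Conv2d(3 * w, n_classes, k=1, rng=rng)
        self.score4 = nn.Conv2d(2 * w, n_classes, k=1, rng=rng)
        self.score2 = nn.Conv2d(w, n_classes, k=1, rng=rng)
        self.score1 = nn.Conv2d(w, n_classes, k=1, rng=rng)

    def encoder_modules(self):
        return [self.enc1, self.enc2, self.enc3a, self.enc3b]

    def decoder_modules(self):
        return [self.score8, self.score4, self.score2, self.score1]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        f0 = nn.relu(self.enc1(x))  # stride 1
        f1 = nn.avg_pool2d(f0, 2)  # stride 2
        f2 = nn.avg_pool2d(nn.relu(self.enc2(f1)), 2)  # stride 4
        f3 = nn.relu(self.enc3a(f2))
        f3 = nn.avg_pool2d(nn.relu(self.enc3b(f3)), 2)  # stride 8
        s = nn.upsample_nearest(self.score8(f3), 2)
        s = s + self.score4(f2)
        s = nn.upsample_nearest(s, 2)
        s = s + self.score2(f1)
        s = nn.upsample_nearest(s, 2)
        # finest skip keeps thin leaflet boundaries pixel-accurate
        return s + self.score1(f0)


@dataclass
class SegTrainConfig:
    epochs: int = 10
    lr: float = 2e-3
    lr_ratio_k: float = 1.0  # decoder lr = k * encoder lr
    class_weights: tuple[float, float, float, float] = (0.5, 1.0, 1.0, 3.0)
    batch_size: int = 8
    input_size: int = 96
    width: int = 12
    augment_flip: bool = True
    seed: int = 0


class SegModel:
    """A trained 4-class dense predictor with resize-in/resize-out contract."""

    def __init__(self, net: FCN8Net, input_size: int):
        self.net = net
        self.input_size = input_size
        self._coords = _coord_channels(input_size)

    def _prepare(self, frame: np.ndarray) -> np.ndarray:
        img = _sktransform.resize(
            np.asarray(frame, dtype=np.float32) / 255.0,
            (self.input_size, self.input_size),
            order=1, preserve_range=True, anti_aliasing=False,
        ).astype(np.float32)
        return np.concatenate([img[None], self._coords])

    def logits(self, frames: np.ndarray) -> np.ndarray:
        x = np.stack([self._prepare(f) for f in frames])
        return self.net(nn.Tensor(x)).data

    def segment(self, frame: np.ndarray) -> np.ndarray:
        """Argmax label map resized back to the frame's own resolution."""
        frame = np.asarray(frame)
        if frame.ndim != 2:
            raise ValidationError("segmenter expects a single 2-D frame")
        labels = np.argmax(self.logits(frame[None])[0], axis=0).astype(np.int8)
        if labels.shape != frame.shape:
            labels = _sktransform.resize(
                labels, frame.shape, order=0, preserve_range=True, anti_aliasing=False
            ).astype(np.int8)
        return labels

    def save(self, path) -> None:
        state = self.net.state_dict()
        meta = {"kind": "segmenter", "input_size": self.input_size,
                "width": self.net.enc1.weight.data.shape[0]}
        np.savez(Path(path), __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path) -> "SegModel":
        with np.load(path, allow_pickle=False) as zf:
            meta = json.loads(str(zf["__meta__"]))
            state = {k: zf[k] for k in zf.files if k != "__meta__"}
        net = FCN8Net(width=meta["width"])
        net.load_state_dict(state)
        return cls(net, meta["input_size"])


def segment_frame(model: SegModel, frame: np.ndarray) -> np.ndarray:
    return model.segment(frame)


def train_segmenter(
    frames, masks, config: SegTrainConfig | None = None
) -> tuple[SegModel, list[float]]:
    """Train the dense predictor on (frame, mask) pairs; returns (model, losses).

    The optimiser runs two parameter groups — encoder at the base learning
    rate, score/decoder layers at ``lr_ratio_k`` times it — and a per-class
    weighted cross-entropy, the two tuning knobs the segmenter exposes.
    """
    cfg = config or SegTrainConfig()
    frames = list(frames)
    masks = list(masks)
    if not frames or len(frames) != len(masks):
        raise DataError("segmenter needs a nonempty, aligned (frame, mask) dataset")
    all_classes = np.unique(np.concatenate([np.unique(m) for m in masks]))
    if len(all_classes) < 2:
        raise DataError("segmentation masks must contain at least two classes")

    rng = np.random.default_rng(cfg.seed)
    net = FCN8Net(width=cfg.width, rng=rng)
    model = SegModel(net, cfg.input_size)

    x = np.stack([model._prepare(f) for f in frames])
    s = cfg.input_size
    y = np.stack([
        _sktransform.resize(
            np.asarray(m), (s, s), order=0, preserve_range=True, anti_aliasing=False
        ).astype(np.int64)
        for m in masks
    ])

    enc_params = [p for m in net.encoder_modules() for p in m.parameters()]
    dec_params = [p for m in net.decoder_modules() for p in m.parameters()]
    opt = nn.Adam([
        {"params": enc_params, "lr": cfg.lr},
        {"params": dec_params, "lr": cfg.lr * cfg.lr_ratio_k},
    ])

    n = len(x)
    weights = np.asarray(cfg.class_weights, dtype=np.float64)
    losses: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total, batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            if cfg.augment_flip:
                flip = rng.random(len(idx)) < 0.5
                xb, yb = xb.copy(), yb.copy()
                xb[flip] = xb[flip, :, :, ::-1]
                xb[flip, 1] = 1.0 - xb[flip, 1]  # keep the x-coordinate channel consistent
                yb[flip] = yb[flip, :, ::-1]
            opt.zero_grad()
            logits = net(nn.Tensor(xb))
            loss = nn.softmax_cross_entropy(logits, yb, class_weights=weights)
            loss.backward()
            opt.step()
            total += float(loss.data)
            batches += 1
        losses.append(total / batches)
        logger.info("segmenter epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, losses[-1])
    return model, losses
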