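"""Systolic-phase recognition with a confidence-gated two-network ensemble.

Two binary frame classifiers are trained independently: a main network A
(dense-concat CNN) and a secondary network B (conv + MLP head).  For each
frame, the positive-class probability of network N is the two-way softmax

    P(N,1) = exp(O(N,1)) / (exp(O(N,0)) + exp(O(N,1)))

and its confidence level is

    Conf_N = 2 * |P(N,1) - 0.5|,

i.e. 0 at a coin-flip prediction and 1 at certainty.  The active-if rule
prefers network A and activates B only when A is unsure and B is surer:
B is chosen iff Conf_A < C and Conf_B > Conf_A, with C = 0.4 by default.

Predicted per-frame labels are parsed into cardiac cycles: each maximal run
of systolic frames is one systole period; within a run, the first frame is
taken as end-diastole (ED) and the last as end-systole (ES).  The ED/ES
convention cancels in evaluation because prediction and ground truth are
parsed identically.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import transform as _sktransform

from . import nn
from .data import DataError, DIASTOLE, PhaseAnnotation, SYSTOLE, ValidationError
from .preprocess import EmptyRoiError, crop_to_roi, extract_roi

logger = logging.getLogger(__name__)

DEFAULT_C_THRESHOLD = 0.4


# ---------------------------------------------------------------------------
# Active-if arithmetic


@dataclass(frozen=True)
class LogitRecord:
    """Raw two-class scores of one network for one frame."""

    o_neg: float
    o_pos: float
    network_id: str = "A"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.o_neg) and np.isfinite(self.o_pos)):
            raise ValidationError("logits must be finite")


@dataclass(frozen=True)
class ConfidenceDecision:
    """Audit record of one active-if selection."""

    p_pos_a: float
    p_pos_b: float
    conf_a: float
    conf_b: float
    c_threshold: float
    chosen: str  # "A" or "B"

    @property
    def p_pos(self) -> float:
        return self.p_pos_a if self.chosen == "A" else self.p_pos_b


def positive_probability(rec, o_pos: float | None = None) -> float:
    """Two-term softmax probability of the positive (systolic) class.

    Accepts a :class:`LogitRecord` or a raw ``(o_neg, o_pos)`` pair.
    Computed with the max logit subtracted, so extreme scores cannot
    overflow.
    """
    if o_pos is None:
        o_neg, o_pos = rec.o_neg, rec.o_pos
    else:
        o_neg = rec
    if not (np.isfinite(o_neg) and np.isfinite(o_pos)):
        raise ValidationError("logits must be finite")
    m = max(o_neg, o_pos)
    e_neg, e_pos = np.exp(o_neg - m), np.exp(o_pos - m)
    return float(e_pos / (e_neg + e_pos))


def confidence(p_pos: float) -> float:
    """Confidence level: twice the distance of P(N,1) from the coin flip."""
    if not 0.0 <= p_pos <= 1.0:
        raise ValidationError(f"probability out of [0, 1]: {p_pos}")
    return 2.0 * abs(p_pos - 0.5)


def active_if_select(conf_a: float, conf_b: float, c_threshold: float = DEFAULT_C_THRESHOLD) -> str:
    """Return "B" iff Conf_A < C and Conf_B > Conf_A (strict); else "A"."""
    if conf_a < c_threshold and conf_b > conf_a:
        return "B"
    return "A"


def predict_phase(frame, model_a, model_b, c_threshold: float = DEFAULT_C_THRESHOLD):
    """Label one frame via the active-if ensemble.

    Models are callables mapping a frame to an ``(o_neg, o_pos)`` pair.
    Returns the phase label string and the full decision record.
    """
    p_a = positive_probability(*_logit_pair(model_a, frame))
    p_b = positive_probability(*_logit_pair(model_b, frame))
    conf_a, conf_b = confidence(p_a), confidence(p_b)
    chosen = active_if_select(conf_a, conf_b, c_threshold)
    decision = ConfidenceDecision(p_a, p_b, conf_a, conf_b, c_threshold, chosen)
    label = SYSTOLE if decision.p_pos >= 0.5 else DIASTOLE
    return label, decision


def _logit_pair(model, frame) -> tuple[float, float]:
    out = model(frame)
    if isinstance(out, LogitRecord):
        return out.o_neg, out.o_pos
    o_neg, o_pos = out
    return float(o_neg), float(o_pos)


def predict_sequence(cine, model_a, model_b, c_threshold: float = DEFAULT_C_THRESHOLD):
    """Label every frame of a cine loop; returns labels + decision records."""
    labels, decisions = [], []
    for t in range(len(cine)):
        label, dec = predict_phase(cine.frames[t], model_a, model_b, c_threshold)
        labels.append(label)
        decisions.append(dec)
    return PhaseAnnotation(np.array(labels)), decisions


def write_decisions_csv(path, labels: PhaseAnnotation, decisions) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["frame_index", "p_pos_A", "p_pos_B", "conf_A", "conf_B", "chosen", "label"]
        )
        for t, (name, d) in enumerate(zip(labels.names, decisions)):
            writer.writerow(
                [t, f"{d.p_pos_a:.6f}", f"{d.p_pos_b:.6f}", f"{d.conf_a:.6f}",
                 f"{d.conf_b:.6f}", d.chosen, name]
            )


# ---------------------------------------------------------------------------
# Cycle parsing


@dataclass
class CyclePrediction:
    """Systole periods with their ED/ES boundary frames."""

    systole_periods: list[tuple[int, int]]  # inclusive (start, end)
    ed_frames: list[int]
    es_frames: list[int]

    def __post_init__(self) -> None:
        n = len(self.systole_periods)
        if len(self.ed_frames) != n or len(self.es_frames) != n:
            raise ValidationError("one ED and one ES frame per systole period")

    @property
    def n_cycles(self) -> int:
        return len(self.systole_periods)


def parse_cycles(labels) -> CyclePrediction:
    """Extract maximal systolic runs; ED = first, ES = last frame of each run."""
    if isinstance(labels, PhaseAnnotation):
        arr = labels.labels
    else:
        arr = PhaseAnnotation(np.asarray(labels)).labels
    if arr.size == 0:
        raise ValidationError("empty label sequence")
    padded = np.concatenate([[0], arr, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    periods = list(zip(starts.tolist(), ends.tolist()))
    return CyclePrediction(periods, [s for s, _ in periods], [e for _, e in periods])


# ---------------------------------------------------------------------------
# Frame classifiers


def _prepare_frame(frame: np.ndarray, size: int) -> np.ndarray:
    """ROI-crop (imaging zone), resize to the model's square input, scale to [0,1]."""
    frame = np.asarray(frame)
    try:
        box = extract_roi(frame)
        frame = crop_to_roi(frame, box)
    except EmptyRoiError:
        pass  # all-black frame: keep full extent
    out = _sktransform.resize(
        frame.astype(np.float32) / 255.0, (size, size), order=1,
        preserve_range=True, anti_aliasing=False,
    )
    return out.astype(np.float32)


class DenseBlockClassifier(nn.Module):
    """Main network A: small CNN with concatenative (dense) feature reuse."""

    def __init__(self, width: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = width
        self.stem = nn.Conv2d(1, w, rng=rng)
        self.d1a = nn.Conv2d(w, w, rng=rng)
        self.d1b = nn.Conv2d(2 * w, w, rng=rng)
        self.trans = nn.Conv2d(3 * w, 2 * w, k=1, rng=rng)
        self.d2a = nn.Conv2d(2 * w, w, rng=rng)
        self.head = nn.Linear(3 * w, 2, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.relu(self.stem(x))
        h = nn.avg_pool2d(h, 2)
        h = nn.concat([h, nn.relu(self.d1a(h))])
        h = nn.concat([h, nn.relu(self.d1b(h))])
        h = nn.avg_pool2d(h, 2)
        h = nn.relu(self.trans(h))
        h = nn.concat([h, nn.relu(self.d2a(h))])
        h = nn.avg_pool2d(h, 2)
        return self.head(nn.global_avg_pool(h))


class ConvMLPClassifier(nn.Module):
    """Secondary network B: strided conv stem + MLP head (distinct bias from A)."""

    def __init__(self, width: int = 6, hidden: int = 32,
                 input_size: int = 64, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stem = nn.Conv2d(1, width, stride=2, rng=rng)
        pooled = input_size // 2 // 4
        self.fc1 = nn.Linear(width * pooled * pooled, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, 2, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.relu(self.stem(x))
        h = nn.avg_pool2d(h, 4)
        n = h.data.shape[0]
        h = nn.reshape(h, (n, -1))
        return self.fc2(nn.relu(self.fc1(h)))


_ARCHS = {"main": DenseBlockClassifier, "secondary": ConvMLPClassifier}


class PhaseModel:
    """A trained frame classifier plus its input-preparation contract."""

    def __init__(self, net: nn.Module, arch: str, input_size: int = 64):
        self.net = net
        self.arch = arch
        self.input_size = input_size

    def logits(self, batch: np.ndarray) -> np.ndarray:
        """Raw two-class scores for a batch of prepared (N, S, S) inputs."""
        x = nn.Tensor(np.asarray(batch, dtype=np.float32)[:, None])
        return self.net(x).data

    def __call__(self, frame: np.ndarray) -> tuple[float, float]:
        if frame.ndim != 2:
            raise ValidationError("phase model expects a single 2-D frame")
        out = self.logits(_prepare_frame(frame, self.input_size)[None])
        return float(out[0, 0]), float(out[0, 1])

    def save(self, path) -> None:
        path = Path(path)
        state = self.net.state_dict()
        meta = {"arch": self.arch, "input_size": self.input_size,
                "kind": "phase", "n_params": len(state)}
        np.savez(path, __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path) -> "PhaseModel":
        with np.load(path, allow_pickle=False) as zf:
            meta = json.loads(str(zf["__meta__"]))
            state = {k: zf[k] for k in zf.files if k != "__meta__"}
        rng = np.random.default_rng(0)
        if meta["arch"] == "secondary":
            net = _ARCHS["secondary"](input_size=meta["input_size"], rng=rng)
        else:
            net = _ARCHS["main"](rng=rng)
        net.load_state_dict(state)
        return cls(net, meta["arch"], meta["input_size"])


@dataclass
class PhaseTrainConfig:
    epochs: int = 5
    lr: float = 3e-3
    batch_size: int = 32
    input_size: int = 64
    augment_flip: bool = True
    seed: int = 0


def _collect_phase_dataset(cases, size: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for case in cases:
        for t in range(case.cine.n_frames):
            xs.append(_prepare_frame(case.cine.frames[t], size))
            ys.append(int(case.phase_labels.labels[t]))
    if not xs:
        raise DataError("empty training dataset")
    return np.stack(xs), np.asarray(ys)


def train_phase_classifier(
    cases, arch: str = "main", config: PhaseTrainConfig | None = None
) -> tuple[PhaseModel, list[float]]:
    """Train one frame classifier on synthetic cases; returns (model, loss log)."""
    cfg = config or PhaseTrainConfig()
    if arch not in _ARCHS:
        raise ValidationError(f"unknown architecture {arch!r}; use 'main' or 'secondary'")
    x, y = _collect_phase_dataset(cases, cfg.input_size)
    if len(np.unique(y)) < 2:
        raise DataError("training data must contain both systolic and diastolic frames")

    rng = np.random.default_rng(cfg.seed)
    if arch == "secondary":
        net = _ARCHS[arch](input_size=cfg.input_size, rng=rng)
    else:
        net = _ARCHS[arch](rng=rng)
    opt = nn.Adam(net.parameters(), lr=cfg.lr)

    n = len(x)
    losses: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x[idx]
            if cfg.augment_flip:
                flip = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                xb[flip] = xb[flip, :, ::-1]
            opt.zero_grad()
            logits = net(nn.Tensor(xb[:, None]))
            loss = nn.softmax_cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / n_batches)
        logger.info("phase[%s] epoch %d/%d loss %.4f", arch, epoch + 1, cfg.epochs, losses[-1])
    return PhaseModel(net, arch, cfg.input_size), losses
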