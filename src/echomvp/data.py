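"""Core in-memory containers shared by all pipeline stages.

A cine loop is an ordered stack of 8-bit grayscale frames covering two to
five cardiac cycles.  Per-frame phase labels mark each frame as systolic or
diastolic; segmentation masks label pixels as background, anterior leaflet
(AL), posterior leaflet (PL) or prolapse (MVP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

# Segmentation label codes.
BACKGROUND = 0
AL = 1
PL = 2
MVP = 3
SEG_CLASS_NAMES = {BACKGROUND: "background", AL: "AL", PL: "PL", MVP: "MVP"}

# Phase label strings (CSV-facing) and integer codes (array-facing).
SYSTOLE = "systole"
DIASTOLE = "diastole"
PHASE_TO_INT = {DIASTOLE: 0, SYSTOLE: 1}
INT_TO_PHASE = {0: DIASTOLE, 1: SYSTOLE}

# The six clinical mitral sub-zones (scallops), lateral to medial.
SUB_ZONES = ("A1", "A2", "A3", "P1", "P2", "P3")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class ConfigurationError(ValueError):
    """Raised when a configuration violates one of its invariants."""


class DataError(ValueError):
    """Raised when a dataset is unusable (empty, single-class, ...)."""


@dataclass
class CineSequence:
    """An ordered stack of grayscale frames plus acquisition metadata."""

    frames: np.ndarray  # (T, H, W) uint8
    case_id: str = "case"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("cine frames must be a (T, H, W) stack")
        if self.frames.dtype != np.uint8:
            raise ValidationError("cine frames must be 8-bit grayscale")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class PhaseAnnotation:
    """Per-frame systole/diastole labels, stored as 0 (diastole) / 1 (systole)."""

    labels: np.ndarray  # (T,) int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.dtype.kind in "US":
            self.labels = np.array([PHASE_TO_INT[str(v)] for v in self.labels])
        self.labels = self.labels.astype(np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("phase labels must be one per frame")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValidationError(f"phase labels must be 0/1, got extras {bad}")

    @property
    def names(self) -> list[str]:
        return [INT_TO_PHASE[int(v)] for v in self.labels]

    def systolic_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    def __len__(self) -> int:
        return int(self.labels.shape[0])


def validate_seg_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Check a 4-class leaflet/prolapse label map and return it as int8."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError("segmentation mask must be 2-D")
    if mask.dtype.kind not in "iu":
        raise ValidationError("segmentation mask must hold integer labels")
    if shape is not None and mask.shape != tuple(shape):
        raise ValidationError(f"mask shape {mask.shape} does not match frame shape {shape}")
    bad = set(np.unique(mask)) - {BACKGROUND, AL, PL, MVP}
    if bad:
        raise ValidationError(f"mask contains labels outside {{0,1,2,3}}: {bad}")
    return mask.astype(np.int8)
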