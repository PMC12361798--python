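"""Ground-truth-backed stand-in models for pipeline testing.

These objects implement the same calling contracts as trained models but
answer from a synthetic case's stored ground truth.  They isolate the
rule-based stages (cycle parsing, diagnosis, severe-zone judgement) from
learned-model error, so rule behaviour can be verified exactly.
"""

from __future__ import annotations

import numpy as np

from .synthetic import SyntheticCase


class OraclePhaseModel:
    """Emits saturated logits matching the case's true phase labels.

    Frames are matched by identity of content (index lookup), so the oracle
    must be built from the same case it is asked about.
    """

    def __init__(self, case: SyntheticCase, magnitude: float = 10.0):
        self.case = case
        self.magnitude = magnitude
        self._index = {case.cine.frames[t].tobytes(): t for t in range(case.cine.n_frames)}

    def _frame_index(self, frame: np.ndarray) -> int:
        key = np.ascontiguousarray(frame).tobytes()
        if key not in self._index:
            raise KeyError("frame does not belong to this oracle's case")
        return self._index[key]

    def __call__(self, frame: np.ndarray) -> tuple[float, float]:
        t = self._frame_index(frame)
        if self.case.phase_labels.labels[t] == 1:
            return (0.0, self.magnitude)
        return (self.magnitude, 0.0)


class OracleSegmenter:
    """Returns the case's stored ground-truth mask for each frame."""

    def __init__(self, case: SyntheticCase):
        self.case = case
        self._index = {case.cine.frames[t].tobytes(): t for t in range(case.cine.n_frames)}

    def segment(self, frame: np.ndarray) -> np.ndarray:
        key = np.ascontiguousarray(frame).tobytes()
        if key not in self._index:
            raise KeyError("frame does not belong to this oracle's case")
        return self.case.masks[self._index[key]].copy()


class OracleHeatmapModel:
    """Returns the binary ground-truth prolapse mask as a saliency map."""

    def __init__(self, case: SyntheticCase):
        self._seg = OracleSegmenter(case)

    def predict(self, frame: np.ndarray) -> np.ndarray:
        from .data import MVP

        return (self._seg.segment(frame) == MVP).astype(np.float64)


class ConstantPhaseModel:
    """A stub emitting one fixed logit pair for every frame."""

    def __init__(self, o_neg: float, o_pos: float):
        self.pair = (float(o_neg), float(o_pos))

    def __call__(self, frame) -> tuple[float, float]:
        return self.pair
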