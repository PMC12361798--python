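"""End-to-end agent: phase recognition -> MVP diagnosis -> heatmaps.

The pipeline order is fixed.  Frames are first labelled systolic/diastolic
by the confidence-gated ensemble; the systolic frames are segmented and the
frame/patient rules applied; for an MVP-positive study the frame with the
largest predicted prolapse area is parsed for the severe-zone call and a
saliency heatmap is produced for every systolic frame.  Each stage's
intermediate output can be persisted to a run directory for audit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .config import AgentConfig
from .data import MVP, CineSequence, ConfigurationError, PhaseAnnotation
from .diagnosis import (
    PatientDiagnosis,
    SegModel,
    SevereZoneCall,
    diagnose_frame,
    diagnose_patient,
    judge_severe_zone,
    parse_regions,
    roc_over_proportion,
)
from .heatmap import HeatmapModel, write_heatmap_png
from .metrics import (
    classification_metrics,
    match_cycles,
    overlap_metrics,
    phase_error_stats,
)
from .phase import PhaseModel, parse_cycles, predict_sequence, write_decisions_csv
from .synthetic import _MASK_PALETTE, SyntheticCase

logger = logging.getLogger(__name__)

__all__ = ["AgentModels", "AgentReport", "run_agent", "evaluate_cases"]


@dataclass
class AgentModels:
    """The three trained (or oracle) models the agent drives."""

    phase_a: object  # callable frame -> (o_neg, o_pos)
    phase_b: object
    segmenter: object  # has .segment(frame) -> label map
    heatmap: object  # has .predict(frame) -> saliency map

    @classmethod
    def load(cls, config: AgentConfig) -> "AgentModels":
        for name in ("phase_main_checkpoint", "phase_secondary_checkpoint",
                     "segmenter_checkpoint", "heatmap_checkpoint"):
            if not Path(getattr(config, name)).exists():
                raise ConfigurationError(f"missing checkpoint: {getattr(config, name)}")
        return cls(
            phase_a=PhaseModel.load(config.phase_main_checkpoint),
            phase_b=PhaseModel.load(config.phase_secondary_checkpoint),
            segmenter=SegModel.load(config.segmenter_checkpoint),
            heatmap=HeatmapModel.load(config.heatmap_checkpoint),
        )


@dataclass
class AgentReport:
    """Everything the agent concluded about one cine loop."""

    case_id: str
    status: str  # "ok" or "no_systole"
    phase_labels: PhaseAnnotation | None = None
    decisions: list = field(default_factory=list)
    patient: PatientDiagnosis | None = None
    severe_zone: SevereZoneCall | None = None
    frame_diagnoses: list = field(default_factory=list)
    masks: dict[int, np.ndarray] = field(default_factory=dict)
    heatmaps: dict[int, np.ndarray] = field(default_factory=dict)
    heatmap_paths: list[str] = field(default_factory=list)

    @property
    def is_mvp(self) -> bool | None:
        return None if self.patient is None else self.patient.is_mvp

    def to_dict(self) -> dict:
        out = {
            "case_id": self.case_id,
            "status": self.status,
            "phase_labels": None if self.phase_labels is None else self.phase_labels.names,
            "patient": None if self.patient is None else self.patient.as_dict(),
            "severe_zone": None if self.severe_zone is None else self.severe_zone.as_dict(),
            "frame_diagnoses": [
                {"frame_index": d.frame_index, "has_mvp": bool(d.has_mvp),
                 "mvp_area": int(d.mvp_area)}
                for d in self.frame_diagnoses
            ],
            "heatmap_paths": list(self.heatmap_paths),
        }
        return out


def run_agent(
    cine: CineSequence,
    config: AgentConfig,
    models: AgentModels | None = None,
    annotated_phases: PhaseAnnotation | None = None,
    out_dir: str | Path | None = None,
) -> AgentReport:
    """Run the full three-stage agent on one cine loop.

    ``annotated_phases``, when given, bypasses the phase models (evaluation
    against expert phase labels); otherwise the active-if ensemble labels
    every frame.  With ``out_dir`` set, per-stage intermediates (decision
    CSV, predicted masks, heatmaps, report JSON) are written for audit.
    """
    if models is None:
        models = AgentModels.load(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    decisions: list = []
    if annotated_phases is not None:
        labels = annotated_phases
    else:
        labels, decisions = predict_sequence(
            cine, models.phase_a, models.phase_b, config.c_threshold
        )
    if out is not None and decisions:
        write_decisions_csv(out / "phase_decisions.csv", labels, decisions)

    systolic = labels.systolic_indices()
    if systolic.size == 0:
        logger.warning("%s: no systolic frames detected", cine.case_id)
        report = AgentReport(cine.case_id, "no_systole", phase_labels=labels,
                             decisions=decisions)
        if out is not None:
            (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        return report

    frame_diags, masks = [], {}
    for t in systolic:
        mask = models.segmenter.segment(cine.frames[t])
        masks[int(t)] = mask
        frame_diags.append(diagnose_frame(mask, frame_index=int(t), min_area=config.min_area))
    patient = diagnose_patient(frame_diags, threshold=config.patient_threshold)

    severe = None
    heatmaps: dict[int, np.ndarray] = {}
    heatmap_paths: list[str] = []
    if patient.is_mvp and patient.index_frame is not None:
        regions = parse_regions(masks[patient.index_frame])
        severe = judge_severe_zone(regions)
        for t in systolic:
            heatmaps[int(t)] = models.heatmap.predict(cine.frames[t])

    report = AgentReport(
        case_id=cine.case_id,
        status="ok",
        phase_labels=labels,
        decisions=decisions,
        patient=patient,
        severe_zone=severe,
        frame_diagnoses=frame_diags,
        masks=masks,
        heatmaps=heatmaps,
    )

    if out is not None:
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for t, mask in masks.items():
            pimg = Image.fromarray(mask.astype(np.uint8), mode="P")
            pimg.putpalette(_MASK_PALETTE)
            pimg.save(mask_dir / f"{t:04d}.png")
        if heatmaps:
            heat_dir = out / "heatmaps"
            heat_dir.mkdir(exist_ok=True)
            for t, heat in heatmaps.items():
                path = heat_dir / f"{t:04d}.png"
                write_heatmap_png(heat, path, frame=cine.frames[t])
                heatmap_paths.append(str(path))
            report.heatmap_paths = heatmap_paths
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report


def evaluate_cases(cases: list[SyntheticCase], reports: list[AgentReport]) -> dict:
    """Score agent reports against ground truth on every defined metric.

    Returns a nested dict with frame-level phase classification (Pre, Rec,
    F1, Acc), cycle-level detection (AccSys plus AE/E1/E2 for ED and ES),
    frame- and patient-level MVP diagnosis (Pre/Rec/F1/Acc and AUC over the
    proportion of systolic frames with MVP) and pixel-level heatmap overlap
    (mean Dice and IoU over systolic prolapse frames).
    """
    if len(cases) != len(reports):
        raise ValueError("one report per case required")

    phase_true, phase_pred = [], []
    t_sum = p_sum = n_sum = 0
    ed_true, ed_pred, es_true, es_pred = [], [], [], []
    frame_true, frame_pred = [], []
    patient_records = []
    patient_true, patient_pred = [], []
    dices, ious = [], []

    for case, report in zip(cases, reports):
        if report.phase_labels is not None:
            phase_true.extend(case.phase_labels.labels.tolist())
            phase_pred.extend(report.phase_labels.labels.tolist())
            gt_cycles = parse_cycles(case.phase_labels)
            pr_cycles = parse_cycles(report.phase_labels)
            if gt_cycles.n_cycles or pr_cycles.n_cycles:
                summary, pairs = match_cycles(gt_cycles, pr_cycles)
                t_sum += summary.t_correct
                p_sum += summary.p_predicted
                n_sum += summary.n_truth
                for gi, pi in pairs:
                    ed_true.append(gt_cycles.ed_frames[gi])
                    ed_pred.append(pr_cycles.ed_frames[pi])
                    es_true.append(gt_cycles.es_frames[gi])
                    es_pred.append(pr_cycles.es_frames[pi])

        if report.patient is not None:
            patient_true.append(case.mvp_truth)
            patient_pred.append(report.patient.is_mvp)
            patient_records.append((report.patient.proportion, case.mvp_truth))
            for diag in report.frame_diagnoses:
                truth_has = bool((case.masks[diag.frame_index] == MVP).any())
                frame_true.append(int(truth_has))
                frame_pred.append(int(diag.has_mvp))

        for t, heat in report.heatmaps.items():
            truth_mask = case.masks[t] == MVP
            if truth_mask.any():
                seg = overlap_metrics(heat >= 0.5, truth_mask)
                dices.append(seg.dice)
                ious.append(seg.iou)

    out: dict = {}
    if phase_true:
        out["phase_frame"] = classification_metrics(phase_true, phase_pred).as_dict()
        out["cycle"] = {
            "accsys": t_sum / (p_sum + n_sum - t_sum) if (p_sum + n_sum) else None,
            "ed": phase_error_stats(ed_true, ed_pred).__dict__ if ed_true else None,
            "es": phase_error_stats(es_true, es_pred).__dict__ if es_true else None,
        }
        for key in ("ed", "es"):
            if out["cycle"][key] is not None:
                stats = out["cycle"][key]
                out["cycle"][key] = {"ae": stats["ae"], "e1": stats["e1"], "e2": stats["e2"]}
    if frame_true:
        out["diagnosis_frame"] = classification_metrics(frame_true, frame_pred).as_dict()
    if patient_true:
        out["diagnosis_patient"] = classification_metrics(
            [int(v) for v in patient_true], [int(v) for v in patient_pred]
        ).as_dict()
        if any(patient_true) and not all(patient_true):
            out["diagnosis_patient"]["auc"] = roc_over_proportion(patient_records).auc
    if dices:
        out["heatmap"] = {"dice": float(np.mean(dices)), "iou": float(np.mean(ious))}
    return out
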