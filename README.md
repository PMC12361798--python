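# echomvp

An automated diagnosis and visualisation agent for **mitral valve prolapse
(MVP)** on echocardiographic cine loops, for researchers building or
evaluating valve-analysis pipelines.  MVP is the systolic displacement of a
mitral leaflet past the annular plane (≥ 2 mm by the clinical criterion);
reading it from 3-D echo renderings requires finding the systolic frames,
recognising the prolapsing tissue, and localising which leaflet scallop
(A1–A3, P1–P3) is affected.  `echomvp` implements that full pipeline as
three tested stages, plus a synthetic cine generator so everything runs and
is verifiable without any clinical data.

## The method

**1. Systolic phase recognition.**  Two independently trained frame
classifiers (a main network A, a secondary network B) are combined by a
confidence-gated *active-if* rule.  With the two-term softmax
P(N,1) = e^{O(N,1)} / (e^{O(N,0)} + e^{O(N,1)}) and confidence
Conf_N = 2·|P(N,1) − 0.5|, network B answers only when

    Conf_A < C   and   Conf_B > Conf_A        (C = 0.4)

and A answers otherwise.  Maximal systolic runs become cardiac cycles; the
first/last frame of each run are taken as ED/ES.

**2. MVP diagnosis.**  An FCN-8-style network segments each systolic frame
into anterior leaflet, posterior leaflet and prolapse.  A frame has MVP if
its mask contains prolapse pixels; a study is MVP if **more than half** of
its systolic frames have MVP.  On the frame with the largest prolapse
area, connected-component parsing plus leaflet-overlap/centroid geometry
yields the affected leaflet (SSZ_APL), per-leaflet involvement (DSZ_APL)
and the severe sub-zone (SSZ_SSZ ∈ {A1..A3, P1..P3}).  Patient-level ROC
sweeps the threshold on the proportion of systolic frames with MVP.

**3. Saliency heatmaps.**  A four-level feature pyramid with learnable
frequency-domain attention on the shallow levels feeds content- and
edge-detection heads; content-gated, edge-guided progressive fusion yields
a per-pixel prolapse saliency map in [0, 1].  Edge supervision targets an
*edge belt* — all pixels within Chebyshev distance w of the mask boundary —
rather than a one-pixel contour.

Evaluation covers every level: Pre/Rec/F1/Acc (frames and patients),
AccSys = T/(P+N−T) with AE/E1/E2 frame errors for ED and ES (cycles), AUC
(patients), Dice/IoU (pixels).  See `docs/methods.md` for definitions,
conventions and limitations.

All networks run on a small numpy autodiff kit bundled with the package
(`echomvp.nn`), sized to train in minutes on one CPU core.

## Worked example

Run the rule pipeline on a generated prolapse case with ground-truth-backed
oracle models (no training needed):

```python
import json
from echomvp import AgentConfig, EchoPhantomConfig, generate_case
from echomvp.agent import AgentModels, run_agent
from echomvp.oracle import OracleHeatmapModel, OraclePhaseModel, OracleSegmenter

case = generate_case(
    EchoPhantomConfig(mvp_case=True, prolapse_amplitude=7.0, prolapse_zone="P2",
                      n_cycles=3, frames_per_cycle=14, systole_fraction=0.45, seed=42),
    case_id="demo",
)
phase = OraclePhaseModel(case)
models = AgentModels(phase, phase, OracleSegmenter(case), OracleHeatmapModel(case))
report = run_agent(case.cine, AgentConfig(), models=models)
print("patient:", json.dumps(report.to_dict()["patient"]))
print("severe_zone:", json.dumps(report.to_dict()["severe_zone"]))
```

prints

```
patient: {"n_systolic_frames": 18, "n_mvp_frames": 18, "proportion": 1.0, "is_mvp": true, "index_frame": 0}
severe_zone: {"ssz_apl": "PL", "dsz_apl": [false, true], "ssz_ssz": "P2"}
```

All 18 systolic frames of the 42-frame loop show prolapse, so the
proportion is 1.0 > 0.5 and the study is called MVP; the geometry step
attributes the largest prolapse component to the posterior leaflet, middle
third — P2, matching the generator's ground truth.

The same pipeline is available from the shell with trained models:

```bash
echomvp generate --n-control 6 --n-mvp 6 --out data/ --seed 5
echomvp train-phase   --data data/ --out run/
echomvp train-seg     --data data/ --out run/
echomvp train-heatmap --data data/ --out run/
echomvp predict  --case-dir data/mvp_000 --out preds/mvp_000 --config run/config.yaml
echomvp evaluate --pred preds/ --truth data/ --out eval/
```

`evaluate` writes `metrics.json`/`metrics.csv` with all frame-, cycle-,
patient- and pixel-level metrics.

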