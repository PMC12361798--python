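# Methods

`echomvp` implements a three-stage analysis agent for cine loops rendered
from 3-D echocardiography of the mitral valve, together with a synthetic
cine generator that provides exact ground truth for every stage.  This note
documents the models, the rules, the numerical choices, and what the
synthetic data can and cannot establish.

## Pipeline overview

Given an ordered stack of 8-bit grayscale frames, the agent

1. labels every frame **systolic or diastolic** with a confidence-gated
   two-network ensemble, and parses the labels into cardiac cycles;
2. **segments** each systolic frame into background, anterior leaflet (AL),
   posterior leaflet (PL) and prolapse (MVP), applies a frame rule and a
   patient rule to diagnose mitral valve prolapse, and localises the most
   severe prolapse zone on the frame with the largest predicted MVP area;
3. produces a per-pixel **saliency heatmap** of the prolapse for every
   systolic frame of a positive study, trained with edge-belt supervision
   and frequency-domain attention.

## Stage 1: systolic phase recognition

Two binary frame classifiers are trained independently: a main network A
and a secondary network B with a different inductive bias.  For network
N with raw two-class scores O(N,0), O(N,1), the positive (systolic)
probability is the two-term softmax

    P(N,1) = exp(O(N,1)) / (exp(O(N,0)) + exp(O(N,1)))

and the confidence level is

    Conf_N = 2 |P(N,1) − 0.5|,

which is 0 at a coin flip and 1 at certainty.  The **active-if rule**
prefers A and activates B only when A is unsure and B is surer:

    use B  ⇔  Conf_A < C  and  Conf_B > Conf_A,       C = 0.4 (default).

Both inequalities are strict; ties keep A.  C is exposed in the
configuration.

Frame labels are thresholded at P ≥ 0.5 (ties positive).  Maximal runs of
systolic labels are the systole periods; within each run the first frame is
taken as end-diastole (ED) and the last as end-systole (ES).  This ED/ES
convention is a package definition — prediction and ground truth are parsed
identically, so the convention cancels in every error metric.  No temporal
smoothing is applied before parsing.

## Stage 2: segmentation-based diagnosis

The segmenter is a small FCN-8-style dense predictor: a convolutional
encoder pooled to strides 2/4/8, 1×1 score maps at every stride fused
top-down by nearest upsampling and addition, plus a full-resolution skip
that keeps the thin leaflet boundaries pixel-accurate.  The input is the
frame resized to a square working size plus two normalised coordinate
channels: the leaflet-versus-prolapse distinction is positional (which side
of the annulus tissue lies on), and explicit coordinates let a shallow
network use that cue.  Training exposes two knobs: per-class loss weights
(default 0.5/1/1/3, up-weighting the small prolapse class) and a
learning-rate ratio K between the encoder and decoder parameter groups
(default 1).

Diagnosis is rule-based on predicted masks:

* **Frame rule** — a systolic frame has MVP iff its mask contains at least
  `min_area` prolapse pixels.  Default 1 px: any predicted MVP area counts.
  The threshold is exposed because noisy segmenters may need it raised.
* **Patient rule** — a study is MVP iff strictly more than half of its
  systolic frames have MVP.  A proportion of exactly 0.5 is negative.
* **Index frame** — the frame with the largest predicted MVP area (ties →
  lowest frame index) is used for localisation.

Severe-zone localisation runs in two steps on the index frame.  The
*region-parsing* step extracts 8-connected components per class with area,
centroid and bounding box, discarding components below a configurable
minimum area.  The *logical-judgement* step relates the prolapse components
to the leaflets geometrically: each leaflet's support is dilated by d = 3 px
(Chebyshev); DSZ_APL reports per leaflet whether any MVP component touches
its dilated support; SSZ_APL is the leaflet whose dilated support overlaps
the largest MVP component most (tie → AL, anterior first, fixed
convention); SSZ_SSZ bins the largest component's centroid into thirds of
the chosen leaflet's extent along the annulus axis, giving A1–A3 or P1–P3
lateral-to-medial.  The annulus axis is taken from the generator when
known, otherwise estimated as the principal axis of the combined leaflet
support.

The ROC for patient diagnosis sweeps the decision threshold over the score
"proportion of systolic frames with MVP"; AUC is computed by the trapezoid
rule and equals the concordant-pair fraction.

## Stage 3: edge-belt-guided saliency heatmaps

A four-level convolutional pyramid (strides 4/8/16/32) feeds three heads:

* a **content-detection** head fusing levels 2–4 (upsampled to stride 8,
  concatenated, convolved) into a coarse single-channel content map;
* an **edge-detection** head reading level 1 — the shallowest features
  carry the most edge information — at stride 4;
* a **refinement** path: levels 2–4 are multiplied by the sigmoid of the
  content map (resized per level), fused top-down (4→3→2) through 3×3
  convolutions and nearest upsampling, gated by the sigmoid of the edge
  map at stride 4, then refined by two learned upsampling stages to full
  resolution and squashed to [0, 1].

**Frequency-domain attention** is applied to the outputs of levels 1 and 2.
Each channel's 2-D spectrum is multiplied by a learnable real weight map
symmetrised over mirrored frequency pairs, transformed back and added
residually:

    y = Re( F⁻¹ ( S ⊙ F x ) ) + x,     S = (W + mirror(W)) / 2.

The symmetrisation makes the spectral symbol conjugate-symmetric, so the
output is exactly real; the operator is self-adjoint, which gives a closed-
form backward pass.  Zero weights are the identity (pure residual), unit
weights a doubling; the gate is initialised at zero so a fresh network is
unperturbed.  At inference sizes other than the training size the learned
spectrum is resampled bilinearly.

**Edge belts.**  Edge supervision does not target the one-pixel boundary.
The boundary of a binary mask is the set of mask pixels 8-adjacent to
background (the image border itself does not create boundary); the belt of
width w is every pixel within Chebyshev distance ≤ w of a boundary pixel
(default w = 3; an empty mask has an empty belt).  A belt of nonzero
thickness concentrates learning on the boundary region while tolerating
small annotation bias at the prolapse rim.  Belt generation is exact and is
tested pixel-for-pixel against an all-pairs distance oracle.

**Losses.**  Joint loss = w_c · BCE(content map, area-averaged-then-
thresholded mask at stride 8) + w_e · BCE(edge map, nearest-downsampled
belt at stride 4) + w_f · (BCE + soft-IoU)(final map, mask), with weights
(1, 1, 2) favouring the final map.  Heatmaps binarised at 0.5 are scored
with Dice and IoU.

## Network implementation

All three models run on a compact reverse-mode autodiff kit written on
numpy (`echomvp.nn`): broadcast arithmetic, im2col-free convolution by
kernel-offset slicing, average pooling, nearest upsampling, concatenation,
the spectral gate, and fused softmax/BCE/soft-IoU losses, with SGD and Adam
optimisers supporting parameter groups.  Every backward pass is verified
against central finite differences in the test suite.  The architectures
are deliberately tiny — a dense-concat CNN and a conv+MLP classifier for
stage 1, the FCN-8-style net for stage 2, the pyramid net for stage 3 — so
that training runs in minutes on one CPU core.  The checkpoints are plain
`.npz` archives.

## Synthetic cine generator

The phantom draws a bright imaging sector (fan) on a black background with
an apex near the top.  A horizontal annulus line crosses the sector; the
anterior leaflet is an arc-band above it and the posterior leaflet below,
spanning a chord, bowed toward the ventricle.  During diastole the
leaflets swing open (a bell-shaped opening profile with a nonzero floor,
mimicking fast early-diastolic filling); during systole they coapt at the
annulus.  In prolapse cases a half-disc of leaflet tissue rooted at the
source leaflet's coapted edge crosses ≥ 2 px past the annulus — the pixel
analogue of the ≥ 2 mm displacement criterion — inside one of six sub-zones
(thirds of each leaflet along the chord, A1–A3/P1–P3 left to right), on
systolic frames only.  Pixels of the other leaflet within a 4-px clearance
of the bulge are removed, so the bulge is geometrically attached to its
source leaflet only, giving an unambiguous localisation ground truth.
Images get multiplicative Rayleigh speckle (unit mean, blended by a sigma
parameter) and Gaussian blur; masks stay noise-free.

Cohorts are sampled from configurable ranges — 2–5 cardiac cycles and
13–26 frames per cycle by default (loop lengths 26–130 frames), varying
systole fraction, sector angle, prolapse amplitude and zone, and speckle
level — and split train/val/test 3:2:3, stratified by class.  The default
working size is 192×192 px so CPU tests stay fast; the native 800×600
acquisition size is available through the configuration.  No pixel-to-mm
calibration is claimed.

**What the phantom does not emulate:** real speckle statistics and shadowing,
out-of-plane motion, probe/gain variation, arrhythmic cycle-length
variability, chordae and papillary structures, regurgitation, and
non-diagnostic prolapse morphologies.  Passing tests therefore establish
that the *rules and learning machinery* behave as specified on data with
the stated geometry — not clinical performance.

## Problem sizes and numerical choices

* Learning checks use a 60-video cohort (30 control / 30 MVP): the phase
  ensemble trains 5 epochs and is scored on held-out frames; the segmenter
  trains 10 epochs on up to 300 systolic frames (round-robin across cases)
  and is scored by mean foreground Dice; the saliency model trains 15
  epochs on up to 200 prolapse frames and is additionally checked to
  memorise a single frame within 300 steps.  Working sizes: 64 px (phase),
  96 px (segmenter), 128 px (heatmap).
* The rule pipeline is checked end-to-end on 40 cases with ground-truth
  oracle models standing in for the learned stages.
* ED/ES frame errors are computed over matched cycles only (an unmatched
  cycle has no frame correspondence); cycle matching is greedy in temporal
  order with at most one predicted period per true cycle, so one long
  predicted period cannot validate several cycles.
* Precision with zero predicted positives is 0 with a logged warning.
  Dice/IoU of two empty masks is 1 by convention (documented; scored frames
  contain prolapse in the intended protocol).
* Softmax and sigmoid evaluations clamp logits at ±60 before
  exponentiation; the two-term softmax subtracts the max logit.

## Known limitations

* The tiny architectures are not the large pretrained backbones used in
  clinical-scale work; they preserve topology and interfaces, not capacity.
* The severe-zone geometry assumes one dominant prolapse component and a
  roughly horizontal annulus; multi-segment flail or heavily rotated views
  would need a more robust annulus estimate.
* The generator's difficulty is tunable; results on it bound nothing about
  hospital data.
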