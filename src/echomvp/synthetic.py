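"""Synthetic echocardiography-like cine loops with exact ground truth.

Real transesophageal 3-D echo renderings of the mitral valve cannot be
redistributed, so this module draws a geometric phantom that preserves the
features the pipeline reasons about: a fan/sector imaging zone on a black
background, two leaflet bands (anterior above, posterior below) meeting at a
horizontal annulus line, leaflets that swing open during diastole and coapt
during systole, and — in prolapse cases — a bulge of leaflet tissue that
crosses the annulus line during systole only, within one of the six clinical
sub-zones A1–A3 / P1–P3.  Multiplicative Rayleigh speckle and Gaussian blur
emulate ultrasound texture on the images; masks stay noise-free.

Every case carries its full ground truth (per-frame phase labels, per-frame
4-class masks, patient-level prolapse status and severe sub-zone), so each
downstream stage can be scored exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data import (
    AL,
    BACKGROUND,
    MVP,
    PL,
    SUB_ZONES,
    CineSequence,
    ConfigurationError,
    PhaseAnnotation,
)

# Palette used when writing indexed mask PNGs (background, AL, PL, MVP).
_MASK_PALETTE = [0, 0, 0, 60, 140, 255, 80, 220, 120, 255, 70, 70]

# Chebyshev clearance carved around a prolapse bulge so the bulge stays
# attached (within the 3-px judgement dilation) to its source leaflet only.
_BULGE_CLEARANCE = 4


@dataclass(frozen=True)
class EchoPhantomConfig:
    """Shape, motion and noise parameters of one synthetic cine loop."""

    image_size: tuple[int, int] = (192, 192)  # (width, height)
    n_cycles: int = 3
    frames_per_cycle: int = 16
    systole_fraction: float = 0.45
    mvp_case: bool = False
    prolapse_amplitude: float = 0.0  # px the bulge crosses past the annulus
    prolapse_zone: str | None = None  # one of A1..P3 when mvp_case
    speckle_sigma: float = 0.4
    blur_sigma: float = 1.0
    seed: int = 0
    # secondary shape knobs, drawn from ranges by generate_dataset
    sector_half_angle_deg: float = 35.0
    blood_intensity: float = 55.0
    tissue_intensity: float = 195.0
    leaflet_thickness: float | None = None  # default scales with height

    def validate(self) -> None:
        w, h = self.image_size
        if w < 32 or h < 32:
            raise ConfigurationError("invariant violated: image_size must be at least 32x32")
        if self.n_cycles < 1:
            raise ConfigurationError("invariant violated: n_cycles >= 1")
        if self.frames_per_cycle < 2:
            raise ConfigurationError("invariant violated: frames_per_cycle >= 2")
        if not 0.0 < self.systole_fraction < 1.0:
            raise ConfigurationError("invariant violated: 0 < systole_fraction < 1")
        if self.mvp_case != (self.prolapse_amplitude > 0):
            raise ConfigurationError(
                "invariant violated: prolapse_amplitude > 0 iff mvp_case"
            )
        if self.mvp_case:
            if self.prolapse_zone not in SUB_ZONES:
                raise ConfigurationError(
                    f"invariant violated: prolapse_zone must be one of {SUB_ZONES}"
                )
            if self.prolapse_amplitude < 2:
                raise ConfigurationError(
                    "invariant violated: prolapse must cross the annulus by >= 2 px"
                )
        elif self.prolapse_zone is not None:
            raise ConfigurationError("invariant violated: prolapse_zone set on a control case")
        if self.speckle_sigma < 0 or self.blur_sigma < 0:
            raise ConfigurationError("invariant violated: noise scales must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.frames_per_cycle

    @property
    def n_systole_per_cycle(self) -> int:
        n = int(round(self.frames_per_cycle * self.systole_fraction))
        return int(np.clip(n, 1, self.frames_per_cycle - 1))


@dataclass
class SyntheticCase:
    """One generated cine with its complete ground truth."""

    cine: CineSequence
    phase_labels: PhaseAnnotation
    masks: np.ndarray  # (T, H, W) int8 labels in {0..3}
    mvp_truth: bool
    severe_zone_truth: str | None
    config: EchoPhantomConfig
    split: str = "train"

    @property
    def case_id(self) -> str:
        return self.cine.case_id

    @property
    def sector_bbox(self) -> tuple[int, int, int, int]:
        """Ground-truth bounding box (x0, y0, x1, y1) of the imaging sector."""
        return tuple(self.cine.meta["sector_bbox"])

    @property
    def annulus_y(self) -> float:
        return float(self.cine.meta["annulus_y"])

    @property
    def leaflet_x_extent(self) -> tuple[float, float]:
        return tuple(self.cine.meta["leaflet_x_extent"])


@dataclass(frozen=True)
class PhantomRanges:
    """Sampling ranges for per-case configs (inclusive bounds).

    Defaults mirror the acquisition statistics the pipeline targets: 2–5
    cardiac cycles per loop and 13–26 frames per cycle, so total video
    length spans 26–130 frames.
    """

    n_cycles: tuple[int, int] = (2, 5)
    frames_per_cycle: tuple[int, int] = (13, 26)
    systole_fraction: tuple[float, float] = (0.35, 0.5)
    prolapse_amplitude: tuple[float, float] = (5.0, 10.0)
    speckle_sigma: tuple[float, float] = (0.25, 0.5)
    sector_half_angle_deg: tuple[float, float] = (30.0, 40.0)
    image_size: tuple[int, int] = (192, 192)


def _phase_vector(cfg: EchoPhantomConfig) -> np.ndarray:
    """0/1 phase labels: each cycle opens with its systolic run."""
    n_sys = cfg.n_systole_per_cycle
    cycle = np.zeros(cfg.frames_per_cycle, dtype=np.int64)
    cycle[:n_sys] = 1
    return np.tile(cycle, cfg.n_cycles)


def _openness(cfg: EchoPhantomConfig) -> np.ndarray:
    """Leaflet opening amount per frame: 0 in systole, bell-shaped in diastole.

    Diastolic opening starts from a nonzero floor: early diastolic filling
    swings the leaflets open quickly, so even transition frames show clear
    separation from the closed systolic position.
    """
    n_sys = cfg.n_systole_per_cycle
    n_dia = cfg.frames_per_cycle - n_sys
    cycle = np.zeros(cfg.frames_per_cycle)
    j = np.arange(n_dia)
    cycle[n_sys:] = 0.3 + 0.7 * np.sin(np.pi * (j + 0.5) / n_dia)
    return np.tile(cycle, cfg.n_cycles)


@dataclass
class _Geometry:
    apex: tuple[float, float]
    radius: float
    half_angle: float
    annulus_y: float
    x_left: float
    x_right: float
    thickness: float
    gap: float
    open_amplitude: float
    curvature: float
    sector: np.ndarray  # bool (H, W)
    sector_bbox: tuple[int, int, int, int]


def _build_geometry(cfg: EchoPhantomConfig) -> _Geometry:
    w, h = cfg.image_size
    cx, cy = w / 2.0, 0.06 * h
    radius = 0.88 * h
    half_angle = np.deg2rad(cfg.sector_half_angle_deg)

    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    dist = np.hypot(dx, dy)
    # angle measured from straight-down beam direction
    ang = np.abs(np.arctan2(dx, dy))
    sector = (dist <= radius) & (ang <= half_angle) & (dy >= 0)
    ys, xs = np.nonzero(sector)
    bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)

    annulus_y = cy + 0.55 * radius
    chord_half = (annulus_y - cy) * np.tan(half_angle)
    inset = 0.12 * chord_half
    thickness = cfg.leaflet_thickness or max(4.0, 0.035 * h)
    return _Geometry(
        apex=(cx, cy),
        radius=radius,
        half_angle=half_angle,
        annulus_y=annulus_y,
        x_left=cx - chord_half + inset,
        x_right=cx + chord_half - inset,
        thickness=thickness,
        gap=1.0,
        open_amplitude=0.09 * h,
        curvature=0.025 * h,
        sector=sector,
        sector_bbox=bbox,
    )


def _leaflet_bands(geo: _Geometry, openness: float, shape: tuple[int, int]) -> np.ndarray:
    """4-class mask of the two leaflet bands at a given opening amount."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    span = geo.x_right - geo.x_left
    s = (xx - geo.x_left) / span
    in_x = (s >= 0) & (s <= 1)
    bow = geo.curvature * np.sin(np.pi * np.clip(s, 0, 1))
    half_t = geo.thickness / 2.0

    y_al = geo.annulus_y - geo.gap - half_t - openness * geo.open_amplitude - bow
    y_pl = geo.annulus_y + geo.gap + half_t + openness * geo.open_amplitude + bow

    mask = np.zeros(shape, dtype=np.int8)
    mask[in_x & (np.abs(yy - y_al) <= half_t)] = AL
    mask[in_x & (np.abs(yy - y_pl) <= half_t)] = PL
    mask[~geo.sector] = BACKGROUND
    return mask


def _zone_center_x(geo: _Geometry, zone: str) -> float:
    third = "123".index(zone[1])
    span = geo.x_right - geo.x_left
    return geo.x_left + (third + 0.5) * span / 3.0


def _add_bulge(mask: np.ndarray, geo: _Geometry, cfg: EchoPhantomConfig) -> np.ndarray:
    """Stamp the systolic prolapse bulge crossing the annulus line.

    The bulge is a half-disc rooted at the inner edge of its source leaflet,
    reaching ``prolapse_amplitude`` px past the annulus into the opposite
    side.  Pixels of the other leaflet within a small Chebyshev clearance of
    the bulge are cleared: the displaced segment pushes the coaptation line
    aside, and the clearance keeps the bulge geometrically attached to its
    own leaflet only.
    """
    zone = cfg.prolapse_zone
    assert zone is not None
    from_al = zone[0] == "A"
    x_z = _zone_center_x(geo, zone)
    # root the bulge at the source leaflet's coapted inner edge (incl. bow)
    s_z = (x_z - geo.x_left) / (geo.x_right - geo.x_left)
    bow = geo.curvature * np.sin(np.pi * s_z)
    offset = geo.gap + bow
    r = offset + cfg.prolapse_amplitude
    y_edge = geo.annulus_y - offset if from_al else geo.annulus_y + offset

    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (xx - x_z) ** 2 + (yy - y_edge) ** 2 <= r**2
    bulge = disc & ((yy >= y_edge) if from_al else (yy <= y_edge)) & geo.sector

    other = PL if from_al else AL
    near = ndimage.binary_dilation(bulge, np.ones((3, 3)), iterations=_BULGE_CLEARANCE)
    out = mask.copy()
    out[near & (out == other)] = BACKGROUND
    out[bulge] = MVP
    return out


def _render_frame(
    mask: np.ndarray, geo: _Geometry, cfg: EchoPhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    img = np.zeros(mask.shape, dtype=np.float64)
    img[geo.sector] = cfg.blood_intensity
    img[mask > 0] = cfg.tissue_intensity
    if cfg.speckle_sigma > 0:
        # Rayleigh multiplier normalised to unit mean, blended by sigma
        ray = rng.rayleigh(scale=1.0, size=mask.shape) / np.sqrt(np.pi / 2.0)
        img *= 1.0 + cfg.speckle_sigma * (ray - 1.0)
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_case(config: EchoPhantomConfig, case_id: str = "case") -> SyntheticCase:
    """Generate one cine loop with frames, masks and phase ground truth.

    Deterministic for a fixed config (including its seed): calling twice
    yields bit-identical frames and masks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    geo = _build_geometry(config)
    w, h = config.image_size

    labels = _phase_vector(config)
    openness = _openness(config)

    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    masks = np.empty((config.n_frames, h, w), dtype=np.int8)
    for t in range(config.n_frames):
        mask = _leaflet_bands(geo, float(openness[t]), (h, w))
        if config.mvp_case and labels[t] == 1:
            mask = _add_bulge(mask, geo, config)
        masks[t] = mask
        frames[t] = _render_frame(mask, geo, config, rng)

    cine = CineSequence(
        frames=frames,
        case_id=case_id,
        meta={
            "sector_bbox": list(geo.sector_bbox),
            "annulus_y": geo.annulus_y,
            "leaflet_x_extent": [geo.x_left, geo.x_right],
            "seed": config.seed,
        },
    )
    return SyntheticCase(
        cine=cine,
        phase_labels=PhaseAnnotation(labels),
        masks=masks,
        mvp_truth=config.mvp_case,
        severe_zone_truth=config.prolapse_zone,
        config=config,
    )


def _sample_config(
    rng: np.random.Generator, ranges: PhantomRanges, mvp_case: bool
) -> EchoPhantomConfig:
    lo, hi = ranges.n_cycles
    n_cycles = int(rng.integers(lo, hi + 1))
    lo, hi = ranges.frames_per_cycle
    fpc = int(rng.integers(lo, hi + 1))
    zone = str(rng.choice(SUB_ZONES)) if mvp_case else None
    amp = float(rng.uniform(*ranges.prolapse_amplitude)) if mvp_case else 0.0
    return EchoPhantomConfig(
        image_size=ranges.image_size,
        n_cycles=n_cycles,
        frames_per_cycle=fpc,
        systole_fraction=float(rng.uniform(*ranges.systole_fraction)),
        mvp_case=mvp_case,
        prolapse_amplitude=amp,
        prolapse_zone=zone,
        speckle_sigma=float(rng.uniform(*ranges.speckle_sigma)),
        sector_half_angle_deg=float(rng.uniform(*ranges.sector_half_angle_deg)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _assign_splits(n: int, ratio: tuple[int, int, int], rng: np.random.Generator) -> list[str]:
    total = sum(ratio)
    counts = [n * r // total for r in ratio]
    for i in range(n - sum(counts)):  # distribute remainder train-first
        counts[i % 3] += 1
    names = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
    rng.shuffle(names)
    return names


def generate_dataset(
    n_control: int,
    n_mvp: int,
    config_ranges: PhantomRanges | None = None,
    seed: int = 0,
    split_ratio: tuple[int, int, int] = (3, 2, 3),
) -> list[SyntheticCase]:
    """Generate a labelled cohort of control and prolapse cine loops.

    Per-case shape parameters are drawn reproducibly from ``config_ranges``;
    each case is assigned to train/val/test in the given ratio (default
    3:2:3), stratified by class.  Deterministic for a fixed seed.
    """
    if n_control < 0 or n_mvp < 0:
        raise ConfigurationError("case counts must be >= 0")
    ranges = config_ranges or PhantomRanges()
    rng = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    for klass, count in (("control", n_control), ("mvp", n_mvp)):
        splits = _assign_splits(count, split_ratio, rng)
        for i in range(count):
            cfg = _sample_config(rng, ranges, mvp_case=(klass == "mvp"))
            case = generate_case(cfg, case_id=f"{klass}_{i:03d}")
            case.split = splits[i]
            cases.append(case)
    return cases


def collect_systolic_frames(
    cases, mvp_only: bool = False, cap: int | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gather (frame, mask) pairs from systolic frames across cases.

    With ``mvp_only`` the mask is the binary prolapse support and frames
    without prolapse pixels are skipped.  When ``cap`` limits the total,
    frames are drawn round-robin across cases so the subset keeps the
    cohort's full geometric diversity rather than exhausting one case at a
    time.
    """
    per_case: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for case in cases:
        if mvp_only and not case.mvp_truth:
            continue
        pairs = []
        for t in case.phase_labels.systolic_indices():
            if mvp_only:
                m = case.masks[t] == MVP
                if not m.any():
                    continue
            else:
                m = case.masks[t]
            pairs.append((case.cine.frames[t], m))
        if pairs:
            per_case.append(pairs)
    frames, masks = [], []
    depth = 0
    while per_case and (cap is None or len(frames) < cap):
        advanced = False
        for pairs in per_case:
            if depth < len(pairs):
                f, m = pairs[depth]
                frames.append(f)
                masks.append(m)
                advanced = True
                if cap is not None and len(frames) >= cap:
                    break
        if not advanced:
            break
        depth += 1
    return frames, masks


# ---------------------------------------------------------------------------
# On-disk case layout: frames/NNNN.png, masks/NNNN.png, phases.csv,
# manifest.json


def write_case(case: SyntheticCase, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for t in range(case.cine.n_frames):
        Image.fromarray(case.cine.frames[t], mode="L").save(out / "frames" / f"{t:04d}.png")
        pimg = Image.fromarray(case.masks[t].astype(np.uint8), mode="P")
        pimg.putpalette(_MASK_PALETTE)
        pimg.save(out / "masks" / f"{t:04d}.png")
    with open(out / "phases.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "label"])
        for t, name in enumerate(case.phase_labels.names):
            writer.writerow([t, name])
    manifest = {
        "case_id": case.case_id,
        "n_frames": case.cine.n_frames,
        "image_size": [case.cine.frame_shape[1], case.cine.frame_shape[0]],
        "mvp_truth": case.mvp_truth,
        "severe_zone_truth": case.severe_zone_truth,
        "split": case.split,
        "seed": case.config.seed,
        "meta": {k: v for k, v in case.cine.meta.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def read_case(case_dir: str | Path) -> SyntheticCase:
    """Load a case written by :func:`write_case`."""
    case_dir = Path(case_dir)
    with open(case_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    n = manifest["n_frames"]
    frames = np.stack(
        [np.asarray(Image.open(case_dir / "frames" / f"{t:04d}.png")) for t in range(n)]
    ).astype(np.uint8)
    masks = np.stack(
        [np.asarray(Image.open(case_dir / "masks" / f"{t:04d}.png")) for t in range(n)]
    ).astype(np.int8)
    with open(case_dir / "phases.csv") as fh:
        rows = list(csv.DictReader(fh))
    labels = np.array([row["label"] for row in sorted(rows, key=lambda r: int(r["frame_index"]))])
    cine = CineSequence(frames, case_id=manifest["case_id"], meta=manifest.get("meta", {}))
    w, h = manifest["image_size"]
    cfg = EchoPhantomConfig(
        image_size=(w, h),
        mvp_case=manifest["mvp_truth"],
        prolapse_amplitude=6.0 if manifest["mvp_truth"] else 0.0,
        prolapse_zone=manifest["severe_zone_truth"],
        seed=manifest["seed"],
    )
    return SyntheticCase(
        cine=cine,
        phase_labels=PhaseAnnotation(labels),
        masks=masks,
        mvp_truth=manifest["mvp_truth"],
        severe_zone_truth=manifest["severe_zone_truth"],
        config=cfg,
        split=manifest.get("split", "train"),
    )
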