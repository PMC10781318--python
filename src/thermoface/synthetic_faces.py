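"""Seeded synthetic thermal-face sessions for offline testing of the pipeline.

Emulates a shortened Trier-Social-Stress-Test acquisition: ``n_subjects``
participants, three states (baseline, stress, relax), ``frames_per_phase``
frames each — by default 25 x 3 x 4 = 300 frames of 240 x 320 pixels.

Each frame is a cooler uniform background with a warm elliptical face.  The
five ROI rectangles (placed from the frame's own ground-truth landmarks and
face box, using the production ROI geometry) are stamped with temperatures

    T[roi] = grand_mean[roi]
             + state_effect_scale * (mu[roi][state] - grand_mean[roi])
             + b[roi]  (subject random effect, shared z across ROIs/frames)
             + eps     (per-frame, per-ROI residual)

where b and eps split the total dispersion ``sd_total`` by
``subject_sd_fraction`` (b ~ N(0, sd_total * sqrt(f)), eps ~ N(0,
sd_total * sqrt(1 - f))).  Per-pixel Gaussian texture is added on top, and the
frame is quantised to gray levels with an auto-ranged temperature scale (the
hottest pixel sits exactly at the sidecar's t_max, so decoding is exact to
half a quantisation step).

Presets
-------
``table1``    state means and dispersions anchored to the published per-ROI
              per-state temperature table; for summary-statistic recovery.
``separable`` a strongly stress-responsive population (state effects x3,
              total dispersion at 1/3) used as the classifier-recovery
              surface; see the methods note for the calibration rationale.

The per-frame ground truth (stamped ROI temperatures before texture and
quantisation) is recorded in a feature table alongside the frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import roi_extraction
from .face_landmarks import FaceBox, LandmarkSet, write_landmarks
from .roi_extraction import ROI_NAMES, anchors_from_landmarks, extract_all, roi_region
from .thermal_codec import ThermalFrame, encode_frame, write_frame

__all__ = [
    "TABLE1_MU",
    "TABLE1_SD",
    "SD_TOTAL",
    "SynthConfig",
    "SyntheticSession",
    "table1_config",
    "separable_config",
    "canonical_landmark_template",
    "sample_subject",
    "render_frame",
    "generate_dataset",
    "extract_features",
]

STATES = ("baseline", "stress", "relax")

#: Published per-ROI mean skin temperature (degrees C) per state.
TABLE1_MU = {
    "nose": {"baseline": 33.50, "stress": 33.28, "relax": 33.30},
    "right_cheek": {"baseline": 35.09, "stress": 34.90, "relax": 35.00},
    "left_cheek": {"baseline": 34.48, "stress": 34.32, "relax": 33.81},
    "forehead": {"baseline": 35.60, "stress": 35.42, "relax": 35.57},
    "chin": {"baseline": 34.65, "stress": 34.68, "relax": 34.56},
}

#: Published per-ROI standard deviation (degrees C) per state.
TABLE1_SD = {
    "nose": {"baseline": 1.22, "stress": 1.31, "relax": 1.23},
    "right_cheek": {"baseline": 0.51, "stress": 0.61, "relax": 0.57},
    "left_cheek": {"baseline": 0.72, "stress": 0.73, "relax": 1.17},
    "forehead": {"baseline": 0.18, "stress": 0.76, "relax": 0.18},
    "chin": {"baseline": 0.44, "stress": 0.52, "relax": 0.33},
}

#: Total marginal dispersion per ROI: the published SDs averaged over states.
SD_TOTAL = {
    roi: float(np.mean([TABLE1_SD[roi][s] for s in STATES])) for roi in ROI_NAMES
}


@dataclass
class SynthConfig:
    n_subjects: int = 25
    frames_per_phase: int = 4
    image_shape: tuple[int, int] = (240, 320)  # (rows, cols)
    t_min: float = 18.0
    t_max: float = 40.0  # upper sanity bound for any simulated temperature
    preset: str = "table1"
    mu: dict = field(default_factory=lambda: {r: dict(TABLE1_MU[r]) for r in ROI_NAMES})
    sd_total: dict = field(default_factory=lambda: dict(SD_TOTAL))
    subject_sd_fraction: float = 0.5
    state_effect_scale: float = 1.0
    dispersion_scale: float = 1.0
    background_temp: float = 27.0
    face_base_temp: float = 33.0
    pixel_texture_sd: float = 0.1
    max_gray: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.subject_sd_fraction <= 1.0:
            raise ValueError("subject_sd_fraction must be in [0, 1]")
        if any(self.sd_total[r] < 0 for r in ROI_NAMES):
            raise ValueError("sd_total must be nonnegative")
        if self.pixel_texture_sd < 0 or self.dispersion_scale < 0:
            raise ValueError("noise scales must be nonnegative")
        for roi in ROI_NAMES:
            for st in STATES:
                if not self.t_min < self.mu[roi][st] < self.t_max:
                    raise ValueError(
                        f"mu[{roi}][{st}]={self.mu[roi][st]} outside "
                        f"({self.t_min}, {self.t_max})"
                    )

    @property
    def n_frames(self) -> int:
        return self.n_subjects * len(STATES) * self.frames_per_phase


def table1_config(seed: int = 0, **overrides) -> SynthConfig:
    """Population matched to the published per-ROI temperature table."""
    return SynthConfig(preset="table1", seed=seed, **overrides)


def separable_config(seed: int = 0, **overrides) -> SynthConfig:
    """Strongly separated states: effect x3, total dispersion at 1/3.

    This is the classifier-recovery surface; the scaling makes the three
    state clusters genuinely separable for a per-frame classifier (the
    table1 dispersions overlap too heavily for that — see methods note).
    """
    overrides.setdefault("state_effect_scale", 3.0)
    overrides.setdefault("subject_sd_fraction", 0.5)
    overrides.setdefault("dispersion_scale", 1.0 / 3.0)
    return SynthConfig(preset="separable", seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Canonical 68-point landmark template
# ---------------------------------------------------------------------------

def _template_normalized() -> np.ndarray:
    """The 68 points in face-box coordinates (x, y in [0, 1], y down)."""
    pts = np.zeros((68, 2))
    # jaw 1-17: lower-elliptical arc, chin bottom at point 9
    t = np.arange(17)
    phi = np.deg2rad((t - 8) / 8.0 * 110.0)
    pts[0:17, 0] = 0.5 + 0.47 * np.sin(phi)
    pts[0:17, 1] = 0.45 + 0.53 * np.cos(phi)
    # brows 18-27: two shallow arcs
    u = np.linspace(0, 1, 5)
    pts[17:22, 0] = 0.17 + 0.24 * u
    pts[17:22, 1] = 0.27 - 0.02 * np.sin(np.pi * u)
    pts[22:27, 0] = 0.59 + 0.24 * u
    pts[22:27, 1] = 0.27 - 0.02 * np.sin(np.pi * u)
    # nose bridge 28-31 (28 bridge top, 31 nose base)
    pts[27:31, 0] = 0.5
    pts[27:31, 1] = np.linspace(0.40, 0.54, 4)
    # nose bottom 32-36 (34 = nose tip, centre)
    pts[31:36, 0] = np.linspace(0.42, 0.58, 5)
    pts[31:36, 1] = [0.60, 0.615, 0.62, 0.615, 0.60]
    # eyes 37-42 / 43-48: hexagons
    hexagon = np.array(
        [(-0.06, 0), (-0.03, -0.025), (0.03, -0.025), (0.06, 0), (0.03, 0.025), (-0.03, 0.025)]
    )
    pts[36:42] = np.array([0.32, 0.36]) + hexagon
    pts[42:48] = np.array([0.68, 0.36]) + hexagon
    # mouth: outer 49-60, inner 61-68 (ellipses)
    th = np.deg2rad(180 - 30 * np.arange(12))
    pts[48:60, 0] = 0.5 + 0.13 * np.cos(th)
    pts[48:60, 1] = 0.79 - 0.055 * np.sin(th)
    th = np.deg2rad(180 - 45 * np.arange(8))
    pts[60:68, 0] = 0.5 + 0.08 * np.cos(th)
    pts[60:68, 1] = 0.79 - 0.025 * np.sin(th)
    return pts


_TEMPLATE = _template_normalized()


def canonical_landmark_template(box: FaceBox, image_shape=None) -> LandmarkSet:
    """Scale/translate the fixed 68-point layout into a face box."""
    if box.w < 32 or box.h < 32:
        raise ValueError(f"face box {box.w}x{box.h} too small (< 32 px a side)")
    points = _TEMPLATE * np.array([box.w, box.h]) + np.array([box.x, box.y])
    if image_shape is None:
        image_shape = (
            int(np.ceil(box.y + box.h)) + 1,
            int(np.ceil(box.x + box.w)) + 1,
        )
    return LandmarkSet(points=points, image_shape=tuple(image_shape))


# ---------------------------------------------------------------------------
# Sampling and rendering
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    participant_id: str
    effect: dict  # roi -> degrees C offset
    box: FaceBox


def sample_subject(config: SynthConfig, subject_index: int, rng) -> dict:
    """Subject random effect per ROI: one shared standard-normal draw z,
    scaled by each ROI's subject-level SD (sd_total * sqrt(fraction))."""
    z = rng.normal()
    f = config.subject_sd_fraction
    return {
        roi: config.dispersion_scale * config.sd_total[roi] * np.sqrt(f) * z
        for roi in ROI_NAMES
    }


def _default_box(config: SynthConfig, rng) -> FaceBox:
    rows, cols = config.image_shape
    w = int(round(0.50 * cols))
    h = int(round(0.75 * rows))
    jx, jy = rng.integers(-4, 5, size=2)
    return FaceBox(
        x=(cols - w) // 2 + int(jx),
        y=(rows - h) // 2 + int(jy),
        w=w,
        h=h,
    )


def render_frame(
    subject: Subject, state: str, config: SynthConfig, rng, frame_id: str = ""
) -> tuple[ThermalFrame, LandmarkSet, FaceBox, dict]:
    """Render one frame; returns (frame, landmarks, box, truth row)."""
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    rows, cols = config.image_shape
    box = subject.box
    lm = canonical_landmark_template(box, image_shape=config.image_shape)

    field_ = np.full((rows, cols), config.background_temp, dtype=float)
    yy, xx = np.mgrid[0:rows, 0:cols]
    cx, cy = box.x + box.w / 2.0, box.y + box.h / 2.0
    mask = ((xx - cx) / (box.w / 2.0)) ** 2 + ((yy - cy) / (box.h / 2.0)) ** 2 <= 1.0
    field_[mask] = config.face_base_temp

    anchors = anchors_from_landmarks(lm)
    grand = {roi: np.mean([config.mu[roi][s] for s in STATES]) for roi in ROI_NAMES}
    f = config.subject_sd_fraction
    truth = {"frame_id": frame_id, "participant_id": subject.participant_id, "phase": state}
    for roi in ROI_NAMES:
        eps = rng.normal() * config.dispersion_scale * config.sd_total[roi] * np.sqrt(1.0 - f)
        value = (
            grand[roi]
            + config.state_effect_scale * (config.mu[roi][state] - grand[roi])
            + subject.effect[roi]
            + eps
        )
        if not config.t_min < value < config.t_max:
            raise ValueError(
                f"stamped {roi} temperature {value:.2f} outside scale "
                f"({config.t_min}, {config.t_max}); widen the scale or shrink noise"
            )
        region = roi_region(roi, anchors, box, config.image_shape)
        field_[region.j_lo : region.j_hi + 1, region.i_lo : region.i_hi + 1] = value
        truth[roi] = float(value)

    if config.pixel_texture_sd > 0:
        field_ += rng.normal(0.0, config.pixel_texture_sd, size=field_.shape)

    # auto-ranged scale: hottest pixel maps to max_gray exactly, so the frame's
    # own maximum gray value equals the quantisation full scale and decoding is
    # exact to half a step
    t_max_frame = float(field_.max())
    if t_max_frame >= config.t_max:
        raise ValueError("simulated frame exceeds the configured temperature bound")
    frame = encode_frame(
        field_,
        t_min=config.t_min,
        t_max=t_max_frame,
        max_gray=config.max_gray,
        frame_id=frame_id,
        participant_id=subject.participant_id,
        phase=state,
    )
    return frame, lm, box, truth


@dataclass
class SyntheticSession:
    """Generated frames with their ground truth."""

    frames: list  # (ThermalFrame, LandmarkSet, FaceBox) triples
    truth: pd.DataFrame  # stamped ROI temperatures, one row per frame
    config: SynthConfig


def generate_dataset(config: SynthConfig | None = None, out_dir=None) -> SyntheticSession:
    """Generate the full session, optionally writing frames + sidecars to disk.

    Fully determined by ``config.seed``; iteration order is subject, then
    phase (baseline, stress, relax), then frame.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    frames, truth_rows = [], []
    for s in range(config.n_subjects):
        pid = f"p{s + 1:02d}"
        effect = sample_subject(config, s, rng)
        subject = Subject(participant_id=pid, effect=effect, box=_default_box(config, rng))
        for state in STATES:
            for k in range(config.frames_per_phase):
                fid = f"{pid}_{state}_{k + 1}"
                frame, lm, box, truth = render_frame(subject, state, config, rng, frame_id=fid)
                frames.append((frame, lm, box))
                truth_rows.append(truth)
    truth = pd.DataFrame(
        truth_rows, columns=["frame_id", "participant_id", "phase", *ROI_NAMES]
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for frame, lm, box in frames:
            img_path = out_dir / f"{frame.frame_id}.png"
            write_frame(
                frame,
                img_path,
                extra_meta={"face_box": [box.x, box.y, box.w, box.h]},
            )
            write_landmarks(lm, out_dir / f"{frame.frame_id}_landmarks.csv")
            manifest.append(
                {
                    "frame_id": frame.frame_id,
                    "participant_id": frame.participant_id,
                    "phase": frame.phase,
                    "image": img_path.name,
                }
            )
        pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
        truth.to_csv(out_dir / "truth.csv", index=False)

    return SyntheticSession(frames=frames, truth=truth, config=config)


def extract_features(session: SyntheticSession) -> pd.DataFrame:
    """Run the production ROI extraction over every generated frame."""
    pairs = [
        (frame, extract_all(frame, lm, box)) for frame, lm, box in session.frames
    ]
    return roi_extraction.feature_table(pairs)
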