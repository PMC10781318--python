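"""Landmark-anchored facial ROI geometry and mean-temperature extraction.

Five rectangular regions of interest — nose, right cheek, left cheek,
forehead, chin — are placed relative to four landmark anchors and scaled by
the detected face box (width ``w``, height ``h``).  With anchor ``(Sx, Sy)``
the inclusive column (``i``) and row (``j``) index ranges are:

    nose         i in [Sx - w/16, Sx + w/16],   j in [Sy - h/13, Sy]
    right cheek  i in [Sx - w/3,  Sx - w/5],    j in [Sy - h/14, Sy + h/14]
    left cheek   i in [Sx + w/5,  Sx + 12w/35], j in [Sy - h/14, Sy + h/14]
    forehead     i in [Sx - w/12, Sx + w/12],   j in [Sy - h/4,  Sy - h/9]
    chin         i in [Sx - w/12, Sx + w/12],   j in [Sy - h/8,  Sy]

Anchors: nose <- landmark 34, both cheeks <- landmark 31, forehead <- 28,
chin <- 9.  "Right cheek" is the region at the lower column indices (image
left), as the geometry is written; no anatomical mirroring is applied.  The
left-cheek outer bound 12w/35 is intentionally asymmetric with the right
cheek's w/3 and is implemented verbatim.

Fractional offsets round to the nearest integer, half away from zero.
Regions are clipped to the image and flagged when clipping occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .face_landmarks import FaceBox, LandmarkSet
from .thermal_codec import TemperatureMatrix, ThermalFrame, decode_frame

__all__ = [
    "ROI_NAMES",
    "ANCHOR_LANDMARKS",
    "RoiAnchors",
    "PixelRegion",
    "RoiTemperatures",
    "EmptyRegionError",
    "anchors_from_landmarks",
    "roi_region",
    "roi_mean_temperature",
    "extract_all",
    "feature_table",
    "write_feature_table",
    "read_feature_table",
]

ROI_NAMES = ("nose", "right_cheek", "left_cheek", "forehead", "chin")

#: 1-based landmark number anchoring each ROI.
ANCHOR_LANDMARKS = {
    "nose": 34,
    "right_cheek": 31,
    "left_cheek": 31,
    "forehead": 28,
    "chin": 9,
}

# (i_lo, i_hi, j_lo, j_hi) offsets as fractions of face (w, h) around the anchor
_REGION_FRACTIONS = {
    "nose": ((-1 / 16, "w"), (1 / 16, "w"), (-1 / 13, "h"), (0.0, "h")),
    "right_cheek": ((-1 / 3, "w"), (-1 / 5, "w"), (-1 / 14, "h"), (1 / 14, "h")),
    "left_cheek": ((1 / 5, "w"), (12 / 35, "w"), (-1 / 14, "h"), (1 / 14, "h")),
    "forehead": ((-1 / 12, "w"), (1 / 12, "w"), (-1 / 4, "h"), (-1 / 9, "h")),
    "chin": ((-1 / 12, "w"), (1 / 12, "w"), (-1 / 8, "h"), (0.0, "h")),
}


class EmptyRegionError(ValueError):
    """The ROI rectangle has no pixels inside the image."""


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class RoiAnchors:
    """Pixel anchor per ROI; both cheeks share landmark 31."""

    nose: tuple[float, float]
    right_cheek: tuple[float, float]
    left_cheek: tuple[float, float]
    forehead: tuple[float, float]
    chin: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.right_cheek) != tuple(self.left_cheek):
            raise ValueError("cheek anchors must coincide (both use landmark 31)")

    def __getitem__(self, roi: str) -> tuple[float, float]:
        return getattr(self, roi)


@dataclass
class PixelRegion:
    """Inclusive rectangular pixel index range (i = column, j = row)."""

    i_lo: int
    i_hi: int
    j_lo: int
    j_hi: int
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.i_lo > self.i_hi or self.j_lo > self.j_hi:
            raise EmptyRegionError(
                f"empty region i=[{self.i_lo},{self.i_hi}] j=[{self.j_lo},{self.j_hi}]"
            )

    @property
    def n_pixels(self) -> int:
        return (self.i_hi - self.i_lo + 1) * (self.j_hi - self.j_lo + 1)

    def pixel_indices(self):
        """All (i, j) pairs in the region — the brute-force enumeration."""
        return [
            (i, j)
            for i in range(self.i_lo, self.i_hi + 1)
            for j in range(self.j_lo, self.j_hi + 1)
        ]


@dataclass
class RoiTemperatures:
    """Mean temperature and pixel count per ROI for one frame."""

    frame_id: str
    mean_temp: dict = field(default_factory=dict)
    pixel_count: dict = field(default_factory=dict)
    incomplete: bool = False
    failures: dict = field(default_factory=dict)  # roi -> error message


def anchors_from_landmarks(lm: LandmarkSet) -> RoiAnchors:
    """Copy the four anchoring landmarks into per-ROI anchors."""
    return RoiAnchors(
        nose=lm.point(34),
        right_cheek=lm.point(31),
        left_cheek=lm.point(31),
        forehead=lm.point(28),
        chin=lm.point(9),
    )


def roi_region(
    roi: str,
    anchors: RoiAnchors,
    box: FaceBox,
    image_shape: tuple[int, int],
) -> PixelRegion:
    """Compute the inclusive pixel range of one ROI, clipped to the image."""
    if roi not in ROI_NAMES:
        raise ValueError(f"unknown ROI {roi!r}")
    ax, ay = anchors[roi]
    ax_i, ay_j = _round_half_away(ax), _round_half_away(ay)
    (f_ilo, _), (f_ihi, _), (f_jlo, _), (f_jhi, _) = _REGION_FRACTIONS[roi]
    i_lo = ax_i + _round_half_away(f_ilo * box.w)
    i_hi = ax_i + _round_half_away(f_ihi * box.w)
    j_lo = ay_j + _round_half_away(f_jlo * box.h)
    j_hi = ay_j + _round_half_away(f_jhi * box.h)

    rows, cols = image_shape
    ci_lo, ci_hi = max(i_lo, 0), min(i_hi, cols - 1)
    cj_lo, cj_hi = max(j_lo, 0), min(j_hi, rows - 1)
    if ci_lo > ci_hi or cj_lo > cj_hi:
        raise EmptyRegionError(f"{roi} region entirely outside the image")
    clipped = (ci_lo, ci_hi, cj_lo, cj_hi) != (i_lo, i_hi, j_lo, j_hi)
    return PixelRegion(i_lo=ci_lo, i_hi=ci_hi, j_lo=cj_lo, j_hi=cj_hi, clipped=clipped)


def roi_mean_temperature(
    temps: TemperatureMatrix, region: PixelRegion
) -> tuple[float, int]:
    """Arithmetic mean over the inclusive rectangle, and its pixel count."""
    values = temps.values if isinstance(temps, TemperatureMatrix) else np.asarray(temps)
    rows, cols = values.shape
    if region.i_hi >= cols or region.j_hi >= rows:
        raise ValueError("region exceeds matrix bounds")
    block = values[region.j_lo : region.j_hi + 1, region.i_lo : region.i_hi + 1]
    if block.size == 0:
        raise EmptyRegionError("empty region")
    return float(block.mean()), int(block.size)


def extract_all(
    frame: ThermalFrame, lm: LandmarkSet, box: FaceBox
) -> RoiTemperatures:
    """Decode the frame once and extract the five ROI mean temperatures.

    A failed ROI (e.g. clipped away entirely) is recorded in ``failures`` and
    marks the result incomplete; the remaining ROIs are still extracted.
    """
    temps = decode_frame(frame)
    anchors = anchors_from_landmarks(lm)
    result = RoiTemperatures(frame_id=frame.frame_id)
    for roi in ROI_NAMES:
        try:
            region = roi_region(roi, anchors, box, frame.shape)
            mean, count = roi_mean_temperature(temps, region)
        except (EmptyRegionError, ValueError) as exc:
            result.failures[roi] = str(exc)
            result.incomplete = True
            continue
        result.mean_temp[roi] = mean
        result.pixel_count[roi] = count
    return result


# ---------------------------------------------------------------------------
# Feature table: one row per frame, five ROI means in degrees C
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ("participant_id", "frame_id", "phase", *ROI_NAMES)


def feature_table(frames_with_results) -> pd.DataFrame:
    """Assemble (frame, RoiTemperatures) pairs into a feature table.

    Incomplete frames are dropped: the classifier contract requires all five
    ROI means.
    """
    rows = []
    for frame, res in frames_with_results:
        if res.incomplete:
            continue
        row = {
            "participant_id": frame.participant_id,
            "frame_id": frame.frame_id,
            "phase": frame.phase,
        }
        row.update({roi: res.mean_temp[roi] for roi in ROI_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write the feature CSV with 2-decimal temperature formatting."""
    df.to_csv(path, index=False, float_format="%.2f")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    return df
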