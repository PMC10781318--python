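"""68-point facial landmark sets and face boxes for thermal frames.

Landmarks follow the standard 68-point annotation scheme (1-based numbering at
the interface): jaw 1-17, brows 18-27, nose bridge 28-31, nose base 32-36,
eyes 37-48, mouth 49-68.  Four of them anchor the thermal regions of interest:
9 (chin bottom), 28 (nose bridge), 31 (nose base) and 34 (nose tip).

Internally coordinates are 0-based pixels, x = column rightward, y = row
downward.  Landmark providers sit behind a single ``detect`` contract:

* :class:`GroundTruthProvider` reads per-frame landmark CSVs and face boxes
  written next to the frames (the test/reference path).
* :class:`ThermalContrastDetector` locates the face as the largest warm
  connected component and fits the canonical landmark template into its
  bounding box — adequate for frontal faces against a cooler background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .thermal_codec import FormatError, ThermalFrame, decode_frame, sidecar_path_for

__all__ = [
    "LandmarkSet",
    "FaceBox",
    "DetectionError",
    "LandmarkProvider",
    "GroundTruthProvider",
    "ThermalContrastDetector",
    "read_landmarks",
    "write_landmarks",
    "box_from_landmarks",
    "get_provider",
]


class DetectionError(RuntimeError):
    """No usable face/landmarks could be produced for a frame."""


@dataclass
class LandmarkSet:
    """Ordered 68 facial points in pixel coordinates.

    ``point(n)`` uses the 1-based numbering of the annotation scheme, so
    ``point(34)`` is the nose tip.
    """

    points: np.ndarray  # (68, 2) float, columns (x, y)
    image_shape: tuple[int, int]  # (rows, cols)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (68, 2):
            raise ValueError(f"expected 68 (x, y) points, got shape {self.points.shape}")
        rows, cols = self.image_shape
        x, y = self.points[:, 0], self.points[:, 1]
        if np.any(x < 0) or np.any(x > cols - 1) or np.any(y < 0) or np.any(y > rows - 1):
            raise ValueError("landmark outside image bounds")

    def point(self, number: int) -> tuple[float, float]:
        """Return landmark ``number`` (1-based, 1..68) as (x, y)."""
        if not 1 <= number <= 68:
            raise ValueError(f"landmark number must be in 1..68, got {number}")
        return tuple(self.points[number - 1])

    def translated(self, dx: float, dy: float, image_shape=None) -> "LandmarkSet":
        return LandmarkSet(
            points=self.points + np.array([dx, dy]),
            image_shape=image_shape or self.image_shape,
        )


@dataclass
class FaceBox:
    """Detected-face rectangle; ``w``/``h`` scale the ROI geometry."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"face box must have positive size, got w={self.w} h={self.h}")


def box_from_landmarks(lm: LandmarkSet) -> FaceBox:
    """Fallback face box from landmark extremes.

    ROI geometry scales with the *detected* face box, which a detector pads
    differently from the landmark hull — use only when no box is available.
    """
    x0, y0 = lm.points.min(axis=0)
    x1, y1 = lm.points.max(axis=0)
    return FaceBox(x=float(x0), y=float(y0), w=float(x1 - x0), h=float(y1 - y0))


# ---------------------------------------------------------------------------
# Landmark CSV I/O (columns: index, x, y; 1-based index 1..68)
# ---------------------------------------------------------------------------

def read_landmarks(path, image_shape) -> LandmarkSet:
    df = pd.read_csv(path)
    for col in ("index", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) != 68:
        raise FormatError(f"{path}: expected 68 rows, got {len(df)}")
    idx = df["index"].to_numpy()
    if sorted(idx.tolist()) != list(range(1, 69)):
        raise FormatError(f"{path}: indices must be a permutation of 1..68")
    df = df.sort_values("index")
    points = df[["x", "y"]].to_numpy(dtype=float)
    return LandmarkSet(points=points, image_shape=tuple(image_shape))


def write_landmarks(lm: LandmarkSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {"index": np.arange(1, 69), "x": lm.points[:, 0], "y": lm.points[:, 1]}
    )
    df.to_csv(path, index=False)


def landmark_path_for(frame_path) -> Path:
    frame_path = Path(frame_path)
    return frame_path.with_name(frame_path.stem + "_landmarks.csv")


# ---------------------------------------------------------------------------
# Providers
# ---------------------------------------------------------------------------

class LandmarkProvider:
    """Contract: ``detect(frame) -> (LandmarkSet, FaceBox)`` or DetectionError."""

    def detect(self, frame: ThermalFrame) -> tuple[LandmarkSet, FaceBox]:
        raise NotImplementedError


class GroundTruthProvider(LandmarkProvider):
    """Serve landmarks/boxes recorded next to the frames on disk.

    Expects, for frame id ``f``: ``<root>/f_landmarks.csv`` and a ``face_box``
    entry ``[x, y, w, h]`` in the frame sidecar ``<root>/f.json``.
    """

    def __init__(self, root) -> None:
        self.root = Path(root)

    def detect(self, frame: ThermalFrame) -> tuple[LandmarkSet, FaceBox]:
        lm_path = self.root / f"{frame.frame_id}_landmarks.csv"
        sidecar = self.root / f"{frame.frame_id}.json"
        if not lm_path.exists() or not sidecar.exists():
            raise DetectionError(f"no ground-truth landmarks for frame {frame.frame_id!r}")
        lm = read_landmarks(lm_path, frame.shape)
        meta = json.loads(sidecar.read_text())
        if "face_box" not in meta:
            raise DetectionError(f"sidecar {sidecar} has no face_box")
        x, y, w, h = meta["face_box"]
        return lm, FaceBox(x=x, y=y, w=w, h=h)


class ThermalContrastDetector(LandmarkProvider):
    """Detect the face as the largest warm blob and fit the landmark template.

    Thresholds the decoded temperature field at the midpoint between the
    coolest and warmest pixel (skin is several degrees warmer than the room),
    takes the largest connected component's bounding box as the face box, and
    instantiates the canonical 68-point template inside it.
    """

    #: Minimum face-box side in pixels for a credible detection.
    min_side = 32

    def detect(self, frame: ThermalFrame) -> tuple[LandmarkSet, FaceBox]:
        temps = decode_frame(frame).values
        thresh = 0.5 * (temps.min() + temps.max())
        mask = temps > thresh
        labels, n = ndimage.label(mask)
        if n == 0:
            raise DetectionError(f"no warm region in frame {frame.frame_id!r}")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        largest = int(np.argmax(sizes)) + 1
        ys, xs = np.nonzero(labels == largest)
        x0, x1 = xs.min(), xs.max()
        y0, y1 = ys.min(), ys.max()
        w, h = x1 - x0 + 1, y1 - y0 + 1
        if w < self.min_side or h < self.min_side:
            raise DetectionError(
                f"warm region {w}x{h} too small for a face in frame {frame.frame_id!r}"
            )
        box = FaceBox(x=float(x0), y=float(y0), w=float(w), h=float(h))
        from .synthetic_faces import canonical_landmark_template

        lm = canonical_landmark_template(box, image_shape=frame.shape)
        return lm, box


def get_provider(name: str, **kwargs) -> LandmarkProvider:
    """Provider factory used by config/CLI (``ground_truth`` | ``thermal_contrast``)."""
    if name == "ground_truth":
        return GroundTruthProvider(**kwargs)
    if name == "thermal_contrast":
        return ThermalContrastDetector()
    raise ValueError(f"unknown landmark provider {name!r}")
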