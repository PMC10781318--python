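"""Conversion between stored grayscale thermograms and physical temperature.

A radiometric thermal camera export is a single-channel image whose pixel
intensities are proportional to surface temperature over a known scale
``[t_min, t_max]`` (degrees Celsius).  The decode rule is

    T(i, j) = t_min + gray(i, j) / t_mgv * (t_max - t_min)

where ``t_mgv`` is the largest gray value found anywhere in the frame, so the
hottest pixel maps exactly to ``t_max``.  This per-frame normalisation matches
auto-ranged exports; a ``full_scale`` mode is available for cameras that emit
fixed full-depth maps (``t_mgv`` = bit-depth maximum).

Frames travel as an image file (8-bit PNG, 8/16-bit TIFF) plus a JSON sidecar
carrying the temperature scale and acquisition metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "PHASES",
    "ThermalFrame",
    "TemperatureMatrix",
    "InvalidFrameError",
    "FormatError",
    "decode_pixel",
    "decode_frame",
    "encode_frame",
    "read_frame",
    "write_frame",
    "sidecar_path_for",
]

#: Protocol phases a frame may be tagged with.
PHASES = ("baseline", "stress", "relax", "acclimatization", "unknown")

#: Default temperature scale assigned to frames created without an explicit one.
DEFAULT_T_MIN = 18.0
DEFAULT_T_MAX = 40.0


class InvalidFrameError(ValueError):
    """The frame violates a codec precondition (e.g. all-zero pixels)."""


class FormatError(ValueError):
    """A file or sidecar does not match the expected on-disk format."""


def _round_half_away(x):
    """Round half away from zero (NumPy's ``round`` rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class ThermalFrame:
    """A grayscale thermogram with its temperature scale and metadata.

    ``t_mgv`` (maximum gray value) is derived from the pixels by default;
    set ``mgv_mode='full_scale'`` with ``bit_depth`` to pin it to the
    bit-depth maximum instead.
    """

    pixels: np.ndarray
    t_min: float = DEFAULT_T_MIN
    t_max: float = DEFAULT_T_MAX
    frame_id: str = ""
    participant_id: str = ""
    phase: str = "unknown"
    mgv_mode: str = "frame"  # 'frame' | 'full_scale'
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InvalidFrameError(
                f"pixels must be a 2-D single-channel matrix, got ndim={self.pixels.ndim}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise InvalidFrameError("pixel matrix must have an integer dtype")
        if self.pixels.size == 0:
            raise InvalidFrameError("empty pixel matrix")
        if self.pixels.min() < 0:
            raise InvalidFrameError("negative gray values")
        if self.pixels.max() > 2**self.bit_depth - 1:
            raise InvalidFrameError(
                f"gray values exceed {self.bit_depth}-bit range"
            )
        if not self.t_min < self.t_max:
            raise InvalidFrameError(f"t_min={self.t_min} must be < t_max={self.t_max}")
        if self.phase not in PHASES:
            raise InvalidFrameError(f"unknown phase {self.phase!r}")
        if self.mgv_mode not in ("frame", "full_scale"):
            raise InvalidFrameError(f"unknown mgv_mode {self.mgv_mode!r}")
        if int(self.pixels.max()) == 0:
            raise InvalidFrameError("all-zero frame: t_mgv would be 0")

    @property
    def t_mgv(self) -> int:
        if self.mgv_mode == "full_scale":
            return 2**self.bit_depth - 1
        return int(self.pixels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TemperatureMatrix:
    """Per-pixel temperatures (degrees C), same shape as the source frame."""

    values: np.ndarray
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def decode_pixel(gray, t_min: float, t_max: float, t_mgv: int):
    """Decode one gray value (or array of them) to a temperature in Celsius.

    Raises :class:`InvalidFrameError` when ``t_mgv < 1`` and ``ValueError``
    when a gray value falls outside ``[0, t_mgv]``.
    """
    if t_mgv < 1:
        raise InvalidFrameError(f"t_mgv must be >= 1, got {t_mgv}")
    if not t_min < t_max:
        raise InvalidFrameError(f"t_min={t_min} must be < t_max={t_max}")
    g = np.asarray(gray, dtype=float)
    if np.any(g < 0) or np.any(g > t_mgv):
        raise ValueError(f"gray value outside [0, {t_mgv}]")
    out = t_min + g / float(t_mgv) * (t_max - t_min)
    return float(out) if np.isscalar(gray) else out


def decode_frame(frame: ThermalFrame) -> TemperatureMatrix:
    """Decode every pixel of a frame with the frame's own ``t_mgv``."""
    values = decode_pixel(frame.pixels, frame.t_min, frame.t_max, frame.t_mgv)
    return TemperatureMatrix(values=values, t_min=frame.t_min, t_max=frame.t_max)


def encode_frame(
    values,
    t_min: float,
    t_max: float,
    max_gray: int = 255,
    **frame_kwargs,
) -> ThermalFrame:
    """Quantise a temperature matrix onto ``[0, max_gray]`` gray levels.

    gray = round((T - t_min) / (t_max - t_min) * max_gray), rounding half away
    from zero.  The emitted frame's ``t_mgv`` is recomputed from its pixels
    (nothing guarantees a pixel attains ``max_gray``); the decode/encode round
    trip is within half a quantisation step exactly when one does.
    """
    if isinstance(values, TemperatureMatrix):
        values = values.values
    values = np.asarray(values, dtype=float)
    if max_gray < 1:
        raise ValueError(f"max_gray must be >= 1, got {max_gray}")
    if not t_min < t_max:
        raise InvalidFrameError(f"t_min={t_min} must be < t_max={t_max}")
    if np.any(values < t_min) or np.any(values > t_max):
        raise ValueError(f"temperature outside [{t_min}, {t_max}]")
    gray = _round_half_away((values - t_min) / (t_max - t_min) * max_gray)
    dtype = np.uint8 if max_gray <= 255 else np.uint16
    bit_depth = 8 if max_gray <= 255 else 16
    return ThermalFrame(
        pixels=gray.astype(dtype),
        t_min=t_min,
        t_max=t_max,
        bit_depth=bit_depth,
        **frame_kwargs,
    )


# ---------------------------------------------------------------------------
# Frame I/O: image file + JSON sidecar
# ---------------------------------------------------------------------------

_REQUIRED_SIDECAR_KEYS = ("t_min", "t_max")


def sidecar_path_for(path) -> Path:
    """Default sidecar location: the image path with a .json suffix."""
    return Path(path).with_suffix(".json")


def read_frame(path, sidecar_path=None) -> ThermalFrame:
    """Read an image + JSON sidecar into a :class:`ThermalFrame`.

    Accepts 8-bit PNG and 8/16-bit TIFF.  Multi-channel images and sidecars
    missing ``t_min``/``t_max`` raise :class:`FormatError`.
    """
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else sidecar_path_for(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in _REQUIRED_SIDECAR_KEYS:
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path} missing key {key!r}")

    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        with Image.open(path) as img:
            pixels = np.asarray(img)
    if pixels.ndim != 2:
        raise FormatError(f"{path} is not single-channel (shape {pixels.shape})")
    bit_depth = 16 if pixels.dtype.itemsize > 1 else 8
    return ThermalFrame(
        pixels=pixels,
        t_min=float(meta["t_min"]),
        t_max=float(meta["t_max"]),
        frame_id=str(meta.get("frame_id", path.stem)),
        participant_id=str(meta.get("participant_id", "")),
        phase=str(meta.get("phase", "unknown")),
        bit_depth=bit_depth,
    )


def write_frame(frame: ThermalFrame, path, sidecar_path=None, extra_meta=None) -> None:
    """Write a frame to PNG/TIFF plus its JSON sidecar (lossless round trip)."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else sidecar_path_for(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    pixels = frame.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        if pixels.max() > 255:
            raise FormatError("PNG output supports 8-bit frames only; use TIFF")
        Image.fromarray(pixels.astype(np.uint8), mode="L").save(path)

    meta = {
        "t_min": frame.t_min,
        "t_max": frame.t_max,
        "frame_id": frame.frame_id,
        "participant_id": frame.participant_id,
        "phase": frame.phase,
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
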