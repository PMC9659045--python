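"""Calibrated image-sequence I/O, tabular result output, and run configuration.

The pipeline consumes a :class:`ImageSequence`: a T x H x W (x C) stack of
frames plus the two calibration constants every physical quantity depends
on, the pixel size (um/pixel) and the frame interval (s). Calibration is
never guessed from file metadata; it must be supplied explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageSequence",
    "RunConfig",
    "read_sequence",
    "translate_frame",
    "write_sequence",
    "write_results",
]

#: column order of every result CSV written by the package
RESULT_COLUMNS = ["timepoint", "vessel_id", "quantity", "value", "units"]


@dataclass
class ImageSequence:
    """A calibrated video: frames indexed [t, y, x] or [t, y, x, channel].

    Integer frames keep their native 8/16-bit intensities; float frames
    are expected in [0, 1] (used for derived videos such as the RPCA
    sparse component).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim not in (3, 4):
            raise ValueError("frames must be (T,H,W) or (T,H,W,C)")
        if f.ndim == 4 and f.shape[-1] not in (1, 3):
            raise ValueError("channel axis must have size 1 or 3")
        if f.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not (self.pixel_size_um > 0 and self.frame_interval_s > 0):
            raise ValueError("calibration (pixel size, frame interval) must be positive")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:3]

    @property
    def bit_depth(self) -> int | None:
        if self.frames.dtype == np.uint8:
            return 8
        if self.frames.dtype == np.uint16:
            return 16
        return None

    def as_float(self) -> np.ndarray:
        """Frames as float64 scaled to [0, 1] (no-op for float input)."""
        f = self.frames
        if f.dtype == np.uint8:
            return f.astype(np.float64) / 255.0
        if f.dtype == np.uint16:
            return f.astype(np.float64) / 65535.0
        return f.astype(np.float64)

    def green(self) -> np.ndarray:
        """Green channel as float [0, 1] (identity for grayscale).

        Green carries the strongest vessel contrast: hemoglobin absorbs
        green light, so vessels appear dark against tissue.
        """
        f = self.as_float()
        if f.ndim == 4:
            return f[..., 1] if f.shape[-1] == 3 else f[..., 0]
        return f


def translate_frame(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer-pixel translation with edge replication."""
    if dy == 0 and dx == 0:
        return img
    h, w = img.shape[:2]
    pad = [(max(dy, 0), max(-dy, 0)), (max(dx, 0), max(-dx, 0))]
    pad += [(0, 0)] * (img.ndim - 2)
    out = np.pad(img, pad, mode="edge")
    return out[max(-dy, 0):max(-dy, 0) + h, max(-dx, 0):max(-dx, 0) + w]


def read_sequence(path, pixel_size_um: float | None = None,
                  frame_interval_s: float | None = None) -> ImageSequence:
    """Read a TIFF stack or a directory of numbered PNG/TIFF frames.

    Calibration is mandatory: there is no safe default for the pixel
    size or frame interval of an arbitrary file.
    """
    if pixel_size_um is None or frame_interval_s is None:
        raise ValueError("pixel_size_um and frame_interval_s are required; "
                         "no silent calibration default")
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames under {path}")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        stack = tifffile.imread(str(path))
        if stack.ndim == 2 or (stack.ndim == 3 and stack.shape[-1] in (1, 3)
                               and stack.shape[0] not in (1, 3)):
            # single frame (H,W) or (H,W,C)
            stack = stack[None]
    return ImageSequence(stack, pixel_size_um=pixel_size_um,
                         frame_interval_s=frame_interval_s)


def write_sequence(seq: ImageSequence, path) -> None:
    """Write frames as a multi-page TIFF (lossless for 8/16-bit data)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), seq.frames)


def write_results(records, path, config: "RunConfig | None" = None) -> None:
    """Write measurement records as a CSV with a stable column order.

    Each record carries (timepoint, vessel_id, quantity, value, units).
    If a config is given, a JSON sidecar ``<path>.json`` echoes it for
    provenance.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(list(records), columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"config": config.to_dict()}, indent=2))


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid config: {msg}")


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run.

    Unknown keys are rejected so that a typo never silently falls back
    to a default.
    """

    pixel_size_um: float
    frame_interval_s: float
    # registration
    search_radius_px: int = 5
    template_box: tuple | None = None  # (y, x, h, w); None = full frame
    # segmentation
    vesselness_scales_px: tuple = (2.0, 3.0, 5.0, 8.0, 12.0, 18.0, 26.0, 36.0)
    segment_threshold: float = 0.28
    min_object_px: int = 64
    # RPCA
    rpca_lambda: float | None = None  # None -> 1/sqrt(max(m, n))
    rpca_tol: float = 1e-7
    rpca_max_iter: int = 500
    rpca_window: int = 150
    # kymograph / velocity
    kymo_n_frames: int = 150
    angle_step_deg: float = 0.25
    min_diameter_um: float = 20.0
    max_diameter_um: float = 100.0
    # diameter
    normal_interval_px: int = 10
    profile_half_length_px: int = 40
    # statistics
    alpha: float = 0.1

    def __post_init__(self) -> None:
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(self.frame_interval_s > 0, "frame_interval_s must be > 0")
        _require(self.search_radius_px >= 0, "search_radius_px must be >= 0")
        self.vesselness_scales_px = tuple(float(s)
                                          for s in self.vesselness_scales_px)
        _require(len(self.vesselness_scales_px) > 0
                 and all(s > 0 for s in self.vesselness_scales_px),
                 "vesselness scales must be positive")
        _require(0 < self.segment_threshold < 1, "segment_threshold in (0,1)")
        _require(self.min_object_px >= 0, "min_object_px must be >= 0")
        _require(self.rpca_lambda is None or self.rpca_lambda > 0,
                 "rpca_lambda must be positive or null")
        _require(self.rpca_tol > 0, "rpca_tol must be > 0")
        _require(self.rpca_max_iter >= 1, "rpca_max_iter must be >= 1")
        _require(self.rpca_window >= 2, "rpca_window must be >= 2")
        _require(self.kymo_n_frames >= 8, "kymo_n_frames must be >= 8")
        _require(self.angle_step_deg > 0, "angle_step_deg must be > 0")
        _require(0 < self.min_diameter_um < self.max_diameter_um,
                 "diameter band must satisfy 0 < min < max")
        _require(self.normal_interval_px >= 1, "normal_interval_px must be >= 1")
        _require(self.profile_half_length_px >= 2,
                 "profile_half_length_px must be >= 2")
        _require(0 < self.alpha < 1, "alpha in (0,1)")
        if self.template_box is not None:
            box = tuple(int(v) for v in self.template_box)
            _require(len(box) == 4 and box[2] > 0 and box[3] > 0,
                     "template_box must be (y, x, h, w) with h, w > 0")
            self.template_box = box

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"invalid config: unknown keys {sorted(unknown)}")
        missing = {"pixel_size_um", "frame_interval_s"} - set(d)
        if missing:
            raise ValueError(f"invalid config: missing required keys {sorted(missing)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("invalid config: YAML root must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vesselness_scales_px"] = list(self.vesselness_scales_px)
        if self.template_box is not None:
            d["template_box"] = list(self.template_box)
        return d
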