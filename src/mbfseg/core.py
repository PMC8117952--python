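"""Shared domain types for the perfusion segmentation pipeline.

All images are 2D numpy arrays indexed (row, col) with the origin at the
top-left pixel centre; dynamic series are (time, row, col).  Millimetre
distances are obtained component-wise from ``pixel_spacing_mm``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from . import geometry
from .errors import MbfsegError


class SliceLocation(str, Enum):
    BASE = "base"
    MID = "mid"
    APEX = "apex"


class Condition(str, Enum):
    REST = "rest"
    STRESS = "stress"


@dataclass
class PerfusionSeries:
    """One slice location's dynamic first-pass image stack."""

    slice_location: SliceLocation
    frames: np.ndarray                      # (time, row, col), arbitrary units
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    frame_times_s: Optional[np.ndarray] = None
    condition: Condition = Condition.REST

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise MbfsegError("frames must be (time, row, col)")
        if self.frames.shape[0] < 10:
            raise MbfsegError("perfusion series needs >= 10 time points")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise MbfsegError("pixel spacing must be positive")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.frames.shape[0], dtype=float)
        else:
            self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
            if len(self.frame_times_s) != self.frames.shape[0]:
                raise MbfsegError("one frame time per frame required")
            if np.any(np.diff(self.frame_times_s) <= 0):
                raise MbfsegError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class MBFMap:
    """One slice's quantitative myocardial-blood-flow map (ml/g/min)."""

    values: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    slice_location: SliceLocation = SliceLocation.BASE
    condition: Condition = Condition.REST

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MbfsegError("MBF map must be 2D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise MbfsegError("MBF values must be finite and >= 0")


@dataclass
class VentricleMasks:
    """Detected LV (and optionally RV) blood pools on one slice."""

    lv_mask: np.ndarray
    rv_mask: Optional[np.ndarray] = None
    lv_center: tuple[float, float] = (0.0, 0.0)
    peak_lv_frame: int = 0

    def __post_init__(self):
        self.lv_mask = np.asarray(self.lv_mask, dtype=bool)
        if not self.lv_mask.any():
            raise MbfsegError("LV mask is empty")
        if self.rv_mask is not None:
            self.rv_mask = np.asarray(self.rv_mask, dtype=bool)
            if (self.lv_mask & self.rv_mask).any():
                raise MbfsegError("LV and RV masks overlap")
        if self.lv_center == (0.0, 0.0):
            r, c = np.nonzero(self.lv_mask)
            self.lv_center = (float(r.mean()), float(c.mean()))


@dataclass
class InsertionLandmark:
    """LV centre and anterior RV insertion angle defining the sector frame."""

    lv_center: tuple[float, float]
    rv_insertion_angle_deg: float

    def __post_init__(self):
        self.rv_insertion_angle_deg = geometry.normalize_angle_deg(
            self.rv_insertion_angle_deg)


@dataclass
class Contour:
    """Ordered closed polyline of continuous (row, col) pixel coordinates."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise MbfsegError("contour points must be (n, 2)")
        if len(self.points) < 8:
            raise MbfsegError("contour needs >= 8 points")

    def mask(self, shape) -> np.ndarray:
        return geometry.contour_mask(self.points, shape)

    @property
    def area(self) -> float:
        return geometry.polygon_area(self.points)

    def is_simple(self) -> bool:
        return geometry.is_simple(self.points)


@dataclass
class MyoSegmentation:
    """Paired endo/epicardial contours and the derived annular myo mask."""

    endo: Contour
    epi: Contour
    myo_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    image_shape: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.myo_mask is None:
            if self.image_shape is None:
                raise MbfsegError("image_shape required to derive myo_mask")
            self.myo_mask = (self.epi.mask(self.image_shape)
                             & ~self.endo.mask(self.image_shape))
        self.myo_mask = np.asarray(self.myo_mask, dtype=bool)
        if not self.myo_mask.any():
            raise MbfsegError("myocardial mask is empty")


@dataclass
class SectorModel:
    """Equal angular sectors anchored at the RV insertion angle."""

    origin: tuple[float, float]
    start_angle_deg: float
    n_sectors: int = 6
    direction: str = "ccw"          # "ccw" or "cw"

    def __post_init__(self):
        if self.n_sectors < 2:
            raise MbfsegError("need at least 2 sectors")
        if self.direction not in ("ccw", "cw"):
            raise MbfsegError("direction must be 'ccw' or 'cw'")
        self.start_angle_deg = geometry.normalize_angle_deg(self.start_angle_deg)

    @property
    def boundary_angles_deg(self) -> np.ndarray:
        step = 360.0 / self.n_sectors
        sign = 1.0 if self.direction == "ccw" else -1.0
        return np.mod(self.start_angle_deg
                      + sign * step * np.arange(self.n_sectors), 360.0)


@dataclass
class SectorReport:
    """Per-sector mean MBF for one slice and condition."""

    slice_location: SliceLocation
    condition: Condition
    n_sectors: int
    mean_mbf: np.ndarray            # nan where the sector is empty
    pixel_count: np.ndarray

    def __post_init__(self):
        self.mean_mbf = np.asarray(self.mean_mbf, dtype=float)
        self.pixel_count = np.asarray(self.pixel_count, dtype=int)
        if len(self.mean_mbf) != self.n_sectors:
            raise MbfsegError("one mean per sector required")
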