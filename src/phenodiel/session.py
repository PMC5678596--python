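"""Time-lapse session handling: loading, ordering and photoperiod partitioning.

A diel imaging experiment alternates visible-light RGB frames (light period,
``VIS``) with near-infrared grayscale frames (dark period, ``NIR``), captured at
a fixed interval (typically 20 min).  A :class:`DielSession` holds the ordered
frames together with the partition into light/dark periods implied by the
photoperiod schedule.

Conventions
-----------
* Raster coordinates are 0-based, row-major, origin top-left; ``x`` is the
  column index.
* Period intervals are half-open ``[lights_on, lights_off)``: a frame stamped
  exactly at lights-off is the first dark frame.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Frame",
    "PhotoperiodSchedule",
    "CalibrationSpec",
    "Period",
    "DielSession",
    "build_session",
    "load_session",
    "write_session",
    "write_masks",
    "read_mask",
    "write_traits",
    "read_traits",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = [
    "plant_id",
    "timestamp",
    "frame_index",
    "period_index",
    "period_kind",
    "pra_px",
    "pra_mm2",
    "missing",
]

#: default timestamp embedded in filenames, e.g. ``frame0007_20240301T124000_VIS.png``
DEFAULT_TS_REGEX = r"(\d{8}T\d{6})"
DEFAULT_TS_FORMAT = "%Y%m%dT%H%M%S"


class Modality(str, enum.Enum):
    VIS = "VIS"
    NIR = "NIR"


@dataclass(frozen=True)
class Frame:
    """One image of the tray: 8-bit pixels, absolute timestamp, modality."""

    pixels: np.ndarray
    timestamp: dt.datetime
    modality: Modality
    frame_index: int = -1

    def __post_init__(self) -> None:
        px = self.pixels
        if self.modality is Modality.VIS:
            if px.ndim != 3 or px.shape[2] != 3:
                raise ValueError("VIS frame must have 3 colour planes")
        else:
            if px.ndim != 2:
                raise ValueError("NIR frame must be single-channel")
        if px.dtype != np.uint8:
            raise ValueError("frame pixels must be 8-bit (uint8)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def luminance(self) -> np.ndarray:
        """Single-channel 8-bit view: Rec.601 luma for VIS, identity for NIR."""
        if self.modality is Modality.NIR:
            return self.pixels
        w = np.array([0.299, 0.587, 0.114])
        return np.clip(np.round(self.pixels @ w), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class PhotoperiodSchedule:
    """Daily lights-on / lights-off clock times (light + dark spans 24 h)."""

    lights_on: dt.time
    lights_off: dt.time

    def __post_init__(self) -> None:
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")

    @property
    def light_hours(self) -> float:
        delta = (_minutes(self.lights_off) - _minutes(self.lights_on)) % (24 * 60)
        return delta / 60.0

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.light_hours

    def is_light(self, t: dt.datetime) -> bool:
        """True iff ``t`` falls in the half-open light interval [on, off)."""
        m = t.hour * 60 + t.minute + t.second / 60.0
        on, off = _minutes(self.lights_on), _minutes(self.lights_off)
        if on < off:
            return on <= m < off
        return m >= on or m < off  # photoperiod wraps midnight


def _minutes(t: dt.time) -> float:
    return t.hour * 60 + t.minute + t.second / 60.0


@dataclass(frozen=True)
class CalibrationSpec:
    """Pixel-to-physical calibration: edge length of one pixel in mm."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be strictly positive")

    def px_to_mm2(self, area_px: float) -> float:
        return float(area_px) * self.mm_per_pixel**2


@dataclass(frozen=True)
class Period:
    """A maximal run of frames within one light or dark phase; [start, stop)."""

    index: int
    kind: str  # "light" | "dark"
    start: int
    stop: int

    @property
    def n_frames(self) -> int:
        return self.stop - self.start


@dataclass
class DielSession:
    frames: list[Frame]
    schedule: PhotoperiodSchedule
    periods: list[Period] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def period_frames(self, period: Period) -> list[Frame]:
        return self.frames[period.start : period.stop]

    def light_periods(self) -> list[Period]:
        return [p for p in self.periods if p.kind == "light"]

    def dark_periods(self) -> list[Period]:
        return [p for p in self.periods if p.kind == "dark"]

    def period_of(self, frame_index: int) -> Period:
        for p in self.periods:
            if p.start <= frame_index < p.stop:
                return p
        raise IndexError(f"frame {frame_index} not covered by any period")


def build_session(
    frames: Iterable[Frame], schedule: PhotoperiodSchedule
) -> DielSession:
    """Sort frames by timestamp, validate, and compute the period partition.

    Raises on duplicate timestamps or mixed raster dimensions.  Frame indices
    are (re)assigned to the sorted order, and each frame's modality is checked
    against the schedule (a VIS frame at a dark time is collapsed to luminance
    with a warning so that dark periods contain only NIR frames).
    """
    ordered = sorted(frames, key=lambda f: f.timestamp)
    if not ordered:
        raise ValueError("session contains no frames")
    stamps = [f.timestamp for f in ordered]
    if len(set(stamps)) != len(stamps):
        raise ValueError("duplicate frame timestamps in session")
    shape = ordered[0].shape
    fixed: list[Frame] = []
    for i, f in enumerate(ordered):
        if f.shape != shape:
            raise ValueError(
                f"mixed raster dimensions: {f.shape} vs {shape} at frame {i}"
            )
        light = schedule.is_light(f.timestamp)
        modality = Modality.VIS if light else Modality.NIR
        px = f.pixels
        if modality is Modality.NIR and f.modality is Modality.VIS:
            warnings.warn(
                f"RGB frame at dark time {f.timestamp}; converting to luminance"
            )
            px = f.luminance()
        elif modality is Modality.VIS and f.modality is Modality.NIR:
            # 1 plane forces NIR regardless of the schedule
            modality = Modality.NIR
        fixed.append(Frame(px, f.timestamp, modality, frame_index=i))

    periods: list[Period] = []
    start = 0
    for i in range(1, len(fixed) + 1):
        if i == len(fixed) or fixed[i].modality is not fixed[start].modality:
            kind = "light" if fixed[start].modality is Modality.VIS else "dark"
            periods.append(Period(len(periods), kind, start, i))
            start = i
    return DielSession(fixed, schedule, periods)


def _parse_timestamp(
    path: Path, ts_regex: str, ts_format: str
) -> tuple[dt.datetime, bool]:
    m = re.search(ts_regex, path.name)
    if m:
        try:
            return dt.datetime.strptime(m.group(1), ts_format), True
        except ValueError as exc:
            raise ValueError(
                f"unparseable timestamp {m.group(1)!r} in file {path.name}"
            ) from exc
    return dt.datetime.fromtimestamp(path.stat().st_mtime), False


def load_session(
    directory: str | Path,
    schedule: PhotoperiodSchedule,
    pattern: str = "*.png",
    ts_regex: str = DEFAULT_TS_REGEX,
    ts_format: str = DEFAULT_TS_FORMAT,
) -> DielSession:
    """Load every image matching ``pattern`` and partition by the schedule.

    Timestamps are parsed from filenames via ``ts_regex``/``ts_format``
    (ISO-8601 basic format by default); file modification time is the fallback,
    with a warning.  Modality is assigned from the schedule; single-channel
    files force NIR.
    """
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    paths = [p for p in paths if not p.stem.endswith("_mask")]
    if not paths:
        raise ValueError(f"no images matching {pattern!r} in {directory}")
    frames = []
    used_mtime = False
    for p in paths:
        stamp, from_name = _parse_timestamp(p, ts_regex, ts_format)
        used_mtime |= not from_name
        px = np.asarray(iio.imread(p))
        if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.dtype != np.uint8:
            raise ValueError(f"{p.name}: expected 8-bit image, got {px.dtype}")
        modality = Modality.NIR if px.ndim == 2 else Modality.VIS
        frames.append(Frame(px, stamp, modality))
    if used_mtime:
        warnings.warn(
            "one or more filenames had no parseable timestamp; "
            "file modification times were used"
        )
    return build_session(frames, schedule)


def frame_filename(frame: Frame) -> str:
    stamp = frame.timestamp.strftime(DEFAULT_TS_FORMAT)
    return f"frame{frame.frame_index:04d}_{stamp}_{frame.modality.value}.png"


def write_session(session: DielSession, out_dir: str | Path) -> list[Path]:
    """Write every frame as PNG with the canonical timestamped filename."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in session.frames:
        p = out_dir / frame_filename(f)
        iio.imwrite(p, f.pixels)
        paths.append(p)
    return paths


def write_masks(
    session: DielSession,
    masks: Sequence[np.ndarray],
    out_dir: str | Path,
) -> list[Path]:
    """Write one losslessly-compressed label PNG per frame (0 = background).

    Filenames mirror the source frames with a ``_mask`` suffix.
    """
    if len(masks) != len(session.frames):
        raise ValueError(
            f"expected {len(session.frames)} masks, got {len(masks)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame, mask in zip(session.frames, masks):
        arr = np.asarray(mask)
        if arr.shape != frame.shape:
            raise ValueError(
                f"mask shape {arr.shape} != frame shape {frame.shape} "
                f"at frame {frame.frame_index}"
            )
        if arr.max(initial=0) > 255 or arr.min(initial=0) < 0:
            raise ValueError("label values must fit in 8 bits")
        stem = frame_filename(frame).rsplit(".", 1)[0]
        p = out_dir / f"{stem}_mask.png"
        iio.imwrite(p, arr.astype(np.uint8))
        paths.append(p)
    return paths


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.int64)


def write_traits(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-plant per-frame trait table as CSV with stable columns."""
    if table.empty:
        raise ValueError("trait table is empty")
    missing = [c for c in TRAIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table lacks columns: {missing}")
    table[TRAIT_COLUMNS].to_csv(path, index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df
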