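"""Synthetic diel time-lapse scenes with exact ground truth.

Generates VIS/NIR image sessions of a tray of non-touching rosettes growing
exponentially, together with per-frame ground-truth label masks and areas, so
the whole segmentation/trait pipeline can be exercised without real imagery.

What is emulated
----------------
* rosettes as lobed star-polygons on a textured soil background;
* exponential growth of the projected area, ``A(t) = A0 * exp(r t)``;
* a transient projected-area dip after each dawn (leaf movement), modelled as
  a half-sine multiplicative reduction of the true area — the observable of
  leaf movement in top view is precisely a PRA change, so no 3-D pose is
  simulated;
* NIR frames with radial illumination falloff and additive Gaussian noise;
* per-pixel colour jitter on plants and soil in VIS frames.

Ground-truth pixel areas are the exact rasterised mask counts, so estimator
errors measured against them are pure segmentation error.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as skcolor
from skimage import draw

from .labeling import LabeledMask
from .session import (
    CalibrationSpec,
    DielSession,
    Frame,
    Modality,
    PhotoperiodSchedule,
    build_session,
)

__all__ = ["RosetteShape", "SceneSpec", "GroundTruth", "render_rosette",
           "generate_session"]

DEFAULT_SCHEDULE = PhotoperiodSchedule(dt.time(8, 0), dt.time(20, 0))
DEFAULT_START = dt.datetime(2024, 3, 1, 8, 0)


@dataclass(frozen=True)
class RosetteShape:
    """Star-polygon rosette outline: n_leaves lobes of relative depth
    ``lobedness``, rotated by ``phase``; optional per-vertex radial jitter."""

    n_leaves: int = 10
    lobedness: float = 0.35
    phase: float = 0.0
    vertex_jitter: float = 0.0

    def radius_profile(self, theta: np.ndarray, rng=None) -> np.ndarray:
        r = 1.0 + self.lobedness * np.cos(self.n_leaves * theta + self.phase)
        if rng is not None and self.vertex_jitter > 0:
            noise = rng.normal(0.0, self.vertex_jitter, theta.size)
            noise = ndimage.uniform_filter1d(noise, 9, mode="wrap")
            r = r * (1.0 + noise)
        return r


@dataclass(frozen=True)
class SceneSpec:
    """Study conditions for one generated session (defaults = WT-like tray).

    ``grid`` is (rows, cols); plants sit at cell centres and the scene is
    rejected if any rosette could touch a cell edge at its maximal simulated
    size.  All randomness flows from ``rng_seed``.
    """

    grid: tuple[int, int] = (3, 6)          # 18 plants, tray-style layout
    cell_px: int = 100
    mm_per_pixel: float = 0.25
    schedule: PhotoperiodSchedule = DEFAULT_SCHEDULE
    start: dt.datetime = DEFAULT_START
    interval_minutes: int = 20
    duration_hours: float = 24.0
    a0_mm2: tuple[float, float] = (40.0, 60.0)   # initial PRA range
    r_per_day: tuple[float, float] = (0.15, 0.25)
    leaf_count: tuple[int, int] = (8, 12)
    lobedness: tuple[float, float] = (0.25, 0.45)
    dip_amplitude: float = 0.10             # relative PRA dip after dawn
    dip_duration_h: float = 2.0
    plant_hsv: tuple[float, float, float] = (115.0, 0.70, 0.55)  # H deg, S, V
    plant_hsv_jitter: tuple[float, float, float] = (5.0, 0.05, 0.05)
    soil_rgb: tuple[float, float, float] = (120.0, 85.0, 60.0)
    soil_noise: float = 8.0                 # per-pixel sigma, grey levels
    soil_texture: float = 10.0              # low-frequency texture amplitude
    nir_soil: float = 90.0
    nir_plant: float = 180.0
    nir_noise: float = 4.0
    nir_falloff: float = 0.30               # radial falloff strength in [0,1)
    rng_seed: int = 0

    @property
    def n_plants(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def raster_shape(self) -> tuple[int, int]:
        return (self.grid[0] * self.cell_px, self.grid[1] * self.cell_px)

    @property
    def calibration(self) -> CalibrationSpec:
        return CalibrationSpec(self.mm_per_pixel)

    @property
    def n_frames(self) -> int:
        return int(self.duration_hours * 60 // self.interval_minutes)

    def validate(self) -> None:
        if not 0.0 <= self.dip_amplitude <= 0.5:
            raise ValueError("dip amplitude must be in [0, 0.5]")
        if not 0.0 <= self.nir_falloff < 1.0:
            raise ValueError("nir_falloff must be in [0, 1)")
        if self.interval_minutes <= 0 or self.duration_hours <= 0:
            raise ValueError("interval and duration must be positive")
        if self.n_frames < 1:
            raise ValueError("spec yields no frames")
        # worst-case rosette must fit its cell with headroom
        a_max_px = (
            self.a0_mm2[1]
            / self.mm_per_pixel**2
            * np.exp(self.r_per_day[1] * self.duration_hours / 24.0)
        )
        lob = self.lobedness[1]
        r_base = np.sqrt(a_max_px / (np.pi * (1 + lob**2 / 2)))
        if 2 * r_base * (1 + lob) * 1.1 >= self.cell_px:
            raise ValueError(
                "rosettes could touch at maximal simulated size; "
                "enlarge cell_px or reduce a0/r/duration"
            )

    # presets mirroring the study's genotype contrasts qualitatively
    @classmethod
    def wt_like(cls, **overrides) -> "SceneSpec":
        """Vigorous genotype: r = 0.20 day^-1, 10% dawn dip."""
        kw = dict(r_per_day=(0.20, 0.20), dip_amplitude=0.10)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def mutant_like(cls, **overrides) -> "SceneSpec":
        """Slow-growing genotype: r = 0.08 day^-1, no dawn dip."""
        kw = dict(r_per_day=(0.08, 0.08), dip_amplitude=0.0)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class GroundTruth:
    """Per-frame label masks and exact per-plant areas, plus the generating
    spec.  ``areas_px[frame_index, plant_id]`` equals the mask's pixel count
    for that plant exactly."""

    masks: list[LabeledMask]
    areas_px: pd.DataFrame     # index frame_index, columns plant_id
    areas_mm2: pd.DataFrame
    spec: SceneSpec

    def plant_ids(self) -> list[int]:
        return list(self.areas_px.columns)


def render_rosette(
    shape: RosetteShape,
    area_px: float,
    cell_px: int,
    rng: np.random.Generator | None = None,
    n_vertices: int = 256,
    tol: float = 0.01,
) -> np.ndarray:
    """Rasterise a rosette stamp whose pixel count is within ``tol`` of
    ``area_px`` (default 1%), by rescaling the outline against the realised
    count.  Deterministic for a given rng state; raises if the outline cannot
    fit the ``cell_px`` x ``cell_px`` stamp.
    """
    if area_px < 1:
        raise ValueError("target area must be >= 1 px")
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    profile = shape.radius_profile(theta, rng)
    # shoelace area of the unit-scale polygon -> first-guess scale factor
    x, y = profile * np.cos(theta), profile * np.sin(theta)
    poly_area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    scale = np.sqrt(area_px / poly_area)
    c = (cell_px - 1) / 2.0
    best = None
    for _ in range(12):
        if scale * profile.max() >= c:
            raise ValueError("target area exceeds the cell size")
        rr, cc = draw.polygon(c + scale * y, c + scale * x, (cell_px, cell_px))
        stamp = np.zeros((cell_px, cell_px), dtype=bool)
        stamp[rr, cc] = True
        count = int(stamp.sum())
        if best is None or abs(count - area_px) < abs(best[1] - area_px):
            best = (stamp, count)
        if abs(count - area_px) <= tol * area_px:
            return stamp
        scale *= np.sqrt(area_px / max(count, 1))
    return best[0]


def _dip_factor(stamp_time: dt.datetime, spec: SceneSpec) -> float:
    """Multiplicative area reduction in [1 - amp, 1] after each dawn."""
    if spec.dip_amplitude <= 0:
        return 1.0
    on = spec.schedule.lights_on
    minutes = (
        (stamp_time.hour - on.hour) * 60 + (stamp_time.minute - on.minute)
    ) % 1440
    dur = spec.dip_duration_h * 60.0
    if minutes < dur:
        return 1.0 - spec.dip_amplitude * np.sin(np.pi * minutes / dur)
    return 1.0


def _render_vis(labels, plant_colors, soil_field, rng, spec) -> np.ndarray:
    h, w = labels.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = spec.soil_rgb[ch] + soil_field
    img += rng.normal(0.0, spec.soil_noise, img.shape)
    for pid, (hue, sat, val) in plant_colors.items():
        sel = labels == pid
        n = int(sel.sum())
        if n == 0:
            continue
        jh, js, jv = spec.plant_hsv_jitter
        hsv = np.stack(
            [
                (rng.normal(hue, jh, n) % 360.0) / 360.0,
                np.clip(rng.normal(sat, js, n), 0, 1),
                np.clip(rng.normal(val, jv, n), 0, 1),
            ],
            axis=-1,
        )
        img[sel] = skcolor.hsv2rgb(hsv[None, :, :])[0] * 255.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _render_nir(labels, plant_nir, soil_field, falloff, rng, spec) -> np.ndarray:
    img = spec.nir_soil + soil_field
    img = np.where(labels > 0, 0.0, img)
    for pid, level in plant_nir.items():
        img = np.where(labels == pid, level, img)
    img = img * falloff + rng.normal(0.0, spec.nir_noise, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_session(spec: SceneSpec) -> tuple[DielSession, GroundTruth]:
    """Render the full session and its ground truth; reproducible from
    ``spec.rng_seed`` (two runs with equal specs are bit-identical)."""
    spec.validate()
    master = np.random.default_rng(spec.rng_seed)
    rows, cols = spec.grid
    h, w = spec.raster_shape
    mmpp2 = spec.mm_per_pixel**2

    plants = []
    for k in range(spec.n_plants):
        r_row, r_col = divmod(k, cols)
        shape = RosetteShape(
            n_leaves=int(master.integers(spec.leaf_count[0], spec.leaf_count[1] + 1)),
            lobedness=float(master.uniform(*spec.lobedness)),
            phase=float(master.uniform(0, 2 * np.pi)),
            vertex_jitter=0.03,
        )
        plants.append(
            {
                "plant_id": k + 1,
                "cell": (r_row, r_col),
                "a0_px": float(master.uniform(*spec.a0_mm2)) / mmpp2,
                "r": float(master.uniform(*spec.r_per_day)),
                "shape": shape,
                "shape_seed": int(master.integers(0, 2**31 - 1)),
                "hsv": (
                    float(master.normal(spec.plant_hsv[0], 3.0)),
                    float(np.clip(master.normal(spec.plant_hsv[1], 0.03), 0, 1)),
                    float(np.clip(master.normal(spec.plant_hsv[2], 0.03), 0, 1)),
                ),
                "nir": float(master.normal(spec.nir_plant, 5.0)),
            }
        )

    # static per-session fields: soil texture and NIR falloff
    soil_field = ndimage.gaussian_filter(
        master.normal(0.0, 1.0, (h, w)), sigma=12.0
    )
    amp = max(np.abs(soil_field).max(), 1e-9)
    soil_field = soil_field / amp * spec.soil_texture
    yy, xx = np.indices((h, w))
    d2 = ((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
    falloff = 1.0 - spec.nir_falloff * d2 / d2.max()

    frames: list[Frame] = []
    masks: list[LabeledMask] = []
    area_rows = []
    plant_ids = tuple(p["plant_id"] for p in plants)
    for k in range(spec.n_frames):
        stamp_time = spec.start + dt.timedelta(minutes=k * spec.interval_minutes)
        t_days = k * spec.interval_minutes / 1440.0
        dip = _dip_factor(stamp_time, spec)
        labels = np.zeros((h, w), dtype=np.int64)
        for p in plants:
            target = p["a0_px"] * np.exp(p["r"] * t_days) * dip
            stamp = render_rosette(
                p["shape"],
                target,
                spec.cell_px,
                rng=np.random.default_rng(p["shape_seed"]),
            )
            rr, cc = p["cell"]
            ys = slice(rr * spec.cell_px, (rr + 1) * spec.cell_px)
            xs = slice(cc * spec.cell_px, (cc + 1) * spec.cell_px)
            labels[ys, xs][stamp] = p["plant_id"]
        counts = np.bincount(labels.ravel(), minlength=len(plants) + 2)
        area_rows.append([int(counts[pid]) for pid in plant_ids])
        masks.append(LabeledMask(labels, plant_ids))

        frame_rng = np.random.default_rng([spec.rng_seed, 7919, k])
        if spec.schedule.is_light(stamp_time):
            px = _render_vis(
                labels,
                {p["plant_id"]: p["hsv"] for p in plants},
                soil_field,
                frame_rng,
                spec,
            )
            modality = Modality.VIS
        else:
            px = _render_nir(
                labels,
                {p["plant_id"]: p["nir"] for p in plants},
                soil_field,
                falloff,
                frame_rng,
                spec,
            )
            modality = Modality.NIR
        frames.append(Frame(px, stamp_time, modality))

    session = build_session(frames, spec.schedule)
    areas_px = pd.DataFrame(
        area_rows, index=range(len(frames)), columns=list(plant_ids)
    )
    truth = GroundTruth(
        masks=masks,
        areas_px=areas_px,
        areas_mm2=areas_px * mmpp2,
        spec=spec,
    )
    return session, truth
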