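"""End-to-end diel workflow: segmentation -> labelling -> traits -> RER.

Light periods are segmented per frame by colour-range (or Otsu) thresholding —
thresholding is cheap and stateless, so no propagation is needed there.  Dark
periods are segmented by Chan-Vese propagation seeded from the adjacent light
masks, run both forward (from the last VIS mask of the preceding light period)
and reverse (from the first VIS mask of the following light period), with the
two PRA series averaged.  Plant identities are locked at the first labelled
frame and carried by nearest-centroid matching.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chanvese import ChanVeseParams, average_passes, propagate_dark_period
from .growth import (
    DEFAULT_WINDOW_FRAMES,
    PRASeries,
    daily_rer,
    detect_dawn_dips,
    diel_rer,
)
from .illumination import IlluminationParams
from .labeling import (
    LabeledMask,
    label_auto,
    label_seeded,
    match_to_centroids,
    read_seed_file,
)
from .session import (
    TRAIT_COLUMNS,
    CalibrationSpec,
    DielSession,
    PhotoperiodSchedule,
    load_session,
    write_masks,
    write_traits,
)
from .threshold import ColorSpace, ThresholdSpec, clean_mask, otsu_threshold, threshold_ranges

__all__ = ["PipelineSettings", "PipelineConfig", "PipelineResult",
           "run_on_session", "run_pipeline", "DEFAULT_THRESHOLD"]

#: HSV ranges that isolate green foliage from brown soil
DEFAULT_THRESHOLD = ThresholdSpec(
    ColorSpace.HSV, ((60.0, 180.0), (0.15, 1.0), (0.05, 1.0))
)


@dataclass
class PipelineSettings:
    """Algorithm parameters for a run (everything except file paths)."""

    calibration: CalibrationSpec = field(
        default_factory=lambda: CalibrationSpec(0.25)
    )
    threshold: ThresholdSpec = DEFAULT_THRESHOLD
    chanvese: ChanVeseParams = field(default_factory=ChanVeseParams)
    illumination: IlluminationParams | None = field(
        default_factory=IlluminationParams
    )
    min_area_px: int = 25
    fill_holes: bool = True
    labelling_mode: str = "auto"          # "auto" | "seeded"
    seeds: list | None = None
    match_max_dist: float = 60.0          # px, centroid identity matching
    rer_window: int = DEFAULT_WINDOW_FRAMES


@dataclass
class PipelineConfig:
    """Settings plus I/O paths and schedule, loadable from one YAML file."""

    input_dir: Path
    output_dir: Path
    schedule: PhotoperiodSchedule
    settings: PipelineSettings = field(default_factory=PipelineSettings)
    pattern: str = "*.png"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            sched = raw["schedule"]
            schedule = PhotoperiodSchedule(
                _parse_clock(sched["lights_on"]), _parse_clock(sched["lights_off"])
            )
            st = PipelineSettings()
            if "calibration" in raw:
                st.calibration = CalibrationSpec(
                    float(raw["calibration"]["mm_per_pixel"])
                )
            if "threshold" in raw:
                th = raw["threshold"]
                space = ColorSpace(th["space"])
                if space is ColorSpace.GRAY_OTSU:
                    st.threshold = ThresholdSpec(space)
                else:
                    st.threshold = ThresholdSpec(
                        space, tuple(tuple(map(float, r)) for r in th["ranges"])
                    )
            if "illumination" in raw:
                il = raw["illumination"]
                if il.get("enabled", True):
                    st.illumination = IlluminationParams(
                        blur_sigma=il.get("blur_sigma"),
                        flatten_strength=il.get("flatten_strength", 0.5),
                    )
                else:
                    st.illumination = None
            if "chanvese" in raw:
                st.chanvese = ChanVeseParams(
                    **{k: v for k, v in raw["chanvese"].items()}
                )
            if "cleaning" in raw:
                st.min_area_px = int(raw["cleaning"].get("min_area_px", 25))
                st.fill_holes = bool(raw["cleaning"].get("fill_holes", True))
            if "labelling" in raw:
                lb = raw["labelling"]
                st.labelling_mode = lb.get("mode", "auto")
                if lb.get("seed_file"):
                    st.seeds = read_seed_file(lb["seed_file"])
                st.match_max_dist = float(lb.get("max_dist", 60.0))
            if "rer" in raw:
                st.rer_window = int(raw["rer"].get("window_frames",
                                                   DEFAULT_WINDOW_FRAMES))
            return cls(
                input_dir=Path(raw["input_dir"]),
                output_dir=Path(raw["output_dir"]),
                schedule=schedule,
                settings=st,
                pattern=raw.get("pattern", "*.png"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid pipeline config {path}: {exc}") from exc


def _parse_clock(text) -> dt.time:
    if isinstance(text, dt.time):
        return text
    parts = str(text).split(":")
    return dt.time(int(parts[0]), int(parts[1]) if len(parts) > 1 else 0)


@dataclass
class PipelineResult:
    masks: list[LabeledMask]
    traits: pd.DataFrame
    rer_table: pd.DataFrame
    dawn_dips: dict[int, list[dict]]
    warnings: list[str]


def _segment_vis(frame, settings: PipelineSettings) -> np.ndarray:
    if settings.threshold.space is ColorSpace.GRAY_OTSU:
        _, binary = otsu_threshold(frame.luminance())
    else:
        binary = threshold_ranges(frame, settings.threshold)
    return clean_mask(binary, settings.min_area_px, settings.fill_holes)


def _areas_frame(masks: list[LabeledMask], index, plant_ids) -> pd.DataFrame:
    rows = []
    for m in masks:
        counts = np.bincount(m.labels.ravel(), minlength=max(plant_ids) + 1)
        rows.append([float(counts[pid]) for pid in plant_ids])
    df = pd.DataFrame(rows, index=index, columns=list(plant_ids))
    return df.replace(0.0, np.nan)  # 0 px = vanished = missing


def run_on_session(
    session: DielSession, settings: PipelineSettings | None = None
) -> PipelineResult:
    """Run the full workflow on an in-memory session; nothing is written."""
    settings = settings or PipelineSettings()
    n = len(session.frames)
    labeled: list[LabeledMask | None] = [None] * n
    run_warnings: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- light periods: stateless per-frame thresholding + labelling
        centroids: dict[int, tuple[float, float]] | None = None
        plant_ids: tuple[int, ...] | None = None
        for period in session.light_periods():
            for fi in range(period.start, period.stop):
                binary = _segment_vis(session.frames[fi], settings)
                if centroids is None:
                    if settings.labelling_mode == "seeded":
                        if not settings.seeds:
                            raise ValueError("seeded labelling requires seeds")
                        lm = label_seeded(binary, settings.seeds)
                    else:
                        lm = label_auto(binary)
                    plant_ids = lm.plant_ids
                else:
                    lm = match_to_centroids(
                        binary, centroids, settings.match_max_dist
                    )
                labeled[fi] = lm
                cur = lm.centroids()
                centroids = dict(centroids or {})
                centroids.update(cur)

        if plant_ids is None:
            raise ValueError("session contains no light period to label from")

        # --- dark periods: forward/reverse Chan-Vese propagation, averaged
        dark_pra: dict[int, pd.DataFrame] = {}
        for period in session.dark_periods():
            frames = session.period_frames(period)
            idx = list(range(period.start, period.stop))
            fwd_seed = labeled[period.start - 1] if period.start > 0 else None
            rev_seed = labeled[period.stop] if period.stop < n else None
            fwd = rev = None
            if fwd_seed is not None:
                fwd = propagate_dark_period(
                    frames, fwd_seed, "forward", settings.chanvese,
                    settings.illumination,
                )
            if rev_seed is not None:
                rev = propagate_dark_period(
                    frames[::-1], rev_seed, "reverse", settings.chanvese,
                    settings.illumination,
                )
                rev = rev[::-1]
            if fwd is None and rev is None:
                run_warnings.append(
                    f"dark period {period.index}: no adjacent light mask; skipped"
                )
                continue
            if fwd is not None and rev is not None:
                pra = average_passes(
                    _areas_frame(fwd, idx, plant_ids),
                    _areas_frame(rev, idx, plant_ids),
                )
            else:
                pra = _areas_frame(fwd or rev, idx, plant_ids)
            dark_pra[period.index] = pra
            canonical = fwd if fwd is not None else rev
            for fi, m in zip(idx, canonical):
                labeled[fi] = m

        # --- trait table
        rows = []
        calib = settings.calibration
        for fi, frame in enumerate(session.frames):
            period = session.period_of(fi)
            if period.kind == "light" and labeled[fi] is not None:
                counts = np.bincount(
                    labeled[fi].labels.ravel(), minlength=max(plant_ids) + 1
                )
                values = {pid: float(counts[pid]) for pid in plant_ids}
            elif period.index in dark_pra:
                row = dark_pra[period.index].loc[fi]
                values = {pid: row[pid] for pid in plant_ids}
            else:
                run_warnings.append(f"frame {fi}: no segmentation available")
                values = {pid: np.nan for pid in plant_ids}
            for pid in plant_ids:
                v = values[pid]
                miss = not np.isfinite(v) or v <= 0
                px = 0.0 if miss else float(v)
                rows.append(
                    dict(
                        plant_id=pid,
                        timestamp=frame.timestamp,
                        frame_index=fi,
                        period_index=period.index,
                        period_kind=period.kind,
                        pra_px=px,
                        pra_mm2=calib.px_to_mm2(px),
                        missing=miss,
                    )
                )
        traits = pd.DataFrame(rows, columns=TRAIT_COLUMNS)

        # --- growth traits
        rer_rows = []
        dips: dict[int, list[dict]] = {}
        for pid in plant_ids:
            try:
                series = PRASeries.from_traits(traits, pid)
            except ValueError:
                continue
            t0 = session.frames[0].timestamp
            try:
                for pidx, value in daily_rer(series, session):
                    p = session.periods[pidx]
                    mid = (
                        (session.frames[p.start].timestamp - t0)
                        + (session.frames[p.stop - 1].timestamp - t0)
                    ) / 2
                    rer_rows.append(
                        dict(plant_id=pid,
                             time_days=mid.total_seconds() / 86400.0,
                             rer_per_day=value, kind="daily")
                    )
            except ValueError as exc:
                run_warnings.append(f"plant {pid}: daily RER failed: {exc}")
            try:
                dr = diel_rer(series, settings.rer_window)
                for t, v in zip(dr.times, dr.rer_values):
                    rer_rows.append(
                        dict(plant_id=pid, time_days=float(t),
                             rer_per_day=float(v), kind="diel")
                    )
            except ValueError as exc:
                run_warnings.append(f"plant {pid}: diel RER failed: {exc}")
            dips[pid] = detect_dawn_dips(series, session)
        rer_table = pd.DataFrame(
            rer_rows, columns=["plant_id", "time_days", "rer_per_day", "kind"]
        )

        run_warnings.extend(str(w.message) for w in caught)

    final_masks = [
        m if m is not None else LabeledMask(
            np.zeros(session.shape, dtype=np.int64), plant_ids
        )
        for m in labeled
    ]
    return PipelineResult(final_masks, traits, rer_table, dips, run_warnings)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load the session, run the workflow, and write all outputs.

    Writes label masks (PNG), ``traits.csv``, ``rer.csv`` and a JSON run
    manifest under ``config.output_dir``.
    """
    session = load_session(config.input_dir, config.schedule, config.pattern)
    result = run_on_session(session, config.settings)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_masks(session, [m.labels for m in result.masks], out / "masks")
    write_traits(result.traits, out / "traits.csv")
    result.rer_table.to_csv(out / "rer.csv", index=False)
    manifest = {
        "package": "phenodiel",
        "version": __version__,
        "input_dir": str(config.input_dir),
        "n_frames": len(session.frames),
        "periods": [
            dict(index=p.index, kind=p.kind, start=p.start, stop=p.stop)
            for p in session.periods
        ],
        "settings": _settings_echo(config.settings),
        "warnings": result.warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _settings_echo(st: PipelineSettings) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, (str, int, float, bool)) or obj is None:
            return obj
        return str(obj)

    return {
        "calibration": enc(st.calibration),
        "threshold": enc(st.threshold),
        "chanvese": enc(st.chanvese),
        "illumination": enc(st.illumination),
        "min_area_px": st.min_area_px,
        "fill_holes": st.fill_holes,
        "labelling_mode": st.labelling_mode,
        "match_max_dist": st.match_max_dist,
        "rer_window": st.rer_window,
    }
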